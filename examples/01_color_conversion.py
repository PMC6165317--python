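"""Convert camera RGB to CIELAB and measure color differences.

The device works in CIE L*a*b*: L* is lightness (black 0, white 100), a* is
the red-green axis, b* the yellow-blue axis.  dE is the Euclidean distance
between two Lab colors — the classical measure of how different two tooth
shades look.
"""

from shadematch import RGBColor, delta_e, rgb_to_lab

white = rgb_to_lab(RGBColor(1.0, 1.0, 1.0))
black = rgb_to_lab(RGBColor(0.0, 0.0, 0.0))
tooth = rgb_to_lab(RGBColor.from_8bit(172, 148, 113))

print(f"white  -> L*={white.L:6.2f} a*={white.a:+5.2f} b*={white.b:+5.2f}")
print(f"black  -> L*={black.L:6.2f} a*={black.a:+5.2f} b*={black.b:+5.2f}")
print(f"tooth  -> L*={tooth.L:6.2f} a*={tooth.a:+5.2f} b*={tooth.b:+5.2f}")

other = rgb_to_lab(RGBColor.from_8bit(166, 145, 120))
d = delta_e(tooth, other)
print(f"dE between the two tooth colors = {d.delta_e:.2f} "
      f"(dL={d.delta_L:+.2f}, da={d.delta_a:+.2f}, db={d.delta_b:+.2f})")
print("A dE above ~3.3 is usually considered clinically noticeable.")
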