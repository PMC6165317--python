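"""Build the reference shade database from simulated device measurements.

Five devices each measure the 26-tab guide seven times (35 records per tab);
the per-tab representative color is the mean of its measurements.
"""

import numpy as np

from shadematch import build_database, default_palette, make_device_profiles
from shadematch.synthetic_data import simulate_device_dataset

palette = default_palette(seed=0)
profiles = make_device_profiles(5, seed=0)
rng = np.random.default_rng(0)

records = []
for profile in profiles:
    records += simulate_device_dataset(palette, profile, n_repeats=7, rng=rng)

db = build_database(records)
counts = db.counts()
print(f"total measurements: {len(db.measurements)} "
      f"({len(profiles)} devices x 7 repeats x 26 tabs)")
print(f"records per tab: {sorted(set(counts.values()))}")
for tab in ("1M1", "3M2", "5M3"):
    rep = db.representatives[tab]
    true = palette[tab]
    print(f"{tab:6s} representative L*a*b* = ({rep.L:5.1f}, {rep.a:+4.1f}, {rep.b:4.1f})"
          f"   palette = ({true.L:5.1f}, {true.a:+4.1f}, {true.b:4.1f})")
print("Representatives sit near the palette colors; the residual offset is "
      "the simulated devices' shared imperfection.")
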