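"""Reference shade database.

The VITA 3D-Master guide has 26 tabs organised by lightness group (1-5),
chroma (1-3, with half steps for the hue-shifted variants) and hue shift
(L = less red, M = middle, R = more red).  The measurement protocol records
each tab repeatedly on several devices (five devices x seven repeats = 35
records per tab for the reference database); the per-tab representative color
is the component-wise mean of its CIELAB measurements.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .colorspace import LabColor
from .errors import IntegrityError, ValidationError

__all__ = [
    "TAB_LABELS",
    "tab_labels",
    "Measurement",
    "ShadeDatabase",
    "build_database",
    "read_measurements",
    "write_measurements",
]


def _make_labels() -> tuple[str, ...]:
    labels: list[str] = ["1M1", "1M2"]
    for g in (2, 3, 4):
        labels += [
            f"{g}L1.5",
            f"{g}L2.5",
            f"{g}M1",
            f"{g}M2",
            f"{g}M3",
            f"{g}R1.5",
            f"{g}R2.5",
        ]
    labels += ["5M1", "5M2", "5M3"]
    return tuple(labels)


#: The 26 valid shade-tab labels in canonical 1M1 -> 5M3 order.
TAB_LABELS: tuple[str, ...] = _make_labels()
_LABEL_INDEX = {lab: i for i, lab in enumerate(TAB_LABELS)}


def tab_labels() -> list[str]:
    """Return the 26 shade-tab labels in canonical order (a fresh list)."""
    return list(TAB_LABELS)


def label_order(label: str) -> int:
    """Canonical sort key of a tab label; raises for unknown labels."""
    try:
        return _LABEL_INDEX[label]
    except KeyError:
        raise ValidationError(f"unknown shade-tab label {label!r}") from None


@dataclass(frozen=True)
class Measurement:
    """One (device, repeat, tab) -> mean CIELAB color record."""

    device_id: int
    repeat_index: int
    tab: str
    color: LabColor

    def __post_init__(self) -> None:
        if self.tab not in _LABEL_INDEX:
            raise ValidationError(f"unknown shade-tab label {self.tab!r}")
        if self.repeat_index < 1:
            raise ValidationError(
                f"repeat_index must be >= 1, got {self.repeat_index}"
            )


@dataclass
class ShadeDatabase:
    """All measurements plus per-tab representative (mean) colors."""

    measurements: list[Measurement]
    representatives: dict[str, LabColor] = field(default_factory=dict)

    def counts(self) -> dict[str, int]:
        """Number of stored measurements per tab label."""
        out: dict[str, int] = {}
        for m in self.measurements:
            out[m.tab] = out.get(m.tab, 0) + 1
        return out

    def features(self) -> tuple[np.ndarray, list[str]]:
        """(n, 3) Lab feature matrix and the parallel label list."""
        X = np.array([m.color.to_array() for m in self.measurements])
        y = [m.tab for m in self.measurements]
        return X, y


def build_database(
    measurements: Iterable[Measurement],
    *,
    representative: str = "mean",
) -> ShadeDatabase:
    """Assemble measurements into a database with per-tab representatives.

    ``representative`` selects the pooled statistic across all devices and
    repeats: ``"mean"`` (default) or ``"median"``.  Duplicate
    (device, repeat, tab) keys raise :class:`IntegrityError`.
    """
    records = list(measurements)
    if not records:
        raise ValidationError("cannot build a database from zero measurements")
    if representative not in ("mean", "median"):
        raise ValidationError(f"unknown representative mode {representative!r}")

    seen: set[tuple[int, int, str]] = set()
    per_tab: dict[str, list[np.ndarray]] = {}
    for m in records:
        key = (m.device_id, m.repeat_index, m.tab)
        if key in seen:
            raise IntegrityError(f"duplicate measurement key {key}")
        seen.add(key)
        per_tab.setdefault(m.tab, []).append(m.color.to_array())

    reduce = np.mean if representative == "mean" else np.median
    reps = {
        tab: LabColor(*reduce(np.stack(vals), axis=0))
        for tab, vals in per_tab.items()
    }
    # keep canonical ordering for deterministic iteration
    reps = {tab: reps[tab] for tab in TAB_LABELS if tab in reps}
    return ShadeDatabase(measurements=records, representatives=reps)


_COLUMNS = ["device_id", "repeat", "tab", "L", "a", "b"]


def write_measurements(db: ShadeDatabase | Sequence[Measurement], path) -> None:
    """Write measurements as CSV with 6-decimal fixed-point Lab columns."""
    records = db.measurements if isinstance(db, ShadeDatabase) else list(db)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(_COLUMNS)
        for m in records:
            writer.writerow(
                [
                    m.device_id,
                    m.repeat_index,
                    m.tab,
                    f"{m.color.L:.6f}",
                    f"{m.color.a:.6f}",
                    f"{m.color.b:.6f}",
                ]
            )


def read_measurements(path) -> list[Measurement]:
    """Read a measurement CSV (device_id, repeat, tab, L, a, b)."""
    path = Path(path)
    try:
        frame = pd.read_csv(path, dtype={"tab": str}, comment="#")
    except Exception as exc:  # malformed CSV as a whole
        raise ValidationError(f"{path}: cannot parse measurement CSV: {exc}") from exc
    missing = [c for c in _COLUMNS if c not in frame.columns]
    if missing:
        raise ValidationError(f"{path}: missing column(s) {missing}")

    out: list[Measurement] = []
    for i, row in enumerate(frame.itertuples(index=False), start=2):
        try:
            out.append(
                Measurement(
                    device_id=int(row.device_id),
                    repeat_index=int(row.repeat),
                    tab=str(row.tab),
                    color=LabColor(float(row.L), float(row.a), float(row.b)),
                )
            )
        except (TypeError, ValueError, ValidationError) as exc:
            raise ValidationError(f"{path}, line {i}: {exc}") from exc
    return out


def group_by_device(
    measurements: Iterable[Measurement],
) -> dict[int, list[Measurement]]:
    """Split records into per-device datasets keyed by device id."""
    out: dict[int, list[Measurement]] = {}
    for m in measurements:
        out.setdefault(m.device_id, []).append(m)
    return dict(sorted(out.items()))
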