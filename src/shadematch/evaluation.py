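"""Accuracy and reliability metrics, and leave-pair-out cross-validation.

* **Matching rate** of one evaluation run over the full guide:
  100 x (number of correctly matched tabs / 26).  Every unrounded per-run
  rate is therefore a multiple of 100/26.
* **Run summaries**: the mean rate (rounded to one decimal) and the sample
  standard deviation computed on the *unrounded* fractional rates — printed
  rates are first snapped back to the k/26 grid, which is what makes the
  summary reproducible from one-decimal tables.
* **Reliability** of a device for one tab: 100 x the frequency of the modal
  prediction over repeated runs, regardless of whether that prediction is
  correct; overall reliability is the mean over the 26 tabs.  The companion
  dispersion statistic ("failure rate") is offered in two readings.
* **LPOCV**: every one of the C(N, p) ways of holding out p of N device
  datasets is scored; each device appears in validation in exactly
  C(N-1, p-1) splits.
"""

from __future__ import annotations

import io
import logging
from collections import Counter
from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping, NamedTuple, Optional, Sequence

import numpy as np

from .errors import ValidationError
from .matching import match_classifier, match_euclidean, train_classifier
from .shade_db import TAB_LABELS, Measurement, build_database, label_order

__all__ = [
    "MatchingRate",
    "RunResult",
    "EvaluationReport",
    "LPOCVResult",
    "matching_rate",
    "summarize_runs",
    "reliability",
    "failure_rate",
    "lpocv",
    "report_table",
]

logger = logging.getLogger(__name__)

N_TABS = len(TAB_LABELS)


class MatchingRate(NamedTuple):
    """A matching rate as the exact percentage and its one-decimal rounding."""

    exact: float
    rounded: float


@dataclass(frozen=True)
class RunResult:
    """Predictions of one full-guide evaluation run on one device."""

    device_id: int
    run_index: int
    predictions: dict[str, str]  # true tab -> predicted tab


@dataclass
class EvaluationReport:
    """Per-run rates plus reliability summaries for one device/method."""

    device_id: int
    method: str
    run_rates: list[float]  # exact percentages
    mean_rate: float
    sd_rate: float
    per_tab_reliability: dict[str, float]
    overall_reliability: float
    failure_rate_run: float
    failure_rate_tab: float


@dataclass
class LPOCVResult:
    """Outcome of exhaustive leave-p-out validation over device datasets."""

    p: int
    algorithm: str
    split_count: int
    per_split_accuracy: list[float]
    validation_members: list[tuple[int, ...]]
    mean_accuracy: float
    sd_accuracy: float
    per_device_counts: dict[int, int] = field(default_factory=dict)


def matching_rate(
    predictions: Mapping[str, str], truth: Optional[Mapping[str, str]] = None
) -> MatchingRate:
    """100 x (matched tabs / 26) for a full-guide run.

    ``predictions`` maps each true tab to the predicted tab; ``truth``
    defaults to the identity (each tab should match itself).  All 26 tabs
    must be present.
    """
    missing = [t for t in TAB_LABELS if t not in predictions]
    if missing:
        raise ValidationError(f"predictions missing tab(s) {missing[:3]}...")
    truth = truth or {t: t for t in TAB_LABELS}
    matched = sum(1 for t in TAB_LABELS if predictions[t] == truth[t])
    exact = 100.0 * matched / N_TABS
    return MatchingRate(exact=exact, rounded=round(exact, 1))


def _snap_to_grid(rate: float, denominator: int) -> float:
    k = round(rate * denominator / 100.0)
    return 100.0 * k / denominator


def summarize_runs(
    rates: Sequence[float], *, snap_denominator: Optional[int] = N_TABS
) -> tuple[float, float]:
    """Mean (rounded to one decimal) and sample SD of per-run rates.

    The SD uses the n-1 denominator and is computed on unrounded fractional
    rates: with ``snap_denominator`` set (default 26), each input rate is
    first snapped to the nearest k/denominator grid point, so one-decimal
    table entries recover the exact underlying fractions.
    """
    vals = np.asarray(rates, dtype=float)
    if vals.size < 2:
        raise ValidationError("need at least 2 run rates for mean/SD")
    if snap_denominator:
        vals = np.array([_snap_to_grid(v, snap_denominator) for v in vals])
    mean = round(float(vals.mean()), 1)
    sd = float(vals.std(ddof=1))
    return mean, sd


def reliability(
    predictions_per_tab: Mapping[str, Sequence[str]],
) -> tuple[dict[str, float], float]:
    """Per-tab and overall repeat-consistency, ignoring correctness.

    A tab is 100% reliable if all repeated predictions agree, even if they
    agree on the wrong label; per-tab reliability is 100 x the modal
    prediction's frequency.  Modal ties pick the canonically first label
    (logged).  Overall reliability is the mean over the tabs present.
    """
    per_tab: dict[str, float] = {}
    for tab, preds in predictions_per_tab.items():
        preds = list(preds)
        if not preds:
            raise ValidationError(f"no predictions recorded for tab {tab!r}")
        counts = Counter(preds)
        top = max(counts.values())
        modal = sorted(
            (lab for lab, c in counts.items() if c == top), key=label_order
        )
        if len(modal) > 1:
            logger.info("reliability tie for tab %s among %s", tab, modal)
        per_tab[tab] = 100.0 * top / len(preds)
    overall = float(np.mean(list(per_tab.values())))
    return per_tab, overall


def failure_rate(
    predictions_per_tab: Mapping[str, Sequence[str]],
    *,
    mode: str = "run",
) -> float:
    """Dispersion of reliability, in the two available readings.

    ``mode="tab"``: sample SD of the per-tab reliabilities.
    ``mode="run"``: per run, the fraction of tabs whose prediction differs
    from that tab's modal prediction is a per-run *disagreement* percentage;
    the statistic is the sample SD of per-run agreement.  The narrative
    convention behind this number is ambiguous, so both readings are
    provided.
    """
    per_tab, _ = reliability(predictions_per_tab)
    if mode == "tab":
        vals = np.array(list(per_tab.values()))
        return float(vals.std(ddof=1)) if vals.size > 1 else 0.0
    if mode != "run":
        raise ValidationError(f"unknown failure-rate mode {mode!r}")
    # per-run agreement with the modal prediction
    tabs = list(predictions_per_tab)
    n_runs = min(len(predictions_per_tab[t]) for t in tabs)
    modal = {}
    for tab in tabs:
        counts = Counter(predictions_per_tab[tab])
        top = max(counts.values())
        modal[tab] = sorted(
            (lab for lab, c in counts.items() if c == top), key=label_order
        )[0]
    per_run = []
    for r in range(n_runs):
        agree = sum(
            1 for tab in tabs if predictions_per_tab[tab][r] == modal[tab]
        )
        per_run.append(100.0 * agree / len(tabs))
    arr = np.array(per_run)
    return float(arr.std(ddof=1)) if arr.size > 1 else 0.0


def _predict_measurements(
    model, method: str, records: Sequence[Measurement], db
) -> list[tuple[str, str]]:
    out = []
    for m in records:
        if method == "euclidean":
            res = match_euclidean(m.color, db)
        else:
            res = match_classifier(m.color, model)
        out.append((m.tab, res.predicted))
    return out


def lpocv(
    datasets: Mapping[int, Sequence[Measurement]] | Sequence[Sequence[Measurement]],
    p: int,
    algorithm: str = "svm",
    seed: int = 0,
    *,
    params: Optional[dict] = None,
    pool_validation: bool = False,
) -> LPOCVResult:
    """Exhaustive leave-p-out cross-validation over device datasets.

    For every p-subset of the N device datasets, a model is trained on the
    union of the remaining N - p datasets and scored on each held-out
    device (percent of its records matched to the true tab).  By default
    the split accuracy averages the per-device accuracies
    (``pool_validation=True`` pools all held-out records instead).  The
    result reports mean and sample SD across the C(N, p) splits.
    """
    if isinstance(datasets, Mapping):
        dev_map = dict(datasets)
    else:
        dev_map = {i + 1: list(d) for i, d in enumerate(datasets)}
    ids = sorted(dev_map)
    N = len(ids)
    if not (1 <= p <= N - 1):
        raise ValidationError(f"p must be in [1, {N - 1}], got {p}")
    for dev, records in dev_map.items():
        covered = {m.tab for m in records}
        if covered != set(TAB_LABELS):
            raise ValidationError(
                f"device {dev} dataset does not cover all 26 tabs"
            )

    per_split: list[float] = []
    members: list[tuple[int, ...]] = []
    counts: dict[int, int] = {i: 0 for i in ids}
    for val_ids in combinations(ids, p):
        train_ids = [i for i in ids if i not in val_ids]
        train_records = [m for i in train_ids for m in dev_map[i]]
        db = build_database(train_records)
        model = None
        if algorithm != "euclidean":
            model = train_classifier(db, algorithm, params=params, seed=seed)
        if pool_validation:
            pairs = []
            for i in val_ids:
                pairs += _predict_measurements(model, algorithm, dev_map[i], db)
            acc = 100.0 * sum(t == p_ for t, p_ in pairs) / len(pairs)
        else:
            per_dev = []
            for i in val_ids:
                pairs = _predict_measurements(model, algorithm, dev_map[i], db)
                per_dev.append(
                    100.0 * sum(t == p_ for t, p_ in pairs) / len(pairs)
                )
            acc = float(np.mean(per_dev))
        per_split.append(acc)
        members.append(val_ids)
        for i in val_ids:
            counts[i] += 1

    arr = np.array(per_split)
    return LPOCVResult(
        p=p,
        algorithm=algorithm,
        split_count=len(per_split),
        per_split_accuracy=per_split,
        validation_members=members,
        mean_accuracy=float(arr.mean()),
        sd_accuracy=float(arr.std(ddof=1)) if arr.size > 1 else 0.0,
        per_device_counts=counts,
    )


def report_table(results: Sequence, *, kind: str = "runs") -> tuple[str, str]:
    """Render evaluation results as aligned text and CSV.

    ``kind="runs"`` takes :class:`EvaluationReport` items (per-device run
    rates, average, SD); ``kind="lpocv"`` takes :class:`LPOCVResult` items
    (algorithm, mean accuracy, SD).  Returns ``(text, csv)``; with no
    results only headers are emitted.  Output ordering is deterministic.
    """
    csv_buf = io.StringIO()
    lines: list[str] = []
    if kind == "runs":
        n_runs = max((len(r.run_rates) for r in results), default=10)
        run_cols = [str(i) for i in range(1, n_runs + 1)]
        header = ["Method", "Device"] + run_cols + ["Average", "SD"]
        csv_buf.write(",".join(header) + "\n")
        lines.append("  ".join(f"{h:>7}" for h in header))
        for r in results:
            rates = [f"{round(v, 1):.1f}" for v in r.run_rates]
            row = (
                [r.method, f"#{r.device_id}"]
                + rates
                + [f"{r.mean_rate:.1f}", f"{r.sd_rate:.2f}"]
            )
            csv_buf.write(",".join(row) + "\n")
            lines.append("  ".join(f"{c:>7}" for c in row))
    elif kind == "lpocv":
        header = ["Algorithm", "MatchingAccuracy", "SD", "Splits"]
        csv_buf.write(",".join(header) + "\n")
        lines.append("  ".join(f"{h:>16}" for h in header))
        for r in results:
            row = [
                r.algorithm,
                f"{r.mean_accuracy:.1f}",
                f"{r.sd_accuracy:.2f}",
                str(r.split_count),
            ]
            csv_buf.write(",".join(row) + "\n")
            lines.append("  ".join(f"{c:>16}" for c in row))
    else:
        raise ValidationError(f"unknown table kind {kind!r}")
    return "\n".join(lines) + "\n", csv_buf.getvalue()
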