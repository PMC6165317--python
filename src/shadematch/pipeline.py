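"""End-to-end workflow: simulate -> calibrate -> build DB -> match -> evaluate.

Mirrors the device protocol: a family of simulated cameras each measures the
26-tab guide; each device fits its own color correction matrix from the
5-patch chart; a subset of devices (default 5 of 8) builds the reference
database; the remaining devices evaluate matching accuracy over repeated
full-guide runs, and leave-pair-out cross-validation compares classifiers
across all devices.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .calibration import apply_ccm, build_chart_from_palette, fit_ccm
from .colorspace import LabColor, RGBColor, rgb_to_lab
from .errors import ValidationError
from .evaluation import (
    EvaluationReport,
    failure_rate,
    lpocv,
    matching_rate,
    reliability,
    report_table,
    summarize_runs,
)
from .matching import match_classifier, match_euclidean, train_classifier
from .segmentation import segment_target
from .shade_db import TAB_LABELS, Measurement, build_database
from .synthetic_data import (
    DeviceProfile,
    SceneSpec,
    TabPalette,
    _aniso_noise,
    default_palette,
    make_device_profiles,
    render_scene,
    simulate_device_dataset,
    simulate_measurement,
    simulate_rgb_reading,
)

__all__ = [
    "RunConfig",
    "calibrate_device",
    "measure_tab_via_image",
    "evaluate_test_device",
    "run_pipeline",
    "svm_vs_euclidean_benchmark",
]

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Validated knobs for the full pipeline run.

    Unknown keys are rejected by :meth:`from_dict`; cross-field constraints
    (device counts, LPOCV p) are checked before any computation.
    """

    seed: int = 0
    n_devices: int = 8
    n_train_devices: int = 5
    n_repeats: int = 7
    n_runs: int = 10
    methods: tuple[str, ...] = ("euclidean", "svm")
    noise_sd: float = 0.01
    distortion_scale: float = 0.1
    bias_scale: float = 0.005
    aniso_stretch: float = 3.0
    svm_params: Optional[dict] = None
    canny_low: float = 10.0
    canny_high: float = 20.0
    min_area_frac: float = 0.01
    glare_exclude: bool = False
    representative: str = "mean"
    failure_rate_mode: str = "run"
    lpocv_p: Optional[int] = None
    lpocv_algorithms: tuple[str, ...] = ("svm", "lr", "rf", "knn")
    render: bool = False
    out_dir: Optional[str] = None

    def __post_init__(self) -> None:
        if self.n_train_devices >= self.n_devices:
            raise ValidationError(
                "n_train_devices must be smaller than n_devices"
            )
        if self.n_repeats < 1 or self.n_runs < 1:
            raise ValidationError("n_repeats and n_runs must be >= 1")
        if self.lpocv_p is not None and not (1 <= self.lpocv_p <= self.n_devices - 1):
            raise ValidationError(
                f"lpocv_p must be in [1, {self.n_devices - 1}], got {self.lpocv_p}"
            )
        for m in self.methods:
            if m not in ("euclidean", "svm", "lr", "rf", "knn"):
                raise ValidationError(f"unknown method {m!r}")

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValidationError(f"unknown config key(s): {sorted(unknown)}")
        data = dict(data)
        for key in ("methods", "lpocv_algorithms"):
            if key in data and isinstance(data[key], list):
                data[key] = tuple(data[key])
        return cls(**data)

    def hash(self) -> str:
        payload = dataclasses.asdict(self)
        payload.pop("out_dir", None)  # where results land is not a knob
        return hashlib.sha1(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:12]


def calibrate_device(
    palette: TabPalette,
    profile: DeviceProfile,
    rng: np.random.Generator,
    n_repeats: int = 7,
    *,
    chart_noise_factor: float = 0.1,
):
    """Fit a device's CCM from repeated raw readings of the 5-patch chart.

    Measured chart colors are the per-patch means of ``n_repeats`` raw RGB
    readings; references are the palette colors of the chart tabs.  The five
    tooth-range chart colors are nearly collinear in RGB, so the fit is
    ill-conditioned and amplifies chart noise into systematic correction
    error; because the chart is captured under a fixed jig and averaged over
    the whole patch, its readings carry much less noise than a run-time
    tooth measurement (``chart_noise_factor`` scales the profile's
    ``noise_sd``).  Returns ``(ccm, chart)``.
    """
    chart = build_chart_from_palette(palette)
    chart_profile = dataclasses.replace(
        profile, noise_sd=profile.noise_sd * chart_noise_factor
    )
    measured = []
    for label, _ in chart.entries:
        reads = np.stack(
            [
                simulate_rgb_reading(palette, label, chart_profile, rng).to_array()
                for _ in range(n_repeats)
            ]
        )
        measured.append(RGBColor(*np.clip(reads.mean(axis=0), 0.0, 1.0)))
    ccm = fit_ccm(measured, [c for _, c in chart.entries])
    return ccm, chart


def measure_tab_via_image(
    palette: TabPalette,
    tab: str,
    profile: DeviceProfile,
    rng: np.random.Generator,
    *,
    ccm=None,
    spec: Optional[SceneSpec] = None,
    glare_exclude: bool = False,
) -> LabColor:
    """Measure one tab through the full imaging path.

    The device's raw (distorted) RGB reading is painted into a rendered
    scene, the scene is segmented, the region's mean RGB is color-corrected
    and converted to Lab, and the device's residual anisotropic variation is
    added — the same chain a captured frame would go through.
    """
    spec = spec or SceneSpec()
    reading = simulate_rgb_reading(palette, tab, profile, rng)
    img, _ = render_scene(spec, reading, rng)
    _, mean_rgb = segment_target(img, glare_exclude=glare_exclude)
    if ccm is not None:
        mean_rgb = apply_ccm(mean_rgb, ccm)
    lab = rgb_to_lab(mean_rgb).to_array() + _aniso_noise(profile, rng)
    return LabColor(*lab)


def evaluate_test_device(
    palette: TabPalette,
    profile: DeviceProfile,
    db,
    models: dict,
    methods: Sequence[str],
    n_runs: int,
    rng: np.random.Generator,
    *,
    ccm=None,
    render: bool = False,
    failure_rate_mode: str = "run",
) -> dict[str, EvaluationReport]:
    """Run the full guide ``n_runs`` times on one test device, per method."""
    preds: dict[str, dict[str, list[str]]] = {m: {t: [] for t in TAB_LABELS} for m in methods}
    rates: dict[str, list[float]] = {m: [] for m in methods}
    for run in range(1, n_runs + 1):
        colors = {}
        for tab in TAB_LABELS:
            if render:
                colors[tab] = measure_tab_via_image(
                    palette, tab, profile, rng, ccm=ccm
                )
            else:
                colors[tab] = simulate_measurement(
                    palette, tab, profile, rng, repeat_index=run, ccm=ccm
                ).color
        for method in methods:
            run_pred = {}
            for tab, color in colors.items():
                if method == "euclidean":
                    res = match_euclidean(color, db)
                else:
                    res = match_classifier(color, models[method])
                run_pred[tab] = res.predicted
                preds[method][tab].append(res.predicted)
            rates[method].append(matching_rate(run_pred).exact)

    reports = {}
    for method in methods:
        if len(rates[method]) >= 2:
            mean, sd = summarize_runs(rates[method], snap_denominator=None)
        else:
            mean, sd = round(float(rates[method][0]), 1), float("nan")
        per_tab, overall = reliability(preds[method])
        reports[method] = EvaluationReport(
            device_id=profile.device_id,
            method=method,
            run_rates=rates[method],
            mean_rate=mean,
            sd_rate=sd,
            per_tab_reliability=per_tab,
            overall_reliability=overall,
            failure_rate_run=failure_rate(preds[method], mode="run"),
            failure_rate_tab=failure_rate(preds[method], mode="tab"),
        )
    return reports


def run_pipeline(config: RunConfig) -> dict:
    """Execute the whole workflow under one seeded generator.

    Stages: palette -> device profiles -> per-device CCM calibration ->
    training measurements -> reference database (+ classifiers) -> repeated
    full-guide runs on the held-out devices -> optional LPOCV over all
    devices.  Artifacts (measurements, tables) are written to
    ``config.out_dir`` when set; every file header embeds the config hash
    and seed.
    """
    rng = np.random.default_rng(config.seed)
    stamp = f"config_hash={config.hash()} seed={config.seed}"
    palette = default_palette(config.seed)
    profiles = make_device_profiles(
        config.n_devices,
        config.seed,
        distortion_scale=config.distortion_scale,
        bias_scale=config.bias_scale,
        noise_sd=config.noise_sd,
        aniso_stretch=config.aniso_stretch,
    )
    train_profiles = profiles[: config.n_train_devices]
    test_profiles = profiles[config.n_train_devices :]

    logger.info("calibrating %d devices", len(profiles))
    ccms = {
        p.device_id: calibrate_device(palette, p, rng, config.n_repeats)[0]
        for p in profiles
    }

    logger.info("building reference database")
    train_records: list[Measurement] = []
    for p in train_profiles:
        train_records += simulate_device_dataset(
            palette, p, config.n_repeats, rng, ccm=ccms[p.device_id]
        )
    db = build_database(train_records, representative=config.representative)

    models = {}
    for method in config.methods:
        if method == "euclidean":
            continue
        params = config.svm_params if method == "svm" else None
        models[method] = train_classifier(db, method, params=params, seed=config.seed)

    logger.info("evaluating %d test devices x %d runs", len(test_profiles), config.n_runs)
    reports: list[EvaluationReport] = []
    for p in test_profiles:
        dev_reports = evaluate_test_device(
            palette,
            p,
            db,
            models,
            config.methods,
            config.n_runs,
            rng,
            ccm=ccms[p.device_id],
            render=config.render,
            failure_rate_mode=config.failure_rate_mode,
        )
        reports += [dev_reports[m] for m in config.methods]

    lpocv_results = []
    if config.lpocv_p is not None:
        logger.info("LPOCV p=%d over %d devices", config.lpocv_p, config.n_devices)
        datasets = {}
        for p in profiles:
            datasets[p.device_id] = simulate_device_dataset(
                palette, p, config.n_repeats, rng, ccm=ccms[p.device_id]
            )
        for algo in config.lpocv_algorithms:
            params = config.svm_params if algo == "svm" else None
            lpocv_results.append(
                lpocv(datasets, config.lpocv_p, algo, seed=config.seed, params=params)
            )

    out = {
        "config": config,
        "palette": palette,
        "db": db,
        "reports": reports,
        "lpocv": lpocv_results,
    }
    if config.out_dir:
        out_dir = Path(config.out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        meas_path = out_dir / "measurements.csv"
        meas_path.write_text(f"# {stamp}\n")
        _append_measurements(meas_path, train_records)
        text, csv_text = report_table(reports, kind="runs")
        (out_dir / "report_runs.txt").write_text(f"# {stamp}\n" + text)
        (out_dir / "report_runs.csv").write_text(f"# {stamp}\n" + csv_text)
        if lpocv_results:
            text, csv_text = report_table(lpocv_results, kind="lpocv")
            (out_dir / "report_lpocv.txt").write_text(f"# {stamp}\n" + text)
            (out_dir / "report_lpocv.csv").write_text(f"# {stamp}\n" + csv_text)
        out["out_dir"] = str(out_dir)
    return out


def _append_measurements(path: Path, records) -> None:
    import csv as _csv

    with open(path, "a", newline="") as fh:
        writer = _csv.writer(fh)
        writer.writerow(["device_id", "repeat", "tab", "L", "a", "b"])
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


def svm_vs_euclidean_benchmark(
    n_replicates: int = 20,
    seed: int = 0,
    *,
    noise_sd: float = 0.01,
    svm_params: Optional[dict] = None,
    n_runs: int = 1,
) -> dict:
    """Mean matching accuracy of SVM vs. nearest-dE on fresh synthetic families.

    Each replicate draws a new 8-device family (5 build the database, 3
    test), calibrates every device, and scores both matchers over ``n_runs``
    full-guide runs per test device.  Returns per-replicate and mean
    accuracies for both methods.
    """
    rng_master = np.random.default_rng(seed)
    svm_acc, euc_acc = [], []
    for rep in range(n_replicates):
        rep_seed = int(rng_master.integers(0, 2**31 - 1))
        config = RunConfig(
            seed=rep_seed,
            noise_sd=noise_sd,
            n_runs=n_runs,
            svm_params=svm_params,
            methods=("euclidean", "svm"),
        )
        result = run_pipeline(config)
        by_method: dict[str, list[float]] = {"euclidean": [], "svm": []}
        for report in result["reports"]:
            by_method[report.method] += report.run_rates
        euc_acc.append(float(np.mean(by_method["euclidean"])))
        svm_acc.append(float(np.mean(by_method["svm"])))
        logger.info(
            "replicate %d: euclidean %.1f%%, svm %.1f%%", rep, euc_acc[-1], svm_acc[-1]
        )
    return {
        "euclidean": euc_acc,
        "svm": svm_acc,
        "mean_euclidean": float(np.mean(euc_acc)),
        "mean_svm": float(np.mean(svm_acc)),
    }
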