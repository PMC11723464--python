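"""End-to-end orchestration: scenes -> slices -> VI features -> classifiers.

A run takes a :class:`PipelineConfig`, executes segmentation, slicing,
VI computation, VI selection and classification, and leaves a run
directory containing ``features.csv``, ``separation_report.json``, one
``report_<algorithm>.json`` per model, and ``manifest.json`` (resolved
config echo, seeds, record counts at every filtering stage). Every
stochastic stage derives its seed from the single global seed, so a rerun
with the same config is bit-identical.

``reproduce_study`` is the one-command synthetic study: a three-time-point
orchard whose quadrant prevalences follow the seasonal healthy:unhealthy
drift (ratios 2.28 -> 0.92 -> 0.39), all stages, and all three
classifiers, with a side-by-side table against the published real-data
reference metrics (clearly labeled as non-matching context: the synthetic
study is a calibration exercise, not a reproduction of field imagery).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .classify import ALGORITHMS, HealthClassifier, ModelSpec, SplitSpec
from .raster_io import write_bandstack, write_feature_table
from .segmentation import SegmentationConfig, segment_plant
from .synthetic import FIG_RATIO_PREVALENCES, OrchardScenario, iter_dataset
from .vegindex import SELECTED_FEATURES, VIConfig, compute_all, separation_report

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline", "reproduce_study", "REFERENCE_METRICS"]

#: Published real-data reference metrics (accuracy, F1 per class, false-
#: negative rate) for the three learners. Shown next to synthetic-run
#: metrics for orientation only; the unreleased field imagery is required
#: to reproduce them, so agreement is neither expected nor checked.
REFERENCE_METRICS = {
    "random_forest": {"accuracy": 0.65, "f1_healthy": 0.61, "f1_unhealthy": 0.69, "fn_rate": 0.136},
    "logistic_regression": {"accuracy": 0.66, "f1_healthy": 0.62, "f1_unhealthy": 0.69, "fn_rate": 0.137},
    "knn": {"accuracy": 0.64, "f1_healthy": 0.61, "f1_unhealthy": 0.67, "fn_rate": 0.160},
}


@dataclass
class PipelineConfig:
    """Resolved configuration of one pipeline run."""

    out_dir: str = "run"
    seed: int = 0
    scenario: OrchardScenario = field(default_factory=OrchardScenario)
    segmentation: SegmentationConfig = field(default_factory=SegmentationConfig)
    vi: VIConfig = field(default_factory=VIConfig)
    feature_names: tuple[str, ...] = SELECTED_FEATURES
    split: SplitSpec = field(default_factory=SplitSpec)
    models: tuple[str, ...] = ALGORITHMS
    selection_threshold_d: float = 0.5
    write_images: bool = False
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs = {}
        if "scenario" in raw:
            kwargs["scenario"] = OrchardScenario(**raw.pop("scenario"))
        if "segmentation" in raw:
            kwargs["segmentation"] = SegmentationConfig(**raw.pop("segmentation"))
        if "vi" in raw:
            kwargs["vi"] = VIConfig(**raw.pop("vi"))
        if "split" in raw:
            kwargs["split"] = SplitSpec(**raw.pop("split"))
        for key in ("feature_names", "models"):
            if key in raw:
                raw[key] = tuple(raw[key])
        kwargs.update(raw)
        return cls(**kwargs)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


def _features_from_dataset(
    dataset, cfg: PipelineConfig, image_dir: Path | None = None
) -> tuple[pd.DataFrame, dict]:
    """Segment, slice and compute VI records for every rendered plant.

    ``dataset`` may be any iterable of (BandStack, GroundTruth); plants are
    consumed one at a time so arbitrarily large orchards stream through.
    """
    rows = []
    counts = {"plants": 0, "slices_total": 0, "slices_kept": 0}
    for stack, truth in dataset:
        if image_dir is not None:
            write_bandstack(stack, image_dir / f"{truth.plant_id}.tif")
        _, slices, kept = segment_plant(
            stack,
            cfg.segmentation,
            plant_id=truth.plant_id,
            quadrant_labels=truth.quadrant_labels,
        )
        counts["plants"] += 1
        counts["slices_total"] += len(slices)
        counts["slices_kept"] += len(kept)
        for sub in kept:
            rec = compute_all(sub, cfg.vi)
            row = rec.as_row()
            row["time_point"] = truth.time_point
            rows.append(row)
    counts["slices_dropped"] = counts["slices_total"] - counts["slices_kept"]
    return pd.DataFrame(rows), counts


def run_pipeline(cfg: PipelineConfig, dataset=None) -> Path:
    """Execute the full pipeline; returns the run directory.

    Without an explicit ``dataset``, the synthetic generator supplies one
    from ``cfg.scenario`` (seeded by the global seed).
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, cfg.log_level.upper(), logging.INFO))
    fh = logging.FileHandler(out / "run.log")
    logging.getLogger().addHandler(fh)
    try:
        return _run(cfg, dataset, out)
    finally:
        logging.getLogger().removeHandler(fh)
        fh.close()


def _run(cfg: PipelineConfig, dataset, out: Path) -> Path:
    manifest: dict = {
        "version": __version__,
        "seed": cfg.seed,
        "config": cfg.to_dict(),
        "counts": {},
    }
    if dataset is None:
        scenario = dataclasses.replace(cfg.scenario, seed=cfg.seed)
        try:
            dataset = iter_dataset(scenario)
        except Exception as exc:
            raise RuntimeError(f"stage synthetic_orchard failed: {exc}") from exc
    img_dir = None
    if cfg.write_images:
        img_dir = out / "images"
        img_dir.mkdir(exist_ok=True)

    try:
        features, counts = _features_from_dataset(dataset, cfg, image_dir=img_dir)
    except Exception as exc:
        raise RuntimeError(f"stage segmentation/vegindex failed: {exc}") from exc
    manifest["counts"].update(counts)
    write_feature_table(features, out / "features.csv")

    labeled = features.dropna(subset=["label"]) if "label" in features.columns else features.iloc[0:0]
    reports = {}
    if len(labeled) and labeled["label"].nunique() == 2:
        sep = separation_report(labeled, threshold_d=cfg.selection_threshold_d)
        (out / "separation_report.json").write_text(json.dumps(sep.to_dict(), indent=2))
        manifest["selected_vis"] = sep.selected
        for algo in cfg.models:
            try:
                model = HealthClassifier(
                    labeled,
                    feature_names=cfg.feature_names,
                    spec=ModelSpec(algorithm=algo),
                    split=dataclasses.replace(cfg.split, seed=cfg.seed),
                )
                res = model.fit(seed=cfg.seed)
            except Exception as exc:
                raise RuntimeError(f"stage health_classifier({algo}) failed: {exc}") from exc
            payload = {
                "algorithm": algo,
                "report": res.report.to_dict(),
                "cv_mean_accuracy": res.cv["mean_accuracy"],
                "cv_sd_accuracy": res.cv["sd_accuracy"],
            }
            (out / f"report_{algo}.json").write_text(json.dumps(payload, indent=2))
            np.savetxt(
                out / f"confusion_{algo}.csv",
                [[res.report.tn, res.report.fp], [res.report.fn, res.report.tp]],
                fmt="%d",
                delimiter=",",
                header="pred0,pred1",
                comments="",
            )
            reports[algo] = payload
    manifest["reports"] = reports
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    with open(out / "config.yaml", "w") as fhh:
        yaml.safe_dump(cfg.to_dict(), fhh, default_flow_style=False)
    return out


def reproduce_study(
    seed: int = 0,
    out_dir: str | Path = "reproduction",
    n_plants_per_time: int = 140,
    models: Sequence[str] = ALGORITHMS,
) -> dict:
    """Run the full three-time-point synthetic study and summarize it.

    Returns the summary dict (also written to ``<out_dir>/summary.json``)
    with the selected VI set, per-model metrics, per-time-point class
    ratios and the published reference metrics for side-by-side context.
    """
    scenario = OrchardScenario(
        n_plants=n_plants_per_time,
        prevalence_unhealthy=FIG_RATIO_PREVALENCES,
        seed=seed,
    )
    cfg = PipelineConfig(
        out_dir=str(out_dir), seed=seed, scenario=scenario, models=tuple(models)
    )
    out = run_pipeline(cfg)
    manifest = json.loads((out / "manifest.json").read_text())
    features = pd.read_csv(out / "features.csv")
    ratios = {}
    for t, grp in features.groupby("time_point"):
        n1 = int((grp["label"] == 1).sum())
        n0 = int((grp["label"] == 0).sum())
        ratios[f"t{t}"] = {"healthy": n0, "unhealthy": n1, "ratio": n0 / n1 if n1 else float("inf")}
    summary = {
        "seed": seed,
        "n_plants": manifest["counts"]["plants"],
        "slices_total": manifest["counts"]["slices_total"],
        "slices_kept": manifest["counts"]["slices_kept"],
        "selected_vis": manifest.get("selected_vis", []),
        "class_ratio_by_time": ratios,
        "models": {
            algo: {
                "accuracy": rep["report"]["accuracy"],
                "f1_healthy": rep["report"]["per_class"]["0"]["f1"],
                "f1_unhealthy": rep["report"]["per_class"]["1"]["f1"],
                "fn_rate": rep["report"]["fn_rate"],
                "cv_mean_accuracy": rep["cv_mean_accuracy"],
            }
            for algo, rep in manifest["reports"].items()
        },
        "reference_metrics_not_expected_to_match": REFERENCE_METRICS,
    }
    (out / "summary.json").write_text(json.dumps(summary, indent=2))
    return summary


def format_study_summary(summary: dict) -> str:
    """Human-readable side-by-side table for ``reproduce_study`` output."""
    lines = [
        "Synthetic reproduction study",
        "=" * 72,
        f"plants: {summary['n_plants']}   slices kept: {summary['slices_kept']}"
        f"/{summary['slices_total']}",
        f"selected VIs: {', '.join(summary['selected_vis'])}",
        "healthy:unhealthy ratio by time point: "
        + ", ".join(f"{k}={v['ratio']:.2f}" for k, v in summary["class_ratio_by_time"].items()),
        "-" * 72,
        f"{'model':<22}{'acc(syn)':>9}{'acc(ref)':>9}{'fn%(syn)':>10}{'fn%(ref)':>10}",
    ]
    for algo, m in summary["models"].items():
        ref = summary["reference_metrics_not_expected_to_match"][algo]
        lines.append(
            f"{algo:<22}{m['accuracy']:>9.3f}{ref['accuracy']:>9.2f}"
            f"{100 * m['fn_rate']:>10.1f}{100 * ref['fn_rate']:>10.1f}"
        )
    lines.append("-" * 72)
    lines.append(
        "reference columns are published real-data values shown for context;"
        " synthetic metrics are not expected to match them."
    )
    return "\n".join(lines)
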