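"""Vegetation indices (VIs) and per-slice aggregation.

Nine indices over GREEN (G), RED (R), RED_EDGE (RE, ~730 nm) and NIR
(~840 nm) reflectance:

====== =============================== ====================================
name   formula                         reads on
====== =============================== ====================================
NDVI   (NIR - R) / (NIR + R)           vigor / green biomass
GNDVI  (NIR - G) / (NIR + G)           chlorophyll, N & water status
GCI    NIR / G - 1                     canopy chlorophyll content
NDREI  (NIR - RE) / (NIR + RE)         chlorophyll, mid/late season
RECI   NIR / RE - 1                    leaf chlorophyll concentration
NRI    (G - R) / (G + R)               nitrogen reflectance
GI     G / R                           greenness
TCARI  3[(RE-R) - 0.2 (RE-G)(RE/R)]    chlorotic areas
SAVI   (1 + L)(NIR - R)/(NIR + R + L)  soil-adjusted vigor
====== =============================== ====================================

Indices are computed per pixel and aggregated per slice as the mean over
valid pixels. A pixel is invalid when the formula's denominator magnitude
falls below ``epsilon``; invalid pixels are dropped from the mean (not
clamped), and the valid-pixel count travels with every aggregate so the
effect is auditable. With ``use_mask=True`` (default) only canopy pixels
enter the mean; ``use_mask=False`` averages the whole slice.

Class-separation scoring (``separation_report``) replaces a by-eye boxplot
comparison with Cohen's d on per-slice means: an index is selected when
|d| >= ``threshold_d``. NDVI is additionally de-selected whenever SAVI is,
because SAVI is NDVI plus a soil-brightness correction and inherits its
information content.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Mapping

import numpy as np
import pandas as pd

from .raster_io import VI_NAMES, RasterConfigError

if TYPE_CHECKING:  # pragma: no cover
    from .segmentation import SubImage

__all__ = [
    "VIConfig",
    "VIRecord",
    "SeparationReport",
    "compute_vi_pixel",
    "compute_vi_map",
    "compute_vi_slice",
    "compute_all",
    "separation_report",
    "SELECTED_FEATURES",
]

#: Feature subset used by the downstream classifier by default.
SELECTED_FEATURES = ("GNDVI", "GCI", "NDREI", "NRI", "GI")


@dataclass(frozen=True)
class VIConfig:
    """Numerical conventions for VI computation.

    L : SAVI soil-adjustment factor in [0, 1]; 0 recovers NDVI, 1 suits
        sparse canopies, 0.5 is the common default.
    epsilon : denominator guard; |denominator| < epsilon marks the pixel
        invalid for that index.
    tcari_variant : 'standard' uses 3[(RE-R) - 0.2(RE-G)(RE/R)];
        'paper_literal' uses 3[(RE-R) - 0.2(R-G)(RE/R)].
    use_mask : average over canopy pixels only (True) or all pixels.
    """

    L: float = 0.5
    epsilon: float = 1e-9
    tcari_variant: str = "standard"
    use_mask: bool = True

    def __post_init__(self) -> None:
        if not 0.0 <= self.L <= 1.0:
            raise RasterConfigError("SAVI L must lie in [0, 1]")
        if self.epsilon <= 0:
            raise RasterConfigError("epsilon must be > 0")
        if self.tcari_variant not in ("standard", "paper_literal"):
            raise RasterConfigError(f"unknown tcari_variant {self.tcari_variant!r}")


def _guard(num: np.ndarray, den: np.ndarray, eps: float) -> np.ndarray:
    out = np.full(np.broadcast(num, den).shape, np.nan)
    ok = np.abs(den) >= eps
    np.divide(num, den, out=out, where=ok)
    return out


def compute_vi_map(
    name: str,
    g: np.ndarray,
    r: np.ndarray,
    re: np.ndarray,
    n: np.ndarray,
    cfg: VIConfig = VIConfig(),
) -> np.ndarray:
    """Vectorized per-pixel VI; invalid pixels come back as NaN."""
    g, r, re, n = (np.asarray(x, dtype=np.float64) for x in (g, r, re, n))
    eps = cfg.epsilon
    if name == "NDVI":
        return _guard(n - r, n + r, eps)
    if name == "GNDVI":
        return _guard(n - g, n + g, eps)
    if name == "GCI":
        return _guard(n, g, eps) - 1.0
    if name == "NDREI":
        return _guard(n - re, n + re, eps)
    if name == "RECI":
        return _guard(n, re, eps) - 1.0
    if name == "NRI":
        return _guard(g - r, g + r, eps)
    if name == "GI":
        return _guard(g, r, eps)
    if name == "TCARI":
        ratio = _guard(re, r, eps)
        if cfg.tcari_variant == "standard":
            return 3.0 * ((re - r) - 0.2 * (re - g) * ratio)
        return 3.0 * ((re - r) - 0.2 * (r - g) * ratio)
    if name == "SAVI":
        return (1.0 + cfg.L) * _guard(n - r, n + r + cfg.L, eps)
    raise RasterConfigError(f"unknown vegetation index {name!r}")


def compute_vi_pixel(
    name: str, g: float, r: float, re: float, n: float, cfg: VIConfig = VIConfig()
) -> float:
    """Scalar VI for one pixel; NaN when the denominator guard trips."""
    return float(compute_vi_map(name, g, r, re, n, cfg))


def compute_vi_slice(sub: "SubImage", name: str, cfg: VIConfig = VIConfig()) -> tuple[float, int]:
    """Mean VI over a slice's valid (and, by default, canopy) pixels.

    Returns ``(mean, n_valid)``; the mean is NaN when no pixel is valid.
    """
    vi = compute_vi_map(
        name, sub.bands["GREEN"], sub.bands["RED"], sub.bands["RED_EDGE"], sub.bands["NIR"], cfg
    )
    valid = np.isfinite(vi)
    if cfg.use_mask:
        valid &= sub.mask
    n_valid = int(valid.sum())
    if n_valid == 0:
        return float("nan"), 0
    return float(vi[valid].mean()), n_valid


@dataclass
class VIRecord:
    """All nine per-slice VI means with their valid-pixel counts."""

    slice_id: str
    means: dict[str, float]
    n_valid: dict[str, int]
    plant_id: str = ""
    grid_row: int = -1
    grid_col: int = -1
    label: int | None = None

    def as_row(self) -> dict:
        row = {
            "slice_id": self.slice_id,
            "plant_id": self.plant_id,
            "grid_row": self.grid_row,
            "grid_col": self.grid_col,
        }
        row.update({vi.lower(): self.means[vi] for vi in VI_NAMES})
        row["n_valid_min"] = min(self.n_valid.values()) if self.n_valid else 0
        if self.label is not None:
            row["label"] = self.label
        return row


def compute_all(sub: "SubImage", cfg: VIConfig = VIConfig()) -> VIRecord:
    """One :class:`VIRecord` carrying all nine index means for a slice."""
    means: dict[str, float] = {}
    n_valid: dict[str, int] = {}
    for vi in VI_NAMES:
        means[vi], n_valid[vi] = compute_vi_slice(sub, vi, cfg)
    return VIRecord(
        slice_id=sub.slice_id,
        means=means,
        n_valid=n_valid,
        plant_id=str(sub.plant_id),
        grid_row=sub.grid_row,
        grid_col=sub.grid_col,
        label=sub.label,
    )


# -- class separation -----------------------------------------------------


@dataclass
class SeparationReport:
    """Per-VI class separation on slice-level means.

    ``d`` is Cohen's d with pooled standard deviation, signed as
    healthy (label 0) minus unhealthy (label 1). ``selected`` is
    |d| >= threshold, with NDVI forced out whenever SAVI is out.
    """

    threshold_d: float
    stats: pd.DataFrame  # index: VI; columns: d, selected, quartiles per class
    n_healthy: int
    n_unhealthy: int

    @property
    def selected(self) -> list[str]:
        return [vi for vi in self.stats.index if self.stats.loc[vi, "selected"]]

    @property
    def excluded(self) -> list[str]:
        return [vi for vi in self.stats.index if not self.stats.loc[vi, "selected"]]

    def to_dict(self) -> dict:
        return {
            "threshold_d": self.threshold_d,
            "n_healthy": self.n_healthy,
            "n_unhealthy": self.n_unhealthy,
            "selected": self.selected,
            "excluded": self.excluded,
            "stats": self.stats.reset_index().rename(columns={"index": "vi"}).to_dict("records"),
        }


def cohens_d(x0: np.ndarray, x1: np.ndarray) -> float:
    """Standardized mean difference (x0 minus x1) with pooled sd."""
    x0 = np.asarray(x0, dtype=float)
    x1 = np.asarray(x1, dtype=float)
    n0, n1 = len(x0), len(x1)
    v0 = x0.var(ddof=1) if n0 > 1 else 0.0
    v1 = x1.var(ddof=1) if n1 > 1 else 0.0
    pooled = np.sqrt(((n0 - 1) * v0 + (n1 - 1) * v1) / max(n0 + n1 - 2, 1))
    if pooled == 0:
        return 0.0
    return float((x0.mean() - x1.mean()) / pooled)


def separation_report(
    records: list[VIRecord] | pd.DataFrame,
    labels: list[int] | None = None,
    threshold_d: float = 0.5,
) -> SeparationReport:
    """Score each VI's healthy-vs-unhealthy separation and flag selections.

    ``records`` may be a list of :class:`VIRecord` (with ``labels``
    supplied separately or on the records) or a feature DataFrame with
    lower-case VI columns and a ``label`` column.
    """
    if isinstance(records, pd.DataFrame):
        df = records
        lab = np.asarray(df["label"] if labels is None else labels, dtype=int)
    else:
        df = pd.DataFrame([r.as_row() for r in records])
        if labels is None:
            labels = [r.label for r in records]
        lab = np.asarray(labels, dtype=int)
    if len(lab) != len(df):
        raise ValueError("records and labels must have equal length")
    classes = set(lab.tolist())
    if classes != {0, 1}:
        raise ValueError(f"both classes required, got labels {sorted(classes)}")

    rows: dict[str, dict] = {}
    for vi in VI_NAMES:
        col = df[vi.lower()].to_numpy(dtype=float)
        ok = np.isfinite(col)
        x0 = col[ok & (lab == 0)]
        x1 = col[ok & (lab == 1)]
        d = cohens_d(x0, x1)
        q0 = np.percentile(x0, [25, 50, 75])
        q1 = np.percentile(x1, [25, 50, 75])
        rows[vi] = {
            "d": d,
            "selected": bool(abs(d) >= threshold_d),
            "healthy_higher": bool(d > 0),
            "q25_healthy": q0[0],
            "median_healthy": q0[1],
            "q75_healthy": q0[2],
            "q25_unhealthy": q1[0],
            "median_unhealthy": q1[1],
            "q75_unhealthy": q1[2],
        }
    # SAVI is NDVI with a soil-brightness correction; when SAVI carries no
    # class signal, NDVI is deemed unsuitable as well.
    if not rows["SAVI"]["selected"]:
        rows["NDVI"]["selected"] = False
    stats = pd.DataFrame.from_dict(rows, orient="index").loc[list(VI_NAMES)]
    return SeparationReport(
        threshold_d=threshold_d,
        stats=stats,
        n_healthy=int((lab == 0).sum()),
        n_unhealthy=int((lab == 1).sum()),
    )
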