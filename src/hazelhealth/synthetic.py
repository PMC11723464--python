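"""Synthetic multispectral orchard scenes with known ground truth.

Generates per-plant four-band (GREEN, RED, RED_EDGE, NIR) reflectance
images that emulate nadir drone views of a hazelnut orchard: a soil
background (NDVI well below the 0.2 soil cut), a bush-like compound
canopy (union of overlapping discs) of healthy foliage, and — inside
quadrants labeled unhealthy — contiguous stressed patches, mimicking the
localized wilting / branch-collapse symptoms that motivate sub-canopy
labeling. Every image ships with a pixel-level ground-truth class map and
the 3x3 quadrant labels, so each downstream stage can be tested without
field data.

Spectral design. Stress is rendered as chlorophyll loss — GREEN rises and
the red-edge shoulder (RED_EDGE) rises — while RED and NIR (canopy
structure / green biomass) are preserved. Under this regime the
chlorophyll-sensitive indices (GNDVI, GCI, NDREI) and the pigment ratios
(NRI, GI) separate the classes, while the structural indices (NDVI, SAVI)
do not: exactly the behavior expected for a bushy, densely-leaved crop
whose stress shows in pigments before biomass.

Variance model (three nested scales):

* between plants — multiplicative log-normal band factors, shared by all
  pixels of a plant (illumination, phenology, vigor). These dominate the
  slice-level dispersion of every index.
* per pixel — independent Gaussian band noise with per-class, per-band sd.
* contamination — a per-plant random fraction of canopy pixels drawn with
  x3 inflated sd (specular glints, sub-pixel soil/shadow mixing). The
  RED_EDGE band is given a wide base sd, so contaminated pixels regularly
  reach the reflectance floor; ratio indices with RED_EDGE in the
  denominator (RECI) then blow up while bounded normalized indices (NDREI)
  saturate harmlessly — which is what decouples RECI (noisy, unusable)
  from NDREI (informative) even though both are monotone in NIR/RED_EDGE.

Reflectance is clipped to [floor, 1] with a small positive floor
(calibrated reflectance is never exactly zero), which caps the ratio-index
spikes at a finite magnitude.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .raster_io import BandStack, RasterConfigError
from .vegindex import VIConfig, compute_vi_pixel

logger = logging.getLogger(__name__)

__all__ = [
    "SpectralProfile",
    "OrchardScenario",
    "GroundTruth",
    "make_default_profiles",
    "render_plant",
    "iter_dataset",
    "generate_dataset",
    "sample_quadrant_labels",
    "with_noise_level",
    "FIG_RATIO_PREVALENCES",
]

BANDS = ("GREEN", "RED", "RED_EDGE", "NIR")

#: Quadrant prevalences for the three acquisition time points, chosen so the
#: expected healthy:unhealthy ratios are 2.28, 0.92 and 0.39 (p = 1/(1+r)).
FIG_RATIO_PREVALENCES = (1 / 3.28, 1 / 1.92, 1 / 1.39)

# class codes in the ground-truth map
SOIL, HEALTHY, UNHEALTHY = 0, 1, 2


@dataclass(frozen=True)
class SpectralProfile:
    """Mean reflectance and noise scales for one surface class.

    ``contamination_fraction`` is the expected share of pixels drawn with
    x3 inflated noise sd; the realized share varies per plant with a
    heavy-tailed (log-normal) distribution around that expectation.
    """

    name: str
    means: dict[str, float]
    pixel_sd: dict[str, float]
    contamination_fraction: float = 0.05

    def __post_init__(self) -> None:
        if self.name not in ("soil", "healthy", "unhealthy"):
            raise RasterConfigError(f"unknown profile name {self.name!r}")
        for b in BANDS:
            if b not in self.means or b not in self.pixel_sd:
                raise RasterConfigError(f"profile {self.name}: missing band {b}")
            if not 0.0 < self.means[b] < 1.0:
                raise RasterConfigError(f"profile {self.name}: mean {b} outside (0, 1)")
            if self.pixel_sd[b] < 0:
                raise RasterConfigError(f"profile {self.name}: negative sd for {b}")
        if not 0.0 <= self.contamination_fraction <= 0.5:
            raise RasterConfigError("contamination_fraction must lie in [0, 0.5]")
        ndvi = self.ndvi_of_means()
        if self.name == "soil" and not ndvi < 0.2:
            raise RasterConfigError(f"soil profile NDVI {ndvi:.3f} must be < 0.2")
        if self.name != "soil" and not ndvi > 0.3:
            raise RasterConfigError(f"{self.name} profile NDVI {ndvi:.3f} must be > 0.3")

    def vi_of_means(self, vi: str, cfg: VIConfig = VIConfig()) -> float:
        """The index ``vi`` evaluated at this profile's band means."""
        m = self.means
        return compute_vi_pixel(vi, m["GREEN"], m["RED"], m["RED_EDGE"], m["NIR"], cfg)

    def ndvi_of_means(self) -> float:
        return self.vi_of_means("NDVI")


@dataclass(frozen=True)
class OrchardScenario:
    """Geometry, prevalence and variability of a simulated orchard.

    spacing_m, gsd_cm_per_px
        4 m planting grid imaged at 1 cm/px -> 400x400 px per-plant frames.
    canopy_radius_m
        Mean +/- sd of the compound-canopy reach; hazelnuts are bushy and
        nearly fill the planting cell.
    prevalence_unhealthy
        Probability a quadrant is unhealthy; a sequence means one batch per
        acquisition time point.
    single_quadrant_fraction
        Share of plants forced to exactly one unhealthy quadrant (localized
        early symptoms).
    band_factor_sd
        Log-sd of the per-plant multiplicative band factors (between-plant
        biological/illumination variability).
    reflectance_floor
        Lower clip of generated reflectance (> 0; calibrated reflectance
        never reaches exactly zero).
    """

    n_plants: int = 50
    spacing_m: float = 4.0
    gsd_cm_per_px: float = 1.0
    canopy_radius_m: float = 1.7
    canopy_radius_sd_m: float = 0.15
    prevalence_unhealthy: float | Sequence[float] = 0.5
    single_quadrant_fraction: float = 0.1
    patch_fraction: float = 0.6
    band_factor_sd: dict[str, float] = field(
        default_factory=lambda: {"GREEN": 0.04, "RED": 0.04, "RED_EDGE": 0.04, "NIR": 0.06}
    )
    reflectance_floor: float = 0.002
    grid_rows: int = 3
    grid_cols: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_plants <= 0:
            raise RasterConfigError("n_plants must be > 0")
        if min(self.spacing_m, self.gsd_cm_per_px, self.canopy_radius_m) <= 0:
            raise RasterConfigError("spacing, gsd and canopy radius must be > 0")
        for p in self.prevalences:
            if not 0.0 <= p <= 1.0:
                raise RasterConfigError("prevalence must lie in [0, 1]")
        if not 0.0 <= self.single_quadrant_fraction <= 1.0:
            raise RasterConfigError("single_quadrant_fraction must lie in [0, 1]")
        if not 0.0 < self.reflectance_floor < 0.1:
            raise RasterConfigError("reflectance_floor must lie in (0, 0.1)")

    @property
    def prevalences(self) -> tuple[float, ...]:
        p = self.prevalence_unhealthy
        return tuple(p) if isinstance(p, (list, tuple)) else (float(p),)

    @property
    def side_px(self) -> int:
        return int(round(self.spacing_m * 100.0 / self.gsd_cm_per_px))


@dataclass
class GroundTruth:
    """Per-pixel class map and per-quadrant labels for one rendered plant."""

    class_map: np.ndarray  # 0 soil, 1 healthy canopy, 2 unhealthy canopy
    quadrant_labels: np.ndarray  # grid_rows x grid_cols of {0, 1}
    plant_id: str = "plant"
    time_point: int = 0

    @property
    def plant_label(self) -> int:
        return int(self.quadrant_labels.any())

    def __post_init__(self) -> None:
        self.class_map = np.asarray(self.class_map, dtype=np.uint8)
        self.quadrant_labels = np.asarray(self.quadrant_labels, dtype=np.int8)


def make_default_profiles() -> tuple[SpectralProfile, SpectralProfile, SpectralProfile]:
    """Default (soil, healthy, unhealthy) spectral profiles.

    Healthy canopy: dark in the visible, bright NIR (vigorous foliage).
    Unhealthy canopy: chlorophyll loss — GREEN and RED_EDGE rise — with
    RED and NIR unchanged (structure preserved), so chlorophyll-based
    indices separate the classes while NDVI/SAVI carry no class signal.
    Soil: flat, bright visible spectrum, NDVI ~ 0.06.
    """
    canopy_sd = {"GREEN": 0.015, "RED": 0.012, "RED_EDGE": 0.10, "NIR": 0.025}
    soil = SpectralProfile(
        name="soil",
        means={"GREEN": 0.18, "RED": 0.22, "RED_EDGE": 0.24, "NIR": 0.25},
        pixel_sd={b: 0.015 for b in BANDS},
        contamination_fraction=0.0,
    )
    healthy = SpectralProfile(
        name="healthy",
        means={"GREEN": 0.10, "RED": 0.06, "RED_EDGE": 0.30, "NIR": 0.50},
        pixel_sd=dict(canopy_sd),
        contamination_fraction=0.08,
    )
    unhealthy = SpectralProfile(
        name="unhealthy",
        means={"GREEN": 0.15, "RED": 0.06, "RED_EDGE": 0.36, "NIR": 0.50},
        pixel_sd=dict(canopy_sd),
        contamination_fraction=0.08,
    )
    return soil, healthy, unhealthy


def with_noise_level(
    profiles: Sequence[SpectralProfile],
    scenario: OrchardScenario,
    pixel_sd: float,
    baseline_sd: float = 0.04,
) -> tuple[tuple[SpectralProfile, ...], OrchardScenario]:
    """Rescale every stochastic spectral term to a common pixel-noise level.

    Sets all canopy per-band pixel sds to ``pixel_sd`` and scales the
    between-plant band factors proportionally (relative to the nominal
    ``baseline_sd``), so a single knob sweeps the whole noise regime for
    degradation studies.
    """
    scale = pixel_sd / baseline_sd
    out = []
    for p in profiles:
        if p.name == "soil":
            out.append(p)
        else:
            out.append(replace(p, pixel_sd={b: pixel_sd for b in BANDS}))
    scen = replace(
        scenario,
        band_factor_sd={b: s * scale for b, s in scenario.band_factor_sd.items()},
    )
    return tuple(out), scen


# -- rendering ------------------------------------------------------------


def _grid_bounds(dim: int, parts: int) -> list[int]:
    return [(i * dim) // parts for i in range(parts)] + [dim]


def _canopy_shape(scenario: OrchardScenario, rng: np.random.Generator) -> np.ndarray:
    """Bush-like canopy: union of 5-9 overlapping discs near frame center."""
    side = scenario.side_px
    r_px = (
        max(scenario.canopy_radius_m + rng.normal(0.0, scenario.canopy_radius_sd_m), 0.3)
        * 100.0
        / scenario.gsd_cm_per_px
    )
    if r_px > side / 2:
        logger.warning("canopy radius %.0f px exceeds half frame; canopy clipped", r_px)
    center = side / 2.0
    yy, xx = np.mgrid[0:side, 0:side]
    mask = np.zeros((side, side), dtype=bool)
    n_discs = rng.integers(5, 10)
    for _ in range(n_discs):
        ang = rng.uniform(0, 2 * np.pi)
        off = rng.uniform(0.0, 0.70) * r_px
        cy = center + off * np.sin(ang)
        cx = center + off * np.cos(ang)
        rad = rng.uniform(0.50, 0.80) * r_px
        mask |= (yy - cy) ** 2 + (xx - cx) ** 2 <= rad**2
    return mask


def _grow_patch(
    candidate: np.ndarray, fraction: float, rng: np.random.Generator
) -> np.ndarray:
    """Compact connected patch covering ~``fraction`` of candidate pixels."""
    idx = np.argwhere(candidate)
    k = int(round(fraction * len(idx)))
    if k <= 0:
        return np.zeros_like(candidate)
    seed = idx[rng.integers(len(idx))]
    d2 = ((idx - seed) ** 2).sum(axis=1)
    chosen = idx[np.argsort(d2, kind="stable")[:k]]
    patch = np.zeros_like(candidate)
    patch[chosen[:, 0], chosen[:, 1]] = True
    return patch


def render_plant(
    scenario: OrchardScenario,
    quadrant_labels: np.ndarray,
    profiles: Sequence[SpectralProfile] | None = None,
    seed: int = 0,
    plant_id: str = "plant",
    time_point: int = 0,
) -> tuple[BandStack, GroundTruth]:
    """Render one plant image plus its ground truth.

    ``quadrant_labels`` is a grid_rows x grid_cols {0,1} array of intended
    unhealthy quadrants; a labeled quadrant with no canopy pixels is
    demoted to 0 in the returned ground truth (labels always agree with
    rendered pixels). Identical arguments give bit-identical output.
    """
    if profiles is None:
        profiles = make_default_profiles()
    soil, healthy, unhealthy = profiles
    labels = np.asarray(quadrant_labels, dtype=np.int8)
    if labels.shape != (scenario.grid_rows, scenario.grid_cols):
        raise ValueError(f"quadrant_labels must be {scenario.grid_rows}x{scenario.grid_cols}")
    if not np.isin(labels, [0, 1]).all():
        raise ValueError("quadrant labels must be binary")
    rng = np.random.default_rng(seed)
    side = scenario.side_px

    canopy = _canopy_shape(scenario, rng)
    class_map = np.where(canopy, HEALTHY, SOIL).astype(np.uint8)

    rb = _grid_bounds(side, scenario.grid_rows)
    cb = _grid_bounds(side, scenario.grid_cols)
    realized = np.zeros_like(labels)
    for i in range(scenario.grid_rows):
        for j in range(scenario.grid_cols):
            if not labels[i, j]:
                continue
            window = np.zeros((side, side), dtype=bool)
            window[rb[i] : rb[i + 1], cb[j] : cb[j + 1]] = True
            candidate = canopy & window
            frac = np.clip(
                rng.uniform(scenario.patch_fraction - 0.2, scenario.patch_fraction + 0.2),
                0.05,
                1.0,
            )
            patch = _grow_patch(candidate, frac, rng)
            if patch.any():
                class_map[patch] = UNHEALTHY
                realized[i, j] = 1

    # per-plant multiplicative band factors, shared across classes so that
    # within-plant healthy/unhealthy contrast is preserved
    factors = {
        b: float(np.exp(rng.normal(0.0, scenario.band_factor_sd.get(b, 0.0)))) for b in BANDS
    }
    by_class = {SOIL: soil, HEALTHY: healthy, UNHEALTHY: unhealthy}
    bands: dict[str, np.ndarray] = {}
    # contamination: per-plant realized fraction, canopy pixels only
    contam = np.zeros((side, side), dtype=bool)
    canopy_frac = healthy.contamination_fraction
    if canopy_frac > 0:
        # heavy-tailed across plants (log-normal, mean = contamination_fraction):
        # most plants are clean, a few are strongly contaminated, as with
        # glint/shadow episodes in real acquisitions
        c_plant = min(canopy_frac * float(rng.lognormal(-0.5, 1.0)), 0.5)
        contam = canopy & (rng.random((side, side)) < c_plant)
    for b in BANDS:
        img = np.empty((side, side), dtype=np.float64)
        sd = np.empty((side, side), dtype=np.float64)
        for code, prof in by_class.items():
            sel = class_map == code
            img[sel] = prof.means[b] * (factors[b] if code != SOIL else 1.0)
            sd[sel] = prof.pixel_sd[b]
        # contaminated pixels are optical artifacts (glint, shadow holes,
        # sub-pixel mixing): identical on healthy and stressed foliage, so
        # they are drawn around the canopy-wide (healthy) mean with x3 sd,
        # independent of the underlying class
        img[contam] = healthy.means[b] * factors[b]
        sd[contam] = 3.0 * healthy.pixel_sd[b]
        img += rng.normal(0.0, 1.0, size=img.shape) * sd
        np.clip(img, scenario.reflectance_floor, 1.0, out=img)
        bands[b] = img

    stack = BandStack(bands, scenario.gsd_cm_per_px, {"synthetic": True, "plant_id": plant_id})
    truth = GroundTruth(class_map, realized, plant_id=plant_id, time_point=time_point)
    return stack, truth


def _draw_labels(
    scenario: OrchardScenario, prevalence: float, rng: np.random.Generator
) -> np.ndarray:
    shape = (scenario.grid_rows, scenario.grid_cols)
    if rng.random() < scenario.single_quadrant_fraction:
        labels = np.zeros(shape, dtype=np.int8)
        labels[rng.integers(shape[0]), rng.integers(shape[1])] = 1
        return labels
    return (rng.random(shape) < prevalence).astype(np.int8)


def sample_quadrant_labels(scenario: OrchardScenario):
    """Draw the per-plant quadrant-label grids without rendering.

    Yields ``(time_point, plant_id, labels, plant_seed)`` using exactly the
    label stream :func:`iter_dataset` consumes, so sampling statistics can
    be studied at large ``n_plants`` without paying for imagery.
    """
    ss = np.random.SeedSequence(scenario.seed)
    for t, prev in enumerate(scenario.prevalences):
        batch_ss = ss.spawn(1)[0]
        label_rng = np.random.default_rng(batch_ss)
        plant_seeds = batch_ss.generate_state(scenario.n_plants)
        for i in range(scenario.n_plants):
            labels = _draw_labels(scenario, prev, label_rng)
            yield t, f"t{t}_p{i:04d}", labels, int(plant_seeds[i])


def iter_dataset(
    scenario: OrchardScenario,
    profiles: Sequence[SpectralProfile] | None = None,
):
    """Lazily render a whole orchard dataset: ``n_plants`` per prevalence
    batch.

    Quadrant labels are i.i.d. Bernoulli(prevalence), except for the
    ``single_quadrant_fraction`` of plants that get exactly one unhealthy
    quadrant at a uniform position. Multi-time scenarios (a sequence of
    prevalences) concatenate one batch per time point. Fully reproducible
    from ``scenario.seed``.
    """
    if profiles is None:
        profiles = make_default_profiles()
    for t, plant_id, labels, plant_seed in sample_quadrant_labels(scenario):
        yield render_plant(
            scenario, labels, profiles, seed=plant_seed, plant_id=plant_id, time_point=t
        )


def generate_dataset(
    scenario: OrchardScenario,
    profiles: Sequence[SpectralProfile] | None = None,
) -> list[tuple[BandStack, GroundTruth]]:
    """Eager counterpart of :func:`iter_dataset` (see there for semantics).

    Prefer :func:`iter_dataset` for large orchards: a rendered plant is
    ~5 MB, so hundreds of plants held at once add up.
    """
    return list(iter_dataset(scenario, profiles))
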