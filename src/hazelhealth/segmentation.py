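"""Canopy segmentation and 3x3 slicing of per-plant images.

The segmentation path: per-pixel NDVI, soil exclusion at a threshold
(pixels with NDVI below 0.2 are soil), then a contour-hierarchy cleanup
that removes any contour strictly contained inside another and fills the
retained outer contours — leaving a union of solid canopy components.
For scenes where canopies overlap, a purely geometric crop centered on
the trunk (side = planting spacing) is available instead.

Each plant image is then partitioned into an exact grid (3x3 by default,
~1.78 m^2 per cell at 4 m spacing and 1 cm/px) and cells that are mostly
soil are dropped before any index statistics are computed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .raster_io import BandStack, RasterConfigError
from .vegindex import VIConfig, compute_vi_map

logger = logging.getLogger(__name__)

__all__ = [
    "SegmentationConfig",
    "CanopyMask",
    "SubImage",
    "geometric_crop",
    "ndvi_map",
    "soil_mask",
    "hierarchical_filter",
    "slice_grid",
    "drop_soil_slices",
    "segment_plant",
]


@dataclass(frozen=True)
class SegmentationConfig:
    """Knobs of the segmentation stage.

    ndvi_threshold : soil cut; pixels with NDVI strictly below it are
        excluded (a pixel exactly at the threshold is canopy).
    min_canopy_fraction : a slice with canopy fraction below this is
        considered "mostly soil" and dropped.
    connectivity : pixel connectivity (4 or 8) for contour components.
    grid_rows, grid_cols : slicing grid (3x3 default).
    """

    ndvi_threshold: float = 0.2
    min_canopy_fraction: float = 0.5
    connectivity: int = 8
    grid_rows: int = 3
    grid_cols: int = 3

    def __post_init__(self) -> None:
        if not 0.0 <= self.ndvi_threshold <= 1.0:
            raise RasterConfigError("ndvi_threshold must lie in [0, 1]")
        if not 0.0 <= self.min_canopy_fraction <= 1.0:
            raise RasterConfigError("min_canopy_fraction must lie in [0, 1]")
        if self.connectivity not in (4, 8):
            raise RasterConfigError("connectivity must be 4 or 8")
        if self.grid_rows < 1 or self.grid_cols < 1:
            raise RasterConfigError("grid dimensions must be >= 1")


@dataclass
class CanopyMask:
    """Boolean canopy map (True = canopy) for one plant image."""

    mask: np.ndarray

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)

    @property
    def canopy_fraction(self) -> float:
        return float(self.mask.mean()) if self.mask.size else 0.0

    @property
    def shape(self) -> tuple[int, int]:
        return self.mask.shape


@dataclass
class SubImage:
    """One cell of the slicing grid, with its band data and mask restriction.

    ``window`` is the half-open (r0, r1, c0, c1) pixel window in the parent
    frame; ``label`` is 0 (healthy), 1 (unhealthy) or None (unknown).
    """

    plant_id: str
    grid_row: int
    grid_col: int
    window: tuple[int, int, int, int]
    bands: dict[str, np.ndarray]
    mask: np.ndarray
    label: int | None = None

    @property
    def slice_id(self) -> str:
        return f"{self.plant_id}_r{self.grid_row}c{self.grid_col}"

    @property
    def canopy_fraction(self) -> float:
        return float(self.mask.mean()) if self.mask.size else 0.0

    @property
    def shape(self) -> tuple[int, int]:
        return self.mask.shape


def geometric_crop(scene: BandStack, trunk_rc: tuple[int, int], spacing_m: float) -> BandStack:
    """Square crop of side ``spacing_m`` centered on the trunk pixel.

    The crop side is ``round(spacing_m * 100 / gsd_cm_per_px)`` pixels
    (400 px for 4 m spacing at 1 cm/px). Area falling outside the scene is
    zero-padded with a warning.
    """
    r, c = trunk_rc
    H, W = scene.shape
    if not (0 <= r < H and 0 <= c < W):
        raise ValueError(f"trunk {trunk_rc} outside scene of shape {scene.shape}")
    side = int(round(spacing_m * 100.0 / scene.gsd_cm_per_px))
    r0 = r - side // 2
    c0 = c - side // 2
    r1, c1 = r0 + side, c0 + side
    out = {b: np.zeros((side, side), dtype=np.float64) for b in scene.bands}
    sr0, sc0 = max(r0, 0), max(c0, 0)
    sr1, sc1 = min(r1, H), min(c1, W)
    if (sr0, sc0, sr1, sc1) != (r0, c0, r1, c1):
        logger.warning("geometric_crop: crop extends outside scene; zero-padding margin")
    for b, arr in scene.bands.items():
        out[b][sr0 - r0 : sr1 - r0, sc0 - c0 : sc1 - c0] = arr[sr0:sr1, sc0:sc1]
    return BandStack(out, scene.gsd_cm_per_px, dict(scene.provenance))


def ndvi_map(stack: BandStack, epsilon: float = 1e-9) -> np.ndarray:
    """Per-pixel NDVI in [-1, 1]; NaN where NIR+RED is below the guard."""
    return compute_vi_map(
        "NDVI",
        stack.bands["GREEN"],
        stack.bands["RED"],
        stack.bands["RED_EDGE"],
        stack.bands["NIR"],
        VIConfig(epsilon=epsilon),
    )


def soil_mask(ndvi: np.ndarray, cfg: SegmentationConfig = SegmentationConfig()) -> CanopyMask:
    """Canopy = valid pixels with NDVI >= threshold (soil is strictly below)."""
    ndvi = np.asarray(ndvi, dtype=float)
    mask = np.isfinite(ndvi) & (ndvi >= cfg.ndvi_threshold)
    return CanopyMask(mask)


def _structure(connectivity: int) -> np.ndarray:
    return ndimage.generate_binary_structure(2, 2 if connectivity == 8 else 1)


def hierarchical_filter(
    cmask: CanopyMask, cfg: SegmentationConfig = SegmentationConfig()
) -> CanopyMask:
    """Drop contours contained in larger ones and fill the outer contours.

    On a binary mask this is exactly hole filling of the outer connected
    components: a contour strictly inside another is either a hole border
    or an island inside a hole, and both disappear when the enclosing
    component is filled. Idempotent by construction.
    """
    mask = cmask.mask
    if not mask.any():
        logger.warning("hierarchical_filter: empty canopy mask")
        return CanopyMask(mask.copy())
    # Foreground connectivity cfg.connectivity; holes are filled with the
    # dual connectivity for the background so 8-connected outlines hold.
    bg_structure = _structure(4 if cfg.connectivity == 8 else 8)
    filled = ndimage.binary_fill_holes(mask, structure=bg_structure)
    return CanopyMask(filled)


def _boundaries(dim: int, parts: int) -> list[int]:
    return [(i * dim) // parts for i in range(parts)] + [dim]


def slice_grid(
    plant: BandStack,
    cmask: CanopyMask,
    cfg: SegmentationConfig = SegmentationConfig(),
    plant_id: str = "plant",
    quadrant_labels: np.ndarray | None = None,
) -> list[SubImage]:
    """Partition a plant image into an exact grid of sub-images.

    Row boundaries sit at ``floor(i * H / grid_rows)`` (columns likewise),
    so the windows tile the frame exactly and cell sides differ by at most
    one pixel. Slices come back in row-major order. ``quadrant_labels``
    (grid_rows x grid_cols of {0,1}) attaches per-slice labels when known.
    """
    if cmask.shape != plant.shape:
        raise ValueError("mask shape does not match plant image shape")
    H, W = plant.shape
    if H < cfg.grid_rows or W < cfg.grid_cols:
        raise ValueError(f"image {H}x{W} smaller than {cfg.grid_rows}x{cfg.grid_cols} grid")
    rb = _boundaries(H, cfg.grid_rows)
    cb = _boundaries(W, cfg.grid_cols)
    slices: list[SubImage] = []
    for i in range(cfg.grid_rows):
        for j in range(cfg.grid_cols):
            r0, r1, c0, c1 = rb[i], rb[i + 1], cb[j], cb[j + 1]
            label = None
            if quadrant_labels is not None:
                label = int(quadrant_labels[i, j])
            slices.append(
                SubImage(
                    plant_id=str(plant_id),
                    grid_row=i,
                    grid_col=j,
                    window=(r0, r1, c0, c1),
                    bands={b: a[r0:r1, c0:c1] for b, a in plant.bands.items()},
                    mask=cmask.mask[r0:r1, c0:c1],
                    label=label,
                )
            )
    return slices


def drop_soil_slices(
    slices: list[SubImage], cfg: SegmentationConfig = SegmentationConfig()
) -> list[SubImage]:
    """Retain slices whose canopy fraction is >= ``min_canopy_fraction``."""
    kept = [s for s in slices if s.canopy_fraction >= cfg.min_canopy_fraction]
    if len(kept) != len(slices):
        logger.info("drop_soil_slices: dropped %d of %d slices as mostly soil",
                    len(slices) - len(kept), len(slices))
    return kept


def segment_plant(
    plant: BandStack,
    cfg: SegmentationConfig = SegmentationConfig(),
    plant_id: str = "plant",
    quadrant_labels: np.ndarray | None = None,
) -> tuple[CanopyMask, list[SubImage], list[SubImage]]:
    """Full per-plant path: NDVI mask -> contour filter -> grid -> soil drop.

    Returns ``(mask, all_slices, kept_slices)``.
    """
    mask = soil_mask(ndvi_map(plant), cfg)
    mask = hierarchical_filter(mask, cfg)
    slices = slice_grid(plant, mask, cfg, plant_id=plant_id, quadrant_labels=quadrant_labels)
    kept = drop_soil_slices(slices, cfg)
    return mask, slices, kept
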