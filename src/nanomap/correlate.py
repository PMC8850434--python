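"""Spot-centric two-channel correlation analysis.

The procedure quantifies the spatial association of a protein of interest
with clathrin-coated structures: clathrin puncta are detected as local
maxima in one channel, a small square region around each punctum is cropped
at identical coordinates from both channels, and the Pearson correlation of
the paired pixel intensities is computed per spot.  An equal number of
randomly positioned regions provides a null for nonspecific colocalization.
Cells are the unit of aggregation; condition summaries average per-cell
means and report pairwise fold changes.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .morphometry import round_sig
from .types import ImageChannel, SpotSet

__all__ = [
    "CorrelationParams",
    "RegionPair",
    "CorrelationResult",
    "RegionOutOfBoundsError",
    "ZeroVarianceError",
    "detect_spots",
    "extract_region_pair",
    "random_region_set",
    "pearson_r",
    "cell_correlation",
    "condition_summary",
]

logger = logging.getLogger(__name__)


class RegionOutOfBoundsError(ValueError):
    """Requested analysis region crosses the image border."""


class ZeroVarianceError(ValueError):
    """A region has zero intensity variance; Pearson r is undefined."""


@dataclass(frozen=True)
class CorrelationParams:
    """Tunable parameters of the correlation analysis.

    ``threshold`` is interpreted per ``threshold_mode``: ``"fraction"``
    (default) places it on the robust intensity range of the masked image
    (1st to 99.9th percentile), ``"absolute"`` uses raw image units.  Spots
    closer than ``edge_exclusion_um`` (default 2 um) to the mask boundary
    are rejected; analysis regions are squares of side ``region_size_um``
    (default 4 um), forced to an odd pixel count so the center pixel is
    unique.
    """

    threshold: float = 0.2
    threshold_mode: str = "fraction"
    edge_exclusion_um: float = 2.0
    region_size_um: float = 4.0
    min_peak_sep_um: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.edge_exclusion_um < 0:
            raise ValueError("edge_exclusion_um must be >= 0")
        if self.region_size_um <= 0:
            raise ValueError("region_size_um must be positive")
        if self.threshold_mode not in ("fraction", "absolute"):
            raise ValueError("threshold_mode must be 'fraction' or 'absolute'")
        if self.min_peak_sep_um < 0:
            raise ValueError("min_peak_sep_um must be >= 0")

    def region_side_px(self, pixel_size_um: float) -> int:
        """Odd pixel side of the analysis square (rounded, then up to odd)."""
        side = int(round(self.region_size_um / pixel_size_um))
        if side % 2 == 0:
            side += 1
        if side < 3:
            raise ValueError("region side must be >= 3 px; increase region_size_um")
        return side


@dataclass
class RegionPair:
    """Matched crops from the two channels at identical coordinates."""

    region_A: np.ndarray
    region_B: np.ndarray
    center_px: tuple[int, int]
    kind: str = "spot"  # "spot" | "null"

    def __post_init__(self) -> None:
        if self.region_A.shape != self.region_B.shape:
            raise ValueError("region shapes must match")


@dataclass
class CorrelationResult:
    """Per-cell spot-wise Pearson statistics (the per-cell 'C')."""

    per_spot_r: np.ndarray
    null_per_region_r: np.ndarray
    cell_id: str = ""
    condition: str = ""
    n_excluded_border: int = 0
    n_excluded_zero_variance: int = 0
    spot_centers: np.ndarray = field(default_factory=lambda: np.empty((0, 2), dtype=int))
    null_centers: np.ndarray = field(default_factory=lambda: np.empty((0, 2), dtype=int))

    @property
    def n_spots(self) -> int:
        return len(self.per_spot_r)

    @property
    def mean_r(self) -> float:
        return float(np.mean(self.per_spot_r)) if self.n_spots else math.nan

    @property
    def null_mean_r(self) -> float:
        return float(np.mean(self.null_per_region_r)) if len(self.null_per_region_r) else math.nan

    @property
    def empty(self) -> bool:
        return self.n_spots == 0


# ---------------------------------------------------------------------------
# detection
# ---------------------------------------------------------------------------


def _edge_distance_um(mask: np.ndarray, pixel_size_um: float) -> np.ndarray:
    """Distance to the cell boundary; the image frame counts as boundary."""
    padded = np.pad(mask, 1, constant_values=False)
    return ndimage.distance_transform_edt(padded)[1:-1, 1:-1] * pixel_size_um


def _resolve_threshold(image: np.ndarray, mask: np.ndarray, params: CorrelationParams) -> float:
    if params.threshold_mode == "absolute":
        return float(params.threshold)
    lo, hi = np.percentile(image[mask], [1.0, 99.9])
    return float(lo + params.threshold * (hi - lo))


def detect_spots(
    image: ImageChannel | np.ndarray,
    mask: np.ndarray,
    params: CorrelationParams,
    pixel_size_um: float | None = None,
) -> SpotSet:
    """Detect punctum peaks: thresholded local maxima away from the cell edge.

    A local maximum is a pixel strictly greater than its 8-neighborhood;
    intensity plateaus are broken by the lowest row-major index.  Accepted
    maxima exceed the resolved threshold, lie at least ``edge_exclusion_um``
    from the mask boundary (Euclidean distance transform), and are mutually
    separated by ``min_peak_sep_um`` (the brighter of a close pair wins).
    Results are sorted by descending peak intensity.
    """
    if isinstance(image, ImageChannel):
        pixel_size_um = image.pixel_size_um
        image = image.data
    if pixel_size_um is None:
        raise ValueError("pixel_size_um is required when image is a bare array")
    mask = np.asarray(mask, dtype=bool)
    if image.shape != mask.shape:
        raise ValueError("image and mask must share a grid")
    if not mask.any():
        raise ValueError("mask is empty")

    thr = _resolve_threshold(image, mask, params)

    footprint = np.ones((3, 3), dtype=bool)
    footprint[1, 1] = False
    neighbor_max = ndimage.maximum_filter(image, footprint=footprint, mode="nearest")
    candidate = image >= neighbor_max  # >= keeps plateaus for the tie-break below

    # plateau tie-break: one peak per connected candidate component, at the
    # lowest row-major index
    labels, n_comp = ndimage.label(candidate, structure=np.ones((3, 3), int))
    peaks: list[tuple[int, int]] = []
    if n_comp:
        flat_idx = np.arange(image.size).reshape(image.shape)
        first = ndimage.minimum(flat_idx, labels, index=np.arange(1, n_comp + 1))
        rows, cols = np.unravel_index(np.asarray(first, dtype=int), image.shape)
        peaks = list(zip(rows, cols))

    dist_um = _edge_distance_um(mask, pixel_size_um)
    kept = [
        (r, c)
        for r, c in peaks
        if mask[r, c] and image[r, c] > thr and dist_um[r, c] >= params.edge_exclusion_um
    ]
    if not kept:
        return SpotSet(np.empty((0, 2)), np.empty(0))

    coords = np.asarray(kept, dtype=float)
    intens = image[tuple(np.asarray(kept).T)]
    order = np.argsort(-intens, kind="stable")
    coords, intens = coords[order], intens[order]

    # greedy minimum-separation filter: brightest first
    min_sep_px = params.min_peak_sep_um / pixel_size_um
    accepted_idx: list[int] = []
    for i in range(len(coords)):
        if accepted_idx:
            d = np.linalg.norm(coords[accepted_idx] - coords[i], axis=1)
            if d.min() < min_sep_px:
                continue
        accepted_idx.append(i)
    return SpotSet(coords[accepted_idx], intens[accepted_idx])


# ---------------------------------------------------------------------------
# region extraction and correlation
# ---------------------------------------------------------------------------


def extract_region_pair(
    image_A: np.ndarray,
    image_B: np.ndarray,
    center_px: tuple[int, int],
    params: CorrelationParams,
    pixel_size_um: float,
    kind: str = "spot",
) -> RegionPair:
    """Crop matched square regions around ``center_px`` from both channels.

    Raises :class:`RegionOutOfBoundsError` if the square crosses the image
    border — callers exclude such spots with a logged reason rather than
    silently truncating the crop.
    """
    if image_A.shape != image_B.shape:
        raise ValueError("channel shapes must match")
    side = params.region_side_px(pixel_size_um)
    half = side // 2
    r, c = int(center_px[0]), int(center_px[1])
    h, w = image_A.shape
    if r - half < 0 or c - half < 0 or r + half + 1 > h or c + half + 1 > w:
        raise RegionOutOfBoundsError(
            f"region of side {side} at ({r}, {c}) crosses the border of {image_A.shape}"
        )
    sl = (slice(r - half, r + half + 1), slice(c - half, c + half + 1))
    return RegionPair(image_A[sl].copy(), image_B[sl].copy(), (r, c), kind=kind)


def pearson_r(region_A: np.ndarray, region_B: np.ndarray) -> float:
    """Product-moment correlation of the flattened pixel intensities."""
    a = np.asarray(region_A, dtype=float).ravel()
    b = np.asarray(region_B, dtype=float).ravel()
    if a.shape != b.shape:
        raise ValueError("regions must have equal shapes")
    da = a - a.mean()
    db = b - b.mean()
    va = float(da @ da)
    vb = float(db @ db)
    if va == 0.0 or vb == 0.0:
        raise ZeroVarianceError("a region has zero intensity variance")
    r = float(da @ db) / math.sqrt(va * vb)
    return float(min(1.0, max(-1.0, r)))


def random_region_set(
    image_A: np.ndarray,
    image_B: np.ndarray,
    mask: np.ndarray,
    n: int,
    params: CorrelationParams,
    pixel_size_um: float,
    seed: int | None = None,
) -> list[RegionPair]:
    """Extract ``n`` region pairs at uniformly random valid centers.

    Valid centers lie inside the mask, at least ``edge_exclusion_um`` from
    its boundary, and far enough from the image border for a full crop.
    Null regions may overlap each other and spot regions.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    mask = np.asarray(mask, dtype=bool)
    side = params.region_side_px(pixel_size_um)
    half = side // 2
    h, w = image_A.shape

    dist_um = _edge_distance_um(mask, pixel_size_um)
    valid = dist_um >= params.edge_exclusion_um
    valid[:half, :] = valid[h - half :, :] = False
    valid[:, :half] = valid[:, w - half :] = False
    centers = np.argwhere(valid)
    if len(centers) == 0:
        raise ValueError("no valid center for null regions")

    rng = np.random.default_rng(params.seed if seed is None else seed)
    idx = rng.choice(len(centers), size=n, replace=len(centers) < n)
    return [
        extract_region_pair(image_A, image_B, tuple(centers[i]), params, pixel_size_um, kind="null")
        for i in idx
    ]


def cell_correlation(
    image_A: ImageChannel | np.ndarray,
    image_B: ImageChannel | np.ndarray,
    mask: np.ndarray,
    params: CorrelationParams,
    pixel_size_um: float | None = None,
    cell_id: str = "",
    condition: str = "",
) -> CorrelationResult:
    """Full per-cell analysis: detect, extract, correlate, and build the null.

    Spots whose region crosses the border and regions with zero variance are
    dropped and tallied, never imputed.  The null uses as many random
    regions as accepted spots.
    """
    if isinstance(image_A, ImageChannel):
        pixel_size_um = image_A.pixel_size_um
        image_A = image_A.data
    if isinstance(image_B, ImageChannel):
        image_B = image_B.data
    if pixel_size_um is None:
        raise ValueError("pixel_size_um is required when images are bare arrays")

    spots = detect_spots(image_A, mask, params, pixel_size_um)
    per_spot: list[float] = []
    centers: list[tuple[int, int]] = []
    n_border = 0
    n_zero = 0
    for (r, c), _ in spots:
        try:
            pair = extract_region_pair(
                image_A, image_B, (int(round(r)), int(round(c))), params, pixel_size_um
            )
            per_spot.append(pearson_r(pair.region_A, pair.region_B))
            centers.append(pair.center_px)
        except RegionOutOfBoundsError:
            n_border += 1
            logger.debug("spot at (%d, %d) excluded: region crosses border", int(r), int(c))
        except ZeroVarianceError:
            n_zero += 1

    null_r: list[float] = []
    null_centers: list[tuple[int, int]] = []
    if per_spot:
        for pair in random_region_set(
            image_A, image_B, mask, len(per_spot), params, pixel_size_um, seed=params.seed
        ):
            try:
                null_r.append(pearson_r(pair.region_A, pair.region_B))
                null_centers.append(pair.center_px)
            except ZeroVarianceError:
                n_zero += 1

    result = CorrelationResult(
        per_spot_r=np.asarray(per_spot),
        null_per_region_r=np.asarray(null_r),
        cell_id=cell_id,
        condition=condition,
        n_excluded_border=n_border,
        n_excluded_zero_variance=n_zero,
        spot_centers=np.asarray(centers, dtype=int).reshape(-1, 2),
        null_centers=np.asarray(null_centers, dtype=int).reshape(-1, 2),
    )
    if result.empty:
        logger.warning("cell %s: zero usable spots", cell_id or "<unnamed>")
    return result


# ---------------------------------------------------------------------------
# condition-level aggregation
# ---------------------------------------------------------------------------


def condition_summary(
    results: list[CorrelationResult],
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Aggregate per-cell results into per-condition statistics.

    The cell is the analysis unit: each condition reports mean +/- SD of the
    per-cell ``mean_r`` along with cell/spot tallies, plus a pooled-spot
    mean for transparency.  All pairwise fold changes of condition means are
    returned as ``"A_vs_B" -> ratio`` (2 significant figures).

    Empty cells (no usable spots) are excluded from summaries.
    """
    usable = [r for r in results if not r.empty]
    if not usable:
        raise ValueError("no non-empty CorrelationResult to summarize")
    by_cond: dict[str, list[CorrelationResult]] = {}
    for r in usable:
        by_cond.setdefault(r.condition, []).append(r)

    rows = []
    for cond, items in by_cond.items():
        cell_means = np.array([r.mean_r for r in items])
        pooled = np.concatenate([r.per_spot_r for r in items])
        null_pooled = np.concatenate(
            [r.null_per_region_r for r in items if len(r.null_per_region_r)]
        )
        rows.append(
            {
                "condition": cond,
                "n_cells": len(items),
                "n_spots": int(sum(r.n_spots for r in items)),
                "mean_r": float(cell_means.mean()),
                "sd_r": float(cell_means.std(ddof=1)) if len(cell_means) > 1 else math.nan,
                "pooled_mean_r": float(pooled.mean()),
                "null_mean_r": float(null_pooled.mean()) if len(null_pooled) else math.nan,
            }
        )
    table = pd.DataFrame(rows).set_index("condition")

    folds: dict[str, float] = {}
    conds = list(table.index)
    for a in conds:
        for b in conds:
            if a == b:
                continue
            denom = table.loc[b, "mean_r"]
            if denom == 0:
                raise ZeroDivisionError(f"condition {b!r} has zero mean_r; fold change undefined")
            folds[f"{a}_vs_{b}"] = round_sig(table.loc[a, "mean_r"] / denom, 2)
    return table, folds
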