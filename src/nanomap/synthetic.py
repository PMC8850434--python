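"""Seeded generators for every input the pipeline consumes.

The generators emulate the three imaging regimes the analysis stages expect:

* two-channel TIRF fields of diffraction-limited puncta with a controllable
  colocalized fraction and amplitude correlation over a smooth background
  with detector (shot + read) noise;
* labeled platinum-replica-style segmentation masks with curvature classes
  (flat / dome / sphere) whose per-class area distributions are set on the
  nm² scale of real lattices;
* IRM-like montage stacks sharing a smooth field-background pattern with
  tile-specific adhesion signal.

Every generator is a pure function of its configuration including the seed,
and records ground truth so downstream stages can be validated pixel-by-pixel.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import ndimage

from .types import ImageChannel, SpotSet

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "ClassParams",
    "StructureSimConfig",
    "IRMStackTruth",
    "make_cell_mask",
    "sample_truth_spots",
    "render_channel_pair",
    "make_structure_mask",
    "make_irm_stack",
    "STRUCTURE_LABELS",
]

logger = logging.getLogger(__name__)

#: Reserved labels of curvature-class segmentation masks.
STRUCTURE_LABELS = {"background": 0, "membrane": 1, "flat": 2, "dome": 3, "sphere": 4}


# ---------------------------------------------------------------------------
# configuration containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of a two-channel TIRF punctum simulation.

    Defaults emulate a 100x/1.45 NA EMCCD acquisition: 0.107 um pixels and a
    PSF sigma of ~0.11 um (diffraction-limited green emission).  Amplitudes
    are lognormal; shared puncta couple their log-amplitudes through a
    bivariate normal with correlation ``amp_corr``.
    """

    image_shape_px: tuple[int, int] = (512, 512)
    pixel_size_um: float = 0.107
    n_spots: int = 200
    coloc_fraction: float = 0.5
    amp_corr: float = 0.8
    psf_sigma_um: float = 0.11
    background_level: float = 100.0
    read_noise_sd: float = 2.0
    shot_noise: bool = True
    min_sep_um: float = 0.5
    edge_margin_um: float = 2.0
    amp_median: float = 400.0
    amp_log_sd: float = 0.35
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.coloc_fraction <= 1.0:
            raise ValueError("coloc_fraction must lie in [0, 1]")
        if not -1.0 <= self.amp_corr <= 1.0:
            raise ValueError("amp_corr must lie in [-1, 1]")
        if self.psf_sigma_um <= 0:
            raise ValueError("psf_sigma_um must be positive")
        if self.min_sep_um < 0:
            raise ValueError("min_sep_um must be non-negative")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        if self.n_spots < 0:
            raise ValueError("n_spots must be non-negative")


@dataclass
class GroundTruth:
    """Bookkeeping of what was rendered into a channel pair."""

    spots_A: SpotSet
    spots_B: SpotSet
    shared_index_pairs: list[tuple[int, int]]

    @property
    def n_shared(self) -> int:
        return len(self.shared_index_pairs)


@dataclass(frozen=True)
class ClassParams:
    """Lognormal size model of one curvature class.

    ``mean_area_nm2`` is the arithmetic mean of the class area distribution;
    with log-standard-deviation ``s`` the underlying normal has
    ``mu = ln(mean) - s^2 / 2`` so samples average to the target.
    """

    count: int
    mean_area_nm2: float
    log_sd: float = 0.35

    def __post_init__(self) -> None:
        if self.count < 0:
            raise ValueError("structure count must be >= 0")
        if self.count and self.mean_area_nm2 <= 0:
            raise ValueError("mean_area_nm2 must be positive")
        if self.log_sd < 0:
            raise ValueError("log_sd must be >= 0")


@dataclass(frozen=True)
class StructureSimConfig:
    """Parameters of a curvature-class segmentation-mask simulation.

    Class size defaults follow measured clathrin lattices: domes average
    ~21,994 nm^2 and spheres ~11,075 nm^2; flat lattices in resting cells
    run near 29,000 nm^2.  The default scale is 1.2 nm per pixel (15,000x
    replica EM magnification).
    """

    membrane_area_px: int = 12_000_000
    flat: ClassParams = field(default_factory=lambda: ClassParams(5, 29_000.0))
    dome: ClassParams = field(default_factory=lambda: ClassParams(3, 21_993.9))
    sphere: ClassParams = field(default_factory=lambda: ClassParams(3, 11_075.2))
    nm_per_px: float = 1.2
    max_retries: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.nm_per_px <= 0:
            raise ValueError("nm_per_px must be positive")
        if self.membrane_area_px <= 0:
            raise ValueError("membrane_area_px must be positive")


class IRMStackTruth(NamedTuple):
    """IRM montage stack with the ground truth used to build it."""

    stack: np.ndarray
    field_pattern: np.ndarray
    offset: float
    spot_table: pd.DataFrame


# ---------------------------------------------------------------------------
# cell masks and punctum positions
# ---------------------------------------------------------------------------


def make_cell_mask(
    shape_px: tuple[int, int],
    coverage_fraction: float = 0.85,
    irregularity: float = 0.15,
    seed: int = 0,
) -> np.ndarray:
    """Generate a single connected blobby cell footprint.

    The outline is a star-convex polygon: a base radius modulated by a few
    random Fourier modes whose relative amplitude is ``irregularity``.  The
    base radius is corrected iteratively so the filled pixel fraction lands
    near ``coverage_fraction``.

    Parameters
    ----------
    shape_px:
        ``(rows, cols)`` of the output mask.
    coverage_fraction:
        Target fraction of frame pixels inside the cell, in ``(0, 1]``.
    irregularity:
        Relative amplitude of the boundary modulation; 0 gives a smooth
        ellipse-like outline.
    seed:
        RNG seed; identical seeds give bitwise-identical masks.
    """
    if not 0.0 < coverage_fraction <= 1.0:
        raise ValueError("coverage_fraction must lie in (0, 1]")
    if irregularity < 0:
        raise ValueError("irregularity must be >= 0")
    h, w = int(shape_px[0]), int(shape_px[1])
    if coverage_fraction == 1.0 and irregularity == 0.0:
        return np.ones((h, w), dtype=bool)

    rng = np.random.default_rng(seed)
    n_modes = 6
    phases = rng.uniform(0, 2 * np.pi, n_modes)
    # decaying mode amplitudes keep the outline smooth at small scales
    amps = rng.uniform(0.3, 1.0, n_modes) / (1.0 + np.arange(n_modes))
    amps *= irregularity / max(amps.sum(), 1e-12)

    rr, cc = np.mgrid[0:h, 0:w]
    dy = (rr - (h - 1) / 2.0) / (h / 2.0)
    dx = (cc - (w - 1) / 2.0) / (w / 2.0)
    rho = np.hypot(dy, dx)
    theta = np.arctan2(dy, dx)
    modulation = np.ones_like(theta)
    for k in range(n_modes):
        modulation += amps[k] * np.cos((k + 2) * theta + phases[k])

    base = math.sqrt(coverage_fraction)
    mask = np.zeros((h, w), dtype=bool)
    for _ in range(8):  # radius correction toward the coverage target
        mask = rho <= base * modulation
        measured = mask.mean()
        if measured <= 0:
            base *= 1.5
            continue
        ratio = coverage_fraction / measured
        if abs(ratio - 1.0) < 0.02:
            break
        base *= math.sqrt(min(max(ratio, 0.5), 2.0))

    # keep the largest connected component only
    labels, n = ndimage.label(mask)
    if n > 1:
        sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
        mask = labels == (1 + int(np.argmax(sizes)))
    if not mask.any():
        raise RuntimeError("cell mask generation produced an empty mask")
    return mask


def sample_truth_spots(
    mask: np.ndarray,
    n: int,
    min_sep_um: float,
    edge_margin_um: float,
    pixel_size_um: float,
    seed: int = 0,
    max_passes: int = 20,
) -> SpotSet:
    """Sample ``n`` punctum centers inside a mask with hard-core separation.

    Positions are drawn by dart throwing over the mask eroded by
    ``edge_margin_um`` (Euclidean distance transform), with sub-pixel jitter,
    rejecting candidates closer than ``min_sep_um`` to an accepted point.

    Raises
    ------
    RuntimeError
        If the packing is infeasible after ``max_passes`` sweeps over the
        candidate pixels; the message names the number achieved.
    """
    if n == 0:
        return SpotSet(np.empty((0, 2)), np.empty(0))
    # the image frame counts as boundary so puncta render fully inside
    dist = ndimage.distance_transform_edt(np.pad(mask, 1, constant_values=False))[1:-1, 1:-1]
    dist = dist * pixel_size_um
    valid = np.argwhere(dist >= max(edge_margin_um, pixel_size_um * 0.5))
    if len(valid) == 0:
        raise ValueError("mask is empty after erosion by edge_margin_um")

    rng = np.random.default_rng(seed)
    min_sep_px = min_sep_um / pixel_size_um
    accepted: list[np.ndarray] = []
    for _ in range(max_passes):
        order = rng.permutation(len(valid))
        for idx in order:
            if len(accepted) >= n:
                break
            cand = valid[idx] + rng.uniform(-0.5, 0.5, size=2)
            cand = np.clip(cand, 0.0, np.asarray(mask.shape, dtype=float) - 1.0)
            if accepted:
                d = np.linalg.norm(np.asarray(accepted) - cand, axis=1)
                if d.min() < min_sep_px:
                    continue
            accepted.append(cand)
        if len(accepted) >= n:
            break
    if len(accepted) < n:
        raise RuntimeError(
            f"could not place {n} spots with min_sep_um={min_sep_um}; achieved {len(accepted)}"
        )
    coords = np.asarray(accepted[:n])
    return SpotSet(coords, np.full(n, np.nan))


# ---------------------------------------------------------------------------
# two-channel punctum rendering
# ---------------------------------------------------------------------------


def _add_gaussian(image: np.ndarray, row: float, col: float, amp: float, sigma_px: float) -> None:
    """Accumulate one isotropic Gaussian punctum in place (local patch only)."""
    h, w = image.shape
    r = int(math.ceil(4 * sigma_px))
    r0, r1 = max(0, int(row) - r), min(h, int(row) + r + 1)
    c0, c1 = max(0, int(col) - r), min(w, int(col) + r + 1)
    if r0 >= r1 or c0 >= c1:
        return
    yy = np.arange(r0, r1)[:, None] - row
    xx = np.arange(c0, c1)[None, :] - col
    image[r0:r1, c0:c1] += amp * np.exp(-(yy**2 + xx**2) / (2.0 * sigma_px**2))


def render_channel_pair(
    truth_spots: SpotSet,
    config: SimulationConfig,
) -> tuple[ImageChannel, ImageChannel, GroundTruth]:
    """Render a two-channel punctum field with a controlled shared fraction.

    Channel A receives every position in ``truth_spots``.  The first
    ``round(coloc_fraction * n)`` of them also appear in channel B at
    identical positions, with lognormal amplitudes whose log values are
    bivariate normal with correlation ``amp_corr``.  The remaining channel-B
    budget is filled with distractor puncta at fresh positions so both
    channels carry the same punctum density.

    Noise model: optional Poisson resampling of the noiseless image (shot
    noise) followed by additive Gaussian read noise.
    """
    h, w = config.image_shape_px
    sigma_px = config.psf_sigma_um / config.pixel_size_um
    if sigma_px < 0.5:
        logger.warning("psf_sigma_um=%g undersamples the pixel grid (sigma < 0.5 px)", config.psf_sigma_um)
    n = len(truth_spots)
    if n != config.n_spots:
        raise ValueError(f"truth_spots has {n} positions but config.n_spots={config.n_spots}")
    coords = truth_spots.coords
    if n and (
        coords.min() < 0 or coords[:, 0].max() >= h or coords[:, 1].max() >= w
    ):
        raise ValueError("truth spots must lie inside the image")

    rng = np.random.default_rng(config.seed)
    n_shared = int(round(config.coloc_fraction * n))

    # log-amplitudes: bivariate normal for the shared block, independent rest
    s = config.amp_log_sd
    cov = s**2 * np.array([[1.0, config.amp_corr], [config.amp_corr, 1.0]])
    z_shared = (
        rng.multivariate_normal([0.0, 0.0], cov, size=n_shared)
        if n_shared
        else np.empty((0, 2))
    )
    amp_A = np.empty(n)
    amp_A[:n_shared] = config.amp_median * np.exp(z_shared[:, 0])
    amp_A[n_shared:] = config.amp_median * np.exp(rng.normal(0, s, n - n_shared))

    n_distract = n - n_shared
    margin = max(int(math.ceil(4 * sigma_px)), 1)
    distract_coords = np.column_stack(
        [
            rng.uniform(margin, h - 1 - margin, n_distract),
            rng.uniform(margin, w - 1 - margin, n_distract),
        ]
    )
    amp_B_shared = config.amp_median * np.exp(z_shared[:, 1]) if n_shared else np.empty(0)
    amp_B_distract = config.amp_median * np.exp(rng.normal(0, s, n_distract))

    coords_B = np.vstack([coords[:n_shared], distract_coords])
    amp_B = np.concatenate([amp_B_shared, amp_B_distract])

    img_A = np.full((h, w), float(config.background_level))
    img_B = np.full((h, w), float(config.background_level))
    for (r, c), a in zip(coords, amp_A):
        _add_gaussian(img_A, r, c, a, sigma_px)
    for (r, c), a in zip(coords_B, amp_B):
        _add_gaussian(img_B, r, c, a, sigma_px)

    if config.shot_noise:
        img_A = rng.poisson(np.clip(img_A, 0, None)).astype(float)
        img_B = rng.poisson(np.clip(img_B, 0, None)).astype(float)
    if config.read_noise_sd > 0:
        img_A = img_A + rng.normal(0, config.read_noise_sd, img_A.shape)
        img_B = img_B + rng.normal(0, config.read_noise_sd, img_B.shape)

    truth = GroundTruth(
        spots_A=SpotSet(coords.copy(), amp_A),
        spots_B=SpotSet(coords_B, amp_B),
        shared_index_pairs=[(i, i) for i in range(n_shared)],
    )
    chan_A = ImageChannel(img_A, config.pixel_size_um, label="A")
    chan_B = ImageChannel(img_B, config.pixel_size_um, label="B")
    return chan_A, chan_B, truth


# ---------------------------------------------------------------------------
# curvature-class segmentation masks
# ---------------------------------------------------------------------------


def _ellipse_mask(area_px: float, aspect: float, angle: float) -> np.ndarray:
    """Rasterize a filled rotated ellipse of approximately ``area_px`` pixels."""
    # area = pi * a * b with b = a / aspect
    a = math.sqrt(area_px * aspect / math.pi)
    b = a / aspect
    half = int(math.ceil(max(a, b))) + 1
    yy, xx = np.mgrid[-half : half + 1, -half : half + 1]
    ca, sa = math.cos(angle), math.sin(angle)
    u = ca * xx + sa * yy
    v = -sa * xx + ca * yy
    return (u / a) ** 2 + (v / b) ** 2 <= 1.0


def make_structure_mask(
    config: StructureSimConfig,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Generate a labeled curvature-class mask plus its truth table.

    The membrane is an elliptical footprint of ``membrane_area_px`` pixels.
    Structures are perturbed ellipses (random aspect 1-2 and orientation)
    placed by rejection sampling with a 1-pixel clearance so components stay
    disjoint under 8-connectivity.  The truth table records the exact
    rendered pixel area of every structure.

    Returns
    -------
    mask : int label image (0 background, 1 membrane, 2 flat, 3 dome, 4 sphere)
    truth : DataFrame with columns structure_id, class_name, area_px, area_nm2
    """
    rng = np.random.default_rng(config.seed)
    scale2 = config.nm_per_px**2

    # sample target areas first so feasibility can be checked up front
    rows: list[dict] = []
    targets: list[tuple[str, float]] = []
    for cls in ("flat", "dome", "sphere"):
        p: ClassParams = getattr(config, cls)
        if p.count == 0:
            continue
        mu = math.log(p.mean_area_nm2) - p.log_sd**2 / 2.0
        areas_nm2 = np.exp(rng.normal(mu, p.log_sd, p.count))
        targets.extend((cls, float(a)) for a in areas_nm2)
    total_px = sum(a / scale2 for _, a in targets)
    if total_px >= config.membrane_area_px:
        raise ValueError(
            f"requested structure area ({total_px:.0f} px) exceeds membrane area "
            f"({config.membrane_area_px} px)"
        )

    # membrane: ellipse of the requested pixel area, mild 4:3 aspect
    aspect = 4.0 / 3.0
    a_mem = math.sqrt(config.membrane_area_px * aspect / math.pi)
    b_mem = a_mem / aspect
    h = int(math.ceil(2 * b_mem)) + 5
    w = int(math.ceil(2 * a_mem)) + 5
    yy, xx = np.mgrid[0:h, 0:w]
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    membrane = ((xx - cx) / a_mem) ** 2 + ((yy - cy) / b_mem) ** 2 <= 1.0

    mask = np.where(membrane, STRUCTURE_LABELS["membrane"], STRUCTURE_LABELS["background"]).astype(
        np.uint8
    )
    # place big structures first: packing is easier and failures are earlier
    order = np.argsort([-a for _, a in targets])
    sid = 0
    for oi in order:
        cls, area_nm2 = targets[oi]
        blob = _ellipse_mask(area_nm2 / scale2, rng.uniform(1.0, 2.0), rng.uniform(0, math.pi))
        # require 1-px clearance from other structures so components are disjoint
        clearance = ndimage.binary_dilation(blob, structure=np.ones((3, 3), bool))
        bh, bw = clearance.shape
        placed = False
        for _ in range(config.max_retries):
            r0 = int(rng.integers(h)) - bh // 2
            c0 = int(rng.integers(w)) - bw // 2
            if r0 < 0 or c0 < 0 or r0 + bh > h or c0 + bw > w:
                continue
            window = mask[r0 : r0 + bh, c0 : c0 + bw]
            if not membrane[r0 : r0 + bh, c0 : c0 + bw][blob].all():
                continue
            if (window[clearance] > STRUCTURE_LABELS["membrane"]).any():
                continue
            window[blob] = STRUCTURE_LABELS[cls]
            placed = True
            break
        if not placed:
            raise RuntimeError(
                f"could not place structure {sid} (class {cls}, "
                f"{area_nm2 / scale2:.0f} px) after {config.max_retries} retries"
            )
        rows.append(
            {
                "structure_id": sid,
                "class_name": cls,
                "area_px": int(blob.sum()),
                "area_nm2": float(blob.sum() * scale2),
            }
        )
        sid += 1

    truth = pd.DataFrame(rows, columns=["structure_id", "class_name", "area_px", "area_nm2"])
    return mask, truth


# ---------------------------------------------------------------------------
# IRM montage stacks
# ---------------------------------------------------------------------------


def make_irm_stack(
    n_tiles: int,
    tile_shape: tuple[int, int] = (128, 128),
    field_amplitude: float = 20.0,
    adhesion_spots: int = 10,
    seed: int = 0,
    offset: float = 100.0,
    spot_amplitude: float = -30.0,
    spot_sigma_px: float = 2.0,
    noise_sd: float = 1.0,
) -> IRMStackTruth:
    """Simulate an IRM montage: shared field pattern + per-tile adhesion signal.

    Every tile is ``offset + field_pattern + tile spots + Gaussian noise``
    where the field pattern (a smooth random low-order surface scaled to
    amplitude ``field_amplitude``) is identical across tiles — the structure
    that field-background averaging is designed to remove.  Adhesion sites
    are dark Gaussians (negative ``spot_amplitude``), matching destructive
    interference at tight membrane-substrate contact.
    """
    if n_tiles < 1:
        raise ValueError("n_tiles must be >= 1")
    h, w = tile_shape
    rng = np.random.default_rng(seed)

    if field_amplitude != 0:
        yy, xx = np.mgrid[0:h, 0:w]
        u = yy / max(h - 1, 1) - 0.5
        v = xx / max(w - 1, 1) - 0.5
        coef = rng.normal(0, 1, 6)
        surf = (
            coef[0] * u
            + coef[1] * v
            + coef[2] * u * v
            + coef[3] * (u**2 - 1 / 12)
            + coef[4] * (v**2 - 1 / 12)
            + coef[5] * np.sin(2 * np.pi * (u + v))
        )
        span = surf.max() - surf.min()
        field_pattern = field_amplitude * (surf - surf.mean()) / max(span, 1e-12)
    else:
        field_pattern = np.zeros((h, w))

    stack = np.empty((n_tiles, h, w))
    spot_rows: list[dict] = []
    for t in range(n_tiles):
        tile = offset + field_pattern.copy()
        for _ in range(adhesion_spots):
            r = rng.uniform(4, h - 5)
            c = rng.uniform(4, w - 5)
            amp = spot_amplitude * rng.uniform(0.5, 1.5)
            _add_gaussian(tile, r, c, amp, spot_sigma_px)
            spot_rows.append({"tile": t, "row": r, "col": c, "amplitude": amp})
        if noise_sd > 0:
            tile = tile + rng.normal(0, noise_sd, tile.shape)
        stack[t] = tile

    spot_table = pd.DataFrame(spot_rows, columns=["tile", "row", "col", "amplitude"])
    return IRMStackTruth(stack=stack, field_pattern=field_pattern, offset=offset, spot_table=spot_table)
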