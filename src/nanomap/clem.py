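"""Point-based affine registration for correlative light/EM overlays.

Landmarks are sub-pixel centers of structures visible in both modalities,
obtained by least-squares fits of an isotropic 2-D Gaussian.  A 6-parameter
affine map (2x2 linear part + translation) is fitted to the paired centers
by linear least squares, and fluorescence images are resampled onto EM
coordinates with nearest-neighbor interpolation (pull semantics through the
inverse map, rounding half-up, fill value 0).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

__all__ = [
    "AffineTransform",
    "GaussianFitError",
    "fit_gaussian_center",
    "fit_affine",
    "warp_nearest",
]


class GaussianFitError(RuntimeError):
    """The Gaussian landmark fit failed to converge."""


@dataclass
class AffineTransform:
    """Affine map ``dst = matrix @ src + translation`` on (row, col) points."""

    matrix: np.ndarray  # (2, 2)
    translation: np.ndarray  # (2,)
    residuals: np.ndarray = field(default_factory=lambda: np.empty(0))
    rms_residual: float = math.nan

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float).reshape(2, 2)
        self.translation = np.asarray(self.translation, dtype=float).reshape(2)

    def apply(self, points: np.ndarray) -> np.ndarray:
        points = np.atleast_2d(np.asarray(points, dtype=float))
        return points @ self.matrix.T + self.translation

    def inverse(self) -> "AffineTransform":
        det = float(np.linalg.det(self.matrix))
        if abs(det) < 1e-300:
            raise np.linalg.LinAlgError("transform is singular; no inverse overlay")
        inv = np.linalg.inv(self.matrix)
        return AffineTransform(inv, -inv @ self.translation)

    @property
    def params(self) -> np.ndarray:
        """The 6 parameters as ``[m00, m01, m10, m11, t0, t1]``."""
        return np.concatenate([self.matrix.ravel(), self.translation])


def _gaussian2d(grid: tuple[np.ndarray, np.ndarray], amp, r0, c0, sigma, offset):
    rr, cc = grid
    return offset + amp * np.exp(-((rr - r0) ** 2 + (cc - c0) ** 2) / (2.0 * sigma**2))


def fit_gaussian_center(patch: np.ndarray) -> tuple[float, float]:
    """Sub-pixel center of a single dominant peak in a patch.

    Fits ``offset + amp * exp(-r^2 / 2 sigma^2)`` (isotropic) by nonlinear
    least squares, seeded at the brightest pixel.

    Raises
    ------
    GaussianFitError
        On non-convergence; the message reports the final residual.
    """
    patch = np.asarray(patch, dtype=float)
    if patch.ndim != 2 or min(patch.shape) < 3:
        raise ValueError("patch must be 2-D with at least 3 px per side")
    rr, cc = np.mgrid[0 : patch.shape[0], 0 : patch.shape[1]]
    r_init, c_init = np.unravel_index(int(np.argmax(patch)), patch.shape)
    p0 = [
        float(patch.max() - patch.min()) or 1.0,
        float(r_init),
        float(c_init),
        max(min(patch.shape) / 6.0, 0.5),
        float(patch.min()),
    ]

    def residual(p):
        return (_gaussian2d((rr, cc), *p) - patch).ravel()

    fit = optimize.least_squares(residual, p0, method="lm", max_nfev=2000)
    if not fit.success:
        raise GaussianFitError(
            f"Gaussian center fit did not converge (final cost {fit.cost:.3g})"
        )
    return float(fit.x[1]), float(fit.x[2])


def fit_affine(src: np.ndarray, dst: np.ndarray) -> AffineTransform:
    """Least-squares affine transform from paired landmarks.

    Minimizes ``sum ||T(src_i) - dst_i||^2`` over the 6 parameters.
    Requires at least 3 non-collinear source points for a unique solution.
    Per-pair residual distances and their RMS are stored on the result.
    """
    src = np.atleast_2d(np.asarray(src, dtype=float))
    dst = np.atleast_2d(np.asarray(dst, dtype=float))
    if src.shape != dst.shape or src.shape[1] != 2:
        raise ValueError("src and dst must both be (n, 2)")
    n = len(src)
    if n < 3:
        raise ValueError(f"need >= 3 landmark pairs, got {n}")
    centered = src - src.mean(axis=0)
    if np.linalg.matrix_rank(centered, tol=1e-9 * max(1.0, float(np.abs(src).max()))) < 2:
        raise ValueError("landmarks are collinear; affine fit is degenerate")

    design = np.column_stack([src, np.ones(n)])  # (n, 3)
    coeffs, *_ = np.linalg.lstsq(design, dst, rcond=None)  # (3, 2)
    matrix = coeffs[:2].T
    translation = coeffs[2]
    transform = AffineTransform(matrix, translation)
    resid = np.linalg.norm(transform.apply(src) - dst, axis=1)
    transform.residuals = resid
    transform.rms_residual = float(np.sqrt(np.mean(resid**2)))
    return transform


def warp_nearest(
    image: np.ndarray,
    transform: AffineTransform,
    out_shape: tuple[int, int],
    fill: float = 0.0,
) -> np.ndarray:
    """Resample ``image`` onto the destination grid with nearest neighbor.

    Each output pixel pulls the value of the nearest source pixel under the
    inverse map (rounding half-up); coordinates falling outside the source
    image take ``fill``.  No interpolation-created values can appear.
    """
    image = np.asarray(image)
    inv = transform.inverse()
    h, w = out_shape
    rr, cc = np.mgrid[0:h, 0:w]
    pts = np.column_stack([rr.ravel(), cc.ravel()]).astype(float)
    src = inv.apply(pts)
    idx = np.floor(src + 0.5).astype(int)  # round half-up
    rows, cols = idx[:, 0], idx[:, 1]
    inside = (rows >= 0) & (rows < image.shape[0]) & (cols >= 0) & (cols < image.shape[1])
    out = np.full(h * w, fill, dtype=float)
    out[inside] = image[rows[inside], cols[inside]]
    return out.reshape(h, w)
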