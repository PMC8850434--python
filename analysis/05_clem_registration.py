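"""Landmark-based affine registration of fluorescence onto EM coordinates.

Simulates structures visible in both modalities: renders Gaussian puncta
in a fluorescence frame, maps their true centers through a known affine
(rotation + anisotropic scale + translation) to EM coordinates, refits
the centers by Gaussian least squares, recovers the transform from the
fitted landmarks, and warps the fluorescence image onto the EM grid.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from nanomap import io
from nanomap.clem import fit_affine, fit_gaussian_center, warp_nearest

OUT = Path(__file__).resolve().parent.parent / "results"
SEED = 20_265


def main() -> None:
    rng = np.random.default_rng(SEED)
    true_matrix = np.array([[1.22, -0.35], [0.31, 1.18]])
    true_translation = np.array([18.0, -7.0])

    # fluorescence frame with 9 well-separated puncta on a jittered grid
    shape = (200, 200)
    yy, xx = np.mgrid[0:shape[0], 0:shape[1]]
    image = np.full(shape, 5.0)
    centers = []
    for gr in range(3):
        for gc in range(3):
            r = 40 + 60 * gr + rng.uniform(-6, 6)
            c = 40 + 60 * gc + rng.uniform(-6, 6)
            centers.append((r, c))
            image += 80.0 * np.exp(-((yy - r) ** 2 + (xx - c) ** 2) / (2 * 2.2**2))
    image += rng.normal(0, 1.0, shape)

    # refit each punctum center from a 15x15 patch (sub-pixel landmarks)
    src = []
    for r, c in centers:
        r0, c0 = int(round(r)) - 7, int(round(c)) - 7
        dr, dc = fit_gaussian_center(image[r0:r0 + 15, c0:c0 + 15])
        src.append((r0 + dr, c0 + dc))
    src = np.asarray(src)
    fit_err = np.linalg.norm(src - np.asarray(centers), axis=1)
    print(f"Gaussian landmark fits: median center error {np.median(fit_err):.3f} px")

    dst = np.asarray(centers) @ true_matrix.T + true_translation
    transform = fit_affine(src, dst)
    param_err = np.abs(transform.matrix - true_matrix).max()
    print(f"affine recovery: RMS landmark residual {transform.rms_residual:.4f} px, "
          f"max linear-part error {param_err:.4f}")

    overlay = warp_nearest(image, transform, (280, 280))
    io.write_image(OUT / "clem_overlay.tif", overlay, dtype="float32")
    pd.DataFrame({
        "src_row": src[:, 0], "src_col": src[:, 1],
        "dst_row": dst[:, 0], "dst_col": dst[:, 1],
        "residual_px": transform.residuals,
    }).to_csv(OUT / "clem_landmarks.csv", index=False)
    io.write_json(OUT / "clem_transform.json", {
        "params": transform.params,
        "rms_residual_px": transform.rms_residual,
        "true_params": np.concatenate([true_matrix.ravel(), true_translation]),
    })
    print(f"overlay written; residuals come from landmark-fit noise only "
          f"(per-pair max {transform.residuals.max():.4f} px)")


if __name__ == "__main__":
    main()
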