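"""Generate the synthetic study inputs for the downstream analyses.

Builds, per condition (resting vs growth-factor stimulated):

* two-channel TIRF punctum fields for several cells — the stimulated
  condition carries a higher colocalized fraction and amplitude coupling,
  emulating receptor recruitment into clathrin structures;
* curvature-class segmentation masks — the stimulated condition has more
  and larger flat lattices while domes and spheres stay put;
* one shared IRM montage stack.

Everything is seeded; outputs (TIFF/CSV/YAML) land under results/data/.
"""

from pathlib import Path

import pandas as pd

from nanomap import io
from nanomap.synthetic import (
    ClassParams,
    SimulationConfig,
    StructureSimConfig,
    make_cell_mask,
    make_irm_stack,
    make_structure_mask,
    render_channel_pair,
    sample_truth_spots,
)

BASE_SEED = 20_260
N_CELLS = 6
SHAPE = (448, 448)
N_SPOTS = 60

# colocalized fraction / amplitude correlation per condition: stimulation
# recruits the receptor into clathrin structures
CONDITIONS = {"ctrl": (0.30, 0.4), "egf": (0.80, 0.8)}

# structure-mask regimes: stimulation grows flat lattices specifically
STRUCTURE_CONDITIONS = {
    "ctrl": dict(flat=ClassParams(4, 29_000.0), dome=ClassParams(3, 21_993.9),
                 sphere=ClassParams(3, 11_075.2)),
    "egf": dict(flat=ClassParams(14, 45_000.0), dome=ClassParams(3, 21_993.9),
                sphere=ClassParams(4, 11_075.2)),
}

OUT = Path(__file__).resolve().parent.parent / "results" / "data"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    print("== two-channel TIRF fields ==")
    for ci, (cond, (frac, corr)) in enumerate(CONDITIONS.items()):
        for cell in range(N_CELLS):
            seed = BASE_SEED + 1_000 * ci + 10 * cell
            config = SimulationConfig(
                image_shape_px=SHAPE, n_spots=N_SPOTS, coloc_fraction=frac,
                amp_corr=corr, seed=seed,
            )
            mask = make_cell_mask(SHAPE, 0.85, 0.12, seed=seed + 1)
            spots = sample_truth_spots(
                mask, N_SPOTS, config.min_sep_um, config.edge_margin_um,
                config.pixel_size_um, seed=seed + 2,
            )
            chan_a, chan_b, truth = render_channel_pair(spots, config)
            stem = OUT / f"tirf_{cond}_cell{cell}"
            io.write_image(f"{stem}_clathrin.tif", chan_a.data, dtype="float32")
            io.write_image(f"{stem}_receptor.tif", chan_b.data, dtype="float32")
            io.write_mask(f"{stem}_mask.tif", mask)
            io.write_yaml(f"{stem}_config.yaml", {
                "condition": cond, "cell": cell, "seed": seed,
                "coloc_fraction": frac, "amp_corr": corr,
                "pixel_size_um": config.pixel_size_um, "n_spots": N_SPOTS,
                "n_shared_truth": truth.n_shared,
            })
        print(f"  {cond}: {N_CELLS} cells, coloc_fraction={frac}, amp_corr={corr}")

    print("== curvature-class segmentation masks ==")
    for ci, (cond, classes) in enumerate(STRUCTURE_CONDITIONS.items()):
        for cell in range(4):
            seed = BASE_SEED + 500 + 1_000 * ci + 10 * cell
            cfg = StructureSimConfig(membrane_area_px=13_000_000, seed=seed, **classes)
            mask, truth = make_structure_mask(cfg)
            stem = OUT / f"prem_{cond}_cell{cell}"
            io.write_mask(f"{stem}_labels.tif", mask)
            truth.assign(condition=cond, cell_id=f"cell{cell}").to_csv(
                f"{stem}_truth.csv", index=False
            )
        n_structures = sum(p.count for p in classes.values())
        print(f"  {cond}: 4 masks, {n_structures} structures each")

    print("== IRM montage stack ==")
    irm = make_irm_stack(16, (160, 160), field_amplitude=25.0, adhesion_spots=12,
                         seed=BASE_SEED + 900)
    io.write_stack(OUT / "irm_stack.tif", irm.stack, dtype="float32")
    irm.spot_table.to_csv(OUT / "irm_spots_truth.csv", index=False)
    print(f"  16 tiles of 160x160 px written to {OUT / 'irm_stack.tif'}")


if __name__ == "__main__":
    main()
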