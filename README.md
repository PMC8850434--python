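# nanomap

Quantitative image-analysis pipeline for studying how flat clathrin
lattices (FCLs) grow on the plasma membrane during growth-factor
signaling, and how receptors and adhesion proteins are recruited into
them. It is written for microscopists who have two-channel TIRF images,
curvature-classed replica-EM segmentation masks, IRM montages, or CLEM
landmark sets — and for anyone who wants to validate such analyses on
synthetic data with known ground truth.

## What it computes

**Spot-wise colocalization.** Clathrin puncta are detected in one channel
as thresholded local maxima, kept only if ≥ 2 µm from the cell edge.
Around each punctum a 4 µm × 4 µm region is cropped at identical
coordinates from both channels and the Pearson correlation

  r = Σ (aᵢ − ā)(bᵢ − b̄) / √(Σ (aᵢ − ā)² · Σ (bᵢ − b̄)²)

is computed over pixels. An equal number of randomly positioned regions
forms the null for nonspecific colocalization. The per-cell mean r is the
condition statistic (the "C" of two-color correlation analysis), and
condition contrasts are reported as fold changes to 2 significant figures.

**Morphometry.** From a label image (background / membrane / flat / dome /
sphere), per-structure areas in nm² (8-connected components ×
nm-per-px²), percent membrane occupancy per class
(100 · class area / membrane area), size summaries with t-based 95% CIs,
and condition fold changes.

**Photometry & IRM.** Corrected total cell fluorescence,
CTCF = (IntDen − Area·BḠ)/Area, i.e. mean cell intensity minus mean
background; and IRM montage normalization (field-background subtraction,
baseline shift, normalization to max = 3 × mean, optional contrast
inversion).

**CLEM registration.** Sub-pixel Gaussian landmark centers, least-squares
affine fit (2×2 + translation) with per-pair residuals, nearest-neighbor
warping of fluorescence onto EM coordinates.

**Statistics.** Shapiro–Wilk normality gate, F-ratio variance gate,
Student/Welch two-tailed t-test or one-way ANOVA with Tukey post-test.

A seeded synthetic-data module (`nanomap.synthetic`) generates every
input — punctum fields with a controllable colocalized fraction, labeled
structure masks with exact truth tables, IRM stacks with a shared field
pattern — so the whole pipeline is testable without microscope data.

## Worked example

```python
import nanomap as nm

config = nm.SimulationConfig(image_shape_px=(384, 384), n_spots=250,
                             coloc_fraction=0.8, amp_corr=0.8, seed=7)
mask = nm.make_cell_mask((384, 384), coverage_fraction=0.9, seed=8)
spots = nm.sample_truth_spots(mask, 250, config.min_sep_um,
                              config.edge_margin_um, config.pixel_size_um, seed=9)
clathrin, receptor, truth = nm.render_channel_pair(spots, config)

result = nm.cell_correlation(clathrin, receptor, mask,
                             nm.CorrelationParams(seed=10))
print(f"n_spots={result.n_spots}  mean_r={result.mean_r:.3f}  "
      f"null_mean_r={result.null_mean_r:.3f}")
```

prints

```
n_spots=249  mean_r=0.735  null_mean_r=0.656
```

249 of the 250 simulated puncta are detected and accepted. With 80% of
puncta shared between channels the spot-centered correlation is high
(0.74); the randomized null (0.66) is the nonspecific floor at this
punctum density — at 250 puncta per frame a random 4 µm region almost
always catches shared puncta — and the spot-vs-null contrast shrinks as
fields get denser (see `docs/methods.md`). On channel-independent fields
both statistics calibrate to zero. The same
analysis is available from the shell:

```bash
nanomap simulate --out sim/ --coloc-fraction 0.8 --seed 7
nanomap correlate --channel-a sim/channel_a.tif --channel-b sim/channel_b.tif \
                  --mask sim/mask.tif --seed 7 --out corr/
```

## Analysis scripts

`analysis/01_simulate_inputs.py` … `06_group_stats.py` run the full
narrative: simulate a two-condition study (resting vs stimulated),
measure receptor-clathrin correlation per cell, quantify flat-lattice
occupancy growth and per-class sizes, process the IRM stack and CTCF,
register CLEM landmarks, and compare conditions statistically. Run them
in order from the repository root; tables and images land under
`results/`.

## Layout

```
src/nanomap/      library: synthetic, correlate, morphometry,
                  photometry, clem, stats, io, cli
analysis/         numbered narrative drivers over the library
tests/            pytest suite (unit, property, acceptance)
scripts/          acceptance.py
docs/methods.md   models, parameter choices, limitations
```
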