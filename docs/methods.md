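# Methods

This note documents the models, parameter choices, and numerical decisions
behind each stage of the pipeline, and what the synthetic-data tests do and
do not establish about real microscope data.

## Scientific setting

Growth-factor stimulation remodels clathrin at the adherent plasma
membrane: flat clathrin lattices (FCLs) grow in size and membrane
coverage while curved pits and spheres change little, and receptors,
adapters, and adhesion proteins are differentially recruited into these
structures. The pipeline quantifies this with five measurements:

1. **Spot-wise two-channel correlation** — how strongly a protein's
   fluorescence tracks clathrin puncta, spot by spot, against a
   randomized-region null.
2. **Curvature-class morphometry** — per-structure areas (nm²) and percent
   membrane occupancy of flat / dome / sphere classes from labeled
   replica-EM segmentation masks.
3. **CTCF photometry** — background-corrected membrane fluorescence of a
   segmented cell.
4. **IRM montage normalization** — the preprocessing that makes
   interference-reflection adhesion images comparable before they feed the
   correlation stage.
5. **CLEM registration** — landmark-based affine mapping of fluorescence
   onto EM coordinates with nearest-neighbor resampling.

A seeded synthetic-data module generates every input with recorded ground
truth, so each stage is validated end to end without the original
microscope data.

## Synthetic data

**Punctum fields.** Diffraction-limited structures are isotropic 2-D
Gaussians (σ = 0.11 µm by default) with lognormal amplitudes on a constant
background (100 counts). Defaults emulate a 100×/1.45 NA EMCCD
acquisition; the pixel pitch default is 0.107 µm — typical for that
configuration and configurable, since real pixel pitch varies by camera.
Sharing between channels is explicit: a fraction `coloc_fraction` of
puncta appears at identical positions in both channels, with
log-amplitudes drawn from a bivariate normal with correlation `amp_corr`
(keeping amplitudes positive and the coupling interpretable); the
remaining channel-B budget is filled with distractor puncta at fresh
positions so both channels have equal density. Detector noise is Poisson
resampling of the noiseless image (shot noise) followed by additive
Gaussian read noise (SD 2 counts) — the physical order for a
photon-counting camera. Punctum positions come from dart throwing over
the cell mask eroded by a 2 µm margin, with a 0.5 µm hard-core minimum
separation.

**Curvature-class masks.** Structures are rotated ellipses (aspect 1–2)
placed without overlap (1-px clearance, so 8-connected components remain
disjoint) on an elliptical membrane footprint. Class sizes are lognormal
and parameterized by their **arithmetic mean** area: domes default to
21,993.9 nm² and spheres to 11,075.2 nm² (measured lattice values); flat
lattices default to 29,000 nm² in the resting condition. The truth table
records the exact rendered pixel count of every structure, making the
morphometry round trip exact by construction. The default scale is
1.2 nm/px (15,000× replica EM).

**IRM montages.** Every tile is `offset + shared field pattern +
tile-specific adhesion spots + Gaussian noise`. The field pattern is a
smooth random low-order surface shared across tiles — the structure that
field-background averaging removes. Adhesion sites are dark Gaussians
(destructive interference at tight contacts). No interference optics are
modeled; the generator reproduces only the statistical structure the
processing pipeline assumes.

**What the generator does not emulate:** spatially varying background and
illumination, punctum shape anisotropy and defocus, camera gain structure,
spot motion or blinking, segmentation error in masks (class labels are
clean by construction), and the long-tailed size/shape diversity of real
lattices. Passing tests therefore establish correctness of the
*measurement code* under the stated model, not robustness to every
real-data artifact.

## Spot correlation

Detection: a punctum peak is a pixel strictly greater than its
8-neighborhood; plateaus are broken at the lowest row-major index. Peaks
must exceed the threshold, lie ≥ 2 µm from the cell-mask boundary
(Euclidean distance transform; the image frame counts as boundary), and be
mutually separated by ≥ 0.5 µm (the brighter of a close pair wins).

The threshold is user-defined, either absolute or (default) a fraction
0.2 of the per-image robust intensity range (1st–99.9th percentile inside
the mask). The fractional form is scale-free on densely punctate images
but collapses into the noise floor when puncta are so sparse that the
99.9th percentile is itself noise — sparse fields should use an absolute
threshold.

Regions are squares of side 4 µm, rounded to pixels and forced odd so the
central pixel is unique; spot and null regions are cropped at identical
coordinates in both channels, and regions crossing the image border are
excluded and tallied (never truncated). Pearson r is computed over
flattened pixels of the raw intensities (no background subtraction);
zero-variance regions are dropped and counted. The null draws as many
uniformly random valid centers as there are accepted spots; null regions
may overlap anything.

**Interpretation of the null.** The randomized null measures nonspecific
colocalization. On channel-independent data it is zero to within sampling
noise (the calibration the acceptance suite checks: |mean r| < 0.05 at
500 spots over 20 seeds). On genuinely colocalized data it is *not* zero:
a random 4 µm region that happens to catch a shared punctum correlates
strongly, so the null floor grows with punctum density. The meaningful
comparison is spot-centered correlation against this floor.

**Aggregation.** The cell is the analysis unit: condition summaries are
mean ± SD over per-cell mean r (matching "N cells – N spots" reporting
conventions), with pooled-spot means also emitted for transparency. Fold
changes between condition means are reported raw and rounded to 2
significant figures.

## Morphometry

Connected components use 8-connectivity (diagonal contact merges).
Structures clipped by the mask edge count at their visible area, because
occupancy is defined against visible membrane. Occupancy of a class is
100 × class pixel area / membrane pixel area, with membrane area
including the structures sitting on it; the "all structures" occupancy is
the sum of the three classes, exactly. Sizes are summarized by median,
quartiles, mean, and a t-based 95% CI of the mean (undefined, not NaN
disguised as a number, at n = 1). The structure "size" is the filled
footprint area of the segmented component.

## CTCF

As commonly printed, the CTCF expression reduces to
`IntegratedDensity − BackgroundMean`, which subtracts a per-pixel mean
from a summed intensity. The implemented quantity is the dimensionally
consistent per-area form

    CTCF = (IntegratedDensity − CellArea × BackgroundMean) / CellArea
         = mean cell intensity − mean background,

with the background mean averaging the means of the background ROIs
(three by convention, any ≥ 1 accepted). The formula reading is carried in
the result metadata rather than silently assumed. This form is invariant
to global additive offsets and scales linearly with gain.

## IRM normalization

Processing: (i) subtract the field background (pixelwise mean across
montage tiles), (ii) shift so the global stack minimum is 0, (iii)
normalize so the stack maximum is three times the stack mean. Step (iii)
cannot be a pure rescaling — dividing by any constant leaves max/mean
unchanged — and naive "divide by mean then clip at 3" overshoots, because
clipping lowers the mean and leaves max/mean > 3. The implementation finds
the unique clip level c* solving `c = 3 · mean(min(x, c))` by monotone
fixed-point iteration (convergence to machine precision from
`c₀ = 3·mean(x)`), clips there, and divides by the clipped mean. The
result has mean 1 and max exactly 3 whenever any pre-clip pixel exceeded
3× the mean, and is a plain division by the mean otherwise. Contrast
inversion (`(max+min) − pixel`, an involution) is applied per tile after
normalization when requested; the max/mean invariant refers to the
pre-inversion stack.

## CLEM registration

Landmarks are sub-pixel centers from least-squares fits of an isotropic
2-D Gaussian plus constant offset (Levenberg–Marquardt, seeded at the
brightest pixel); anisotropy is out of scope. The affine map (6
parameters) is the linear least-squares solution over ≥ 3 non-collinear
pairs; per-pair residuals and their RMS are reported, and with isotropic
landmark noise SD σ the expected RMS residual is σ·√(2(n−3)/n) (6 of the
2n residual degrees of freedom are absorbed by the fit) — verified by
Monte Carlo. Warping uses pull semantics: each output pixel takes the
nearest source pixel under the inverse map, rounding half-up, fill 0; no
interpolation-created values can appear.

## Statistics

Two groups: Shapiro–Wilk normality per group, then a two-sided F-ratio
gate at α = 0.05 for equal variances deciding Student vs Welch t-test
(the F gate is a declared concrete choice; the variance-gate procedure is
often left unspecified in write-ups). More than two groups: one-way ANOVA
with Tukey HSD. Non-normal data are not auto-switched to a nonparametric
test; the parametric result is emitted with the failed gate flagged, so
the gate decision is always visible in the report. Type-I calibration of
the two-sample ladder (rejection rate 0.05 ± 0.01 under the null at
α = 0.05, 10,000 simulated pairs of n = 30) is checked in the acceptance
suite.

## Problem sizes and defaults used in the validation runs

* Null calibration: 20 seeds × 500 puncta on 512×512 frames (0.107 µm/px).
* Colocalization recovery: shared fraction ∈ {0, 0.25, 0.5, 0.75, 1},
  3 seeds × 250 puncta on 384×384 frames; the noiseless full-overlap case
  recovers mean r = 1.
* Dome-size calibration: 200 structures at 9.6 nm/px (coarser than the
  1.2 nm/px default purely to keep canvases small; areas are scale-true).
* Analysis drivers: 6 cells × 60 puncta per condition for correlation;
  4 masks per condition with 13 × 10⁶ membrane pixels for morphometry,
  which puts occupancies in the sub-percent-to-few-percent regime of real
  membranes.

These sizes are the package's validation conditions; all are configurable.

## Known limitations

* The correlation stage has no sub-pixel localization, spot tracking, or
  deconvolution; detection is whole-pixel by design.
* The segmentation masks are inputs — no automatic clathrin detection or
  curvature classification from raw EM images is attempted.
* The null floor depends on punctum density (above); comparing conditions
  at very different densities requires care.
* IRM contrast is treated purely photometrically; no interference model.
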