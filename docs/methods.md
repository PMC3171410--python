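# Methods

This note records how `gazeframe` defines its quantities, the defaults
and regimes in which its procedures are valid, and the design choices
made where the literature leaves the construction open.

## Coordinates, geometry and density maps

Fixations live on a pixel screen with `x` = column, `y` = row, origin
top-left, half-open intervals [0, W) × [0, H); coordinates are treated
as positions whose containing grid cell is found by truncation (pixel
*centers* are the reference — the convention is recorded here because
raw eye-tracking exports are inconsistent about it). Angular distances
convert to pixels linearly per axis (`px_per_deg = W_px / W_deg`); no
tangent correction is applied since only a single global stimulus
extent is assumed known. Out-of-screen fixations are dropped with a
warning by default (`reject-file` available), because tracker noise
routinely produces them.

A fixation density map (FDM) is the 2-D histogram of fixation
positions smoothed with a Gaussian kernel and normalized to unit mass.
The kernel is specified by its full width at half maximum in degrees,
default **2°** (σ = FWHM / (2√(2 ln 2)) ≈ FWHM/2.355), matching
eye-tracker calibration error and the ~2° foveal sampling window.
σ is computed per axis from per-axis pixels-per-degree. The kernel is
truncated at the screen border and the map renormalized globally
afterwards; consequently FDMs are exactly linear in their fixations
only while kernels stay inside the screen — border trials renormalize
slightly differently, which is accepted as the cost of not distorting
interior values. Maps are computed directly at the working grid scale
with the kernel rescaled accordingly (smoothing after rescaling, not
before); the default working scale for bound computations is 1/20
(64 × 48 cells on a 1280 × 960 screen), comfortably finer than the 2°
kernel. Downsampling of existing maps is by block sum, conserving
mass exactly.

For entropy and KL work a *coarse grid* is derived from the geometry:
square bins whose area equals a 2°-diameter disc (12 × 16 bins,
N = 192, on the reference display). Histograms on this grid are not
smoothed — the grid itself is at the effective resolution of a
2°-smoothed FDM.

## AUC

Positives are map values at fixated cells (nearest cell, no
interpolation); negatives are, selectably, all cells, all never-fixated
cells, or the values at locations fixated on other images (the hook
for center-bias-corrected variants). Thresholds are the unique positive
values; the step ROC is integrated by lower sums, with trapezoidal
integration where negatives tie a threshold and for the final segment
when the hit rate has not reached one. Algebraically each positive
earns the fraction of negatives strictly below it plus half the
fraction tied, so the implementation equals the Mann-Whitney statistic
and full-curve trapezoidal integration to machine precision (asserted
in the tests against both oracles); a constant map scores exactly 0.5
and perfect separation exactly 1.

The theoretical maximum AUC of a density treats the prediction as the
density itself and the controls as uniform over cells. The published
derivation defers the case of a spatially biased control distribution
("equilibrating the spatial discretization"); so does this
implementation, and the result carries
`controls: uniform (no spatial bias)` in its parameters.

## Measure parameters left open in the literature

* **NSS** normalizes by the *population* standard deviation of the map.
* **Ratio of medians**: disc radius default 5.6°, elliptical in cells
  when pixels are anisotropic, clipped at borders; control points
  default to as many as there are fixations, uniform over the image,
  seeded.
* **Naive Bayes**: equal priors, equal-width bins (default 10) over the
  pooled score range, Laplace-smoothed counts, stratified k-fold
  (default 10) so every point is tested exactly once.
* **KL divergence**: q is floored at `1e-12 / N` (10⁻¹² of the uniform
  mass) and renormalized before taking logs — the raw measure is
  infinite whenever the model assigns exact zero to a fixated cell;
  p·log p terms with p = 0 contribute 0. Natural log by default; the
  log base is an explicit parameter everywhere and is recorded in every
  estimate, since published figures rarely state it.
* **Jeffreys correction** adds ½ to each bin count (the
  Jeffreys/Krichevsky-Trofimov prior) before normalizing.

## Entropy/KL bias correction

Chao-Shen coverage adjustment: C = 1 − f₁/n (f₁ = singleton bins),
p̂ᵢ = C·cᵢ/n, and each entropy term is divided by the inclusion
probability 1 − (1 − p̂ᵢ)ⁿ. Treating the model density Q as exact, the
same adjustment applies to the cross-entropy term, giving the corrected
KL Σᵢ p̂ᵢ log(p̂ᵢ/qᵢ) / (1 − (1 − p̂ᵢ)ⁿ). When every observation is a
singleton (C = 0) the estimator is undefined and a typed error is
raised; the simulation harness records such draws as missing. The
harness draws multinomial samples of each requested size from an
arbitrary truth density and reports mean and SD per (method, n) for
entropy or for KL against truth (or a distinct model density, whose
analytic divergence is included for reference). The bias experiment in
the test suite uses a smooth Gaussian on the 16 × 12 coarse grid,
n from 6 to 400 and 200 replicates — a size chosen so the full suite
stays interactive; the qualitative conclusions (plug-in bias falls
with n; corrected estimators beat it for n ≥ N/2) are scale-free.

## Reference-frame protocol

All bound computations run per stimulus category and never pool across
categories. For every (n_subjects, n_images) cell of the schedule and
every (test subject, test image) pair, repeated random training draws
are made; the test subject is excluded from every training set, and the
test image as well for the lower bound and subject-specific curves.
Draws of one or two donors are explicitly balanced by consuming
reshuffled donor cycles, so no donor is over-represented across
repetitions; larger draws are uniform without replacement. The default
schedule mirrors a 48-subject × 64-image study (subject sizes 1, 2, 4,
7, 13, 25, 47; image sizes 1 … 63; 47 repetitions, 63 for the
subject-specific bias); `CVSchedule.geometric` adapts it to any dataset
size. Cells the dataset cannot support are reported missing rather
than silently shrunk. KL-based evaluation uses the coarse grid with the
sample-size-corrected estimator (Jeffreys by default for per-trial test
sets, Chao-Shen when the test set holds at least a few dozen
fixations), since per-trial fixation counts are far below the bin
count.

PCA cleaning: per-subject bias maps are smoothed FDMs at the working
scale, flattened, centered by their mean and decomposed by SVD; the
top k = 5 components are kept. Component signs are fixed (largest-
magnitude coefficient positive) purely for reproducibility. A subject's
noisy bias is regressed onto the components (ordinary least squares;
identical to projection since the components are orthonormal),
reconstructed from the mean map, clipped at zero and renormalized. The
eigenvalue-weighted sum of components serves as the subject-blind
control. The combined subject × image prediction divides the
inter-subject FDM point-wise by the training subjects' spatial bias
(floored at 10⁻⁶ of the uniform mass to keep zero-support cells from
exploding) and multiplies by the predicted subject's bias, then
renormalizes.

## Synthetic generator

Each fixation is drawn from a three-component mixture: a
category-dependent central Gaussian (default σ 5° × 4° for "naturals",
7.5° × 6° for "urbans" — natural scenes show the tighter central bias),
one of a small number of per-image hotspot Gaussians (default 2 per
image, σ 1.5°, centers drawn once per image on the central 80% of the
screen and shared by all subjects), and a subject-specific Gaussian
(default σ 4°) displaced by a per-subject offset that is a linear
combination of `n_subject_components` fixed unit direction fields with
weights ~ N(0, `subject_weight_sd`°). Default mixture weights are
(0.35, 0.45, 0.20) for (central, hotspot, subject); trials hold 15
fixations on a 1280 × 960 / 28.4° × 21.3° display. Off-screen samples
are rejected and redrawn, so every component is a properly truncated
density, and the ground-truth bundle evaluates exactly those truncated,
grid-renormalized mixtures. Independent random streams derive from the
root seed for image layout, subject weights and each trial, so layouts
are invariant to the subject count.

What the generator does *not* emulate: temporal scan-path structure,
saccade-length statistics, fixation durations, repeated fixations of
the same object, blinks and tracker dropout, or non-Gaussian hotspot
shapes. Tests passing on synthetic data therefore validate the
estimation machinery — train/test hygiene, bias corrections, ordering
and recovery properties — not the realism of any particular fixation
model.

### Regime required for PCA subspace recovery

The subject model is *offset*-based, and a Gaussian shifted by δ is a
linear function of δ only to first order: b(x − δ) ≈ b(x) − δ·∇b(x) +
O(|δ|²/σ²). Recovery of a planted 2-dimensional offset subspace as two
dominant principal components therefore requires (i) offsets small
against the subject-kernel width (|δ| ≲ σ/3; the second-order leakage
grows as (δ/σ)²), and (ii) enough fixations per subject that
multinomial sampling noise stays well below the planted variance —
noise spreads across all sample-PCA components and otherwise inflates
the trailing eigenvalues. The recovery test uses offsets of sd 1.5° on
a 6° subject kernel, ~3800 fixations per subject, and a 5°-FWHM
analysis kernel matched to the component scale (heavier smoothing
suppresses sampling noise without attenuating 6°-scale structure).
Outside this regime — large idiosyncratic shifts or few fixations —
the planted structure genuinely occupies more than two components, and
the package makes no claim that PCA cleaning identifies "the" subject
dimensions there; the cleaning step itself (projection on the leading
components) remains beneficial far outside the linear regime, as the
sign tests show. The combined-prediction experiment likewise needs
bias estimates at realistic study sizes (≥ ~60 images for the subject
bias); with per-image noise of small studies the division step
amplifies noise faster than the idiosyncrasy gain, which was verified
against an analytic-bias oracle where the effect is always positive.

## Problem sizes in the test suite

The suite favors the smallest sizes at which each property is
meaningfully testable: oracle equivalences on ≤ 200-point samples; the
bias simulation at N = 192, n ≤ 400, 200 replicates; the reference
frame on 12 subjects × 16 images with 3 repetitions; the idiosyncrasy
studies on 24 subjects with 64 and 256 images. The full-size default
schedule (47 repetitions over a 49-cell grid) is exercised through the
CLI on miniature datasets only.

## Known limitations

* The lower-sum/trapezoid AUC assumes exchangeable controls; weighted
  (spatially equilibrated) controls for the theoretical bound are not
  implemented.
* Chao-Shen corrected KL treats Q as exact; if Q is itself estimated,
  both sides are biased and no correction is attempted.
* Entropy estimators beyond ML, Miller-Madow, Chao-Shen and Jeffreys
  (shrinkage, NSB, minimax, …) are out of scope, though the simulation
  harness's output schema accommodates externally computed columns.
* Per-trial KL scores at the coarse grid remain noisy below ~N/2
  fixations per test set; the bounds engine reports them but they are
  only comparable at matched test-set sizes.
* `FixationDataset` keeps the first `max_fixations` fixations per
  trial (by trial index); duration weighting is not supported.
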