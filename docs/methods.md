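# Methods

`ramanhisto` models a Raman spectral-histopathology workflow for liver
tissue: matched carcinoma / adjacent-parenchyma cohorts are simulated with
known ground truth, preprocessed, classified with a 1-D convolutional
network under a patient-level protocol, and hyperspectral maps are unmixed
and segmented for tumour-margin delineation and label-free histochemistry.
This note records the models, the parameters that matter, and the design
choices where more than one reasonable option existed.

## Synthetic spectra

A spectrum on the fingerprint axis (500–2000 cm⁻¹, 889 points) is

    I(ν) = g · e_p · Σ_k a_k m_k(c) · G(ν; ν_k, w) + b(ν) + ε(ν),  clipped at 0

where `G` is a Gaussian line of FWHM `w` (default 12 cm⁻¹, typical of
condensed-phase tissue bands; no line shape is canonical for tissue, and a
Voigt adds parameters the analysis never exercises), `a_k` are the reference
amplitudes of the 19 characteristic bands, `m_k(c)` the class multipliers,
`g` the class global scale, `e_p` a per-patient log-normal intensity factor
(σ = 0.15) shared by both of a patient's samples, `b` a fluorescence-like
background (cubic polynomial plus one broad Gaussian hump, coefficients
redrawn per spectrum), and `ε` additive Gaussian noise (σ = 12 a.u. against
reference band amplitudes of 200–950 a.u.). A heteroscedastic noise option
(σ ∝ √intensity) exists but is off by default.

The 19th band: eighteen band positions are fixed by their literature
assignments (aromatic amino acids, carotenoids, lipids, nucleic acids,
amide I, saccharides); the remaining band defaults to the ubiquitous
1448 cm⁻¹ CH₂ deformation and is configurable.

### Class contrasts

Class profiles encode only inequalities that the underlying tissue biology
supports, with magnitudes chosen once so that the classification tasks span
a realistic accuracy range (binary separation strong, differentiation-grade
separation weak):

- Carcinoma vs parenchyma: global scale ×0.72 plus a carotenoid-dominated
  *shape* signature — HCC suppresses the resonance-enhanced carotenoid bands
  (1003/1156/1519 cm⁻¹) to ×0.60 and lipid bands (1081/1130/1304 cm⁻¹) to
  ×0.82; ICC suppresses carotenoids to ×0.85 and amino-acid/nucleic-acid
  bands (749/974/1304/1356/1393/1586 cm⁻¹) to ×0.72. Every band therefore
  sits strictly below its parenchyma level, while the two subtypes remain
  mutually distinguishable (ICC retains more carotenoid, less of the rest).
  A shape signature is essential, not cosmetic: the per-patient intensity
  factor makes a purely global-scale contrast unlearnable for patients in
  the overlap of the two log-normal scale distributions, which no amount of
  training fixes.
- Stage and grade (HCC only): modifiers are *suppress-only* (all factors
  ≤ 1) — advanced stage loses 15% at 1003/1156/1519/1130/749/1547 cm⁻¹,
  early stage 15% at 674/974/835 cm⁻¹; moderate/poor differentiation lose
  7%/15% globally and at the carotenoid bands. Suppress-only composition
  guarantees no stage/grade combination pushes a band back up to parenchyma
  level, so the subgroup structure adds within-class variability for the
  binary task without ever inverting its cue.
- Stage and grade label proportions default to uniform and are
  configurable; subtype counts are exact (98 HCC / 22 ICC of 120 patients).

What the generator does *not* emulate: instrument response, étalon fringes,
wavelength-calibration drift, cosmic-ray statistics matched to a real CCD,
spatial correlation of noise within maps, or real biological covariance
between bands beyond the class means. Passing tests therefore demonstrate
that the pipeline recovers structure *of the kind assumed*, at realistic
noise, not that it reaches any particular accuracy on real tissue.

## Preprocessing

Baseline: asymmetric least squares (Whittaker smoother) — minimise
`Σ w_i (y_i − z_i)² + λ Σ (Δ² z)²` with `w = p` above and `1 − p` below the
baseline, iterated 10 times; defaults λ = 1e5, p = 0.01, the standard
regime for fluorescence-dominated tissue Raman. A polynomial fit is the
alternative. Smoothing: Savitzky–Golay, window 11, order 3. Peak intensity:
maximum within ±8 cm⁻¹ of the band centre (area integration available);
no normalization is applied by default because the diagnostic contrasts
here are absolute-intensity differences between matched tissues —
vector-normalising would discard the global-scale cue and is exposed only
as an option. Cosmic rays (imaging chain): a pixel/band entry is a spike
when its deviation from the 3×3 spatial-neighbourhood median exceeds 8
robust standard deviations; the scale is the per-band MAD floored by a
cube-wide upper-quantile estimate, because bands with near-zero signal
(clipped at zero) otherwise report a degenerate scale. Statistical tests:
equal-variance two-sided Student's t per band (Welch by flag); Pearson
correlation matrices with average-linkage dendrogram ordering.

## The classifier

A 1-D adaptation of VGG-16: thirteen convolutional layers (kernel 3,
same-length padding, ReLU) in blocks of 2×64, 2×128, 3×256, 3×512, 3×512
channels, max-pooling (2,2) between blocks (889 → 444 → 222 → 111 → 55 →
27), then fully connected 256 → 128 → n_classes with dropout 0.5, softmax
output, weighted cross-entropy (class weights ∝ 1/n_c, normalised so all
classes contribute equally), Adam at lr 1e-4, batch 128, 50 epochs,
best-validation-loss checkpoint. Optimiser, FC widths and epoch count are
not canonical for this architecture family; Adam and 256/128 are the
conventional choices. Inputs are standardised per wavenumber channel with
train-set statistics (stored on the model); this is an optimisation aid,
not a spectral normalization. One master seed drives initialisation,
shuffling and dropout; runs are deterministic at a fixed BLAS thread count.
Ties in the argmax resolve to the lower class index.

Splits are patient-level throughout: all spectra of a patient land in
exactly one partition. Binary task: 20 held-out patient pairs, remainder
8:2 train/validation. Subgroup tasks: 20% of patients per class held out,
remainder 9:1. The subtype task uses carcinoma spectra; stage and grade
tasks use HCC carcinoma spectra; grade is 3-class (well/moderate/poor).

### Desk-scale profile

The full profile is impractical for routine CPU testing, so a documented
desk-scale profile is used by the test suite: 40 patients (32 HCC / 8 ICC)
× 2 samples × 30 spectra = 2,400 spectra, all layer widths ÷ 4, the
spectral axis decimated ×2 (445 points — the 12 cm⁻¹ bands keep ≥ 4 points
so no band is lost), 30 epochs at Adam lr 3e-4. The larger step compensates
for the few (~12) minibatches per epoch at this cohort size; the full-scale
default keeps lr 1e-4. At this scale the four tasks train in roughly ten
minutes on one CPU.

## Unmixing and segmentation

MCR-ALS factorises the pixel × wavenumber matrix as `X = C·Sᵀ + E` with
`C, S ≥ 0`. Initialisation is a deterministic purest-pixel selection
(largest-norm spectrum first, then sequentially the pixel with the largest
residual after projection onto the chosen spectra — SIMPLISMA-like, no
random seed needed). Each half-step solves exact non-negativity-constrained
least squares; with K ≤ ~8 components the active set is found by
enumerating passive subsets, vectorised over pixels (a clipped
unconstrained solve is available by flag). The scale ambiguity is fixed by
unit-maximum pure spectra; permutation and per-spectrum scale remain the
only indeterminacies, so recovery metrics are computed after best
permutation matching. Convergence: relative lack-of-fit change < 1e-6 or
500 iterations (or lack-of-fit < 1e-9 %, the exact-reconstruction case);
the lack-of-fit trace is non-increasing because each half-step is an exact
constrained minimiser. The number of components K is user-set (default 2
both for margin maps — carcinoma vs parenchyma — and for slice maps —
protein vs lipid); a scree-style lack-of-fit-vs-K sweep can be produced by
calling the decomposition at successive K.

HCA: Ward linkage on Euclidean distances of (preprocessed) pixel spectra;
cluster identity is made deterministic by numbering clusters in decreasing
mean total intensity. Maps beyond a pixel budget (default 4096) are
clustered on a deterministic evenly-spaced subsample with the remaining
pixels assigned to the nearest cluster mean. Z-stacks are reconstructed by
greedily matching components across planes by cosine similarity of the pure
spectra.

## Serology

AFP values are drawn per patient from a two-component log-normal mixture
truncated at the 200 ng/ml positivity threshold by inverse-CDF sampling, so
the expected positive fraction among HCC patients equals the configured
rate (default 25/92) exactly; ICC patients draw from the sub-threshold
component. Sensitivity is reported as positives/HCC-total × 100 to one
decimal; AUCs are reported to three decimals.

## Numerical and degenerate-input conventions

- Spectra identically zero or containing non-finite values are rejected at
  the preprocessing boundary; non-finite matrices are rejected by the
  unmixing entry point.
- A t-test on two zero-variance groups returns p = 1 when the means agree
  (no evidence), p = 0 when they differ (infinite effect).
- Pearson correlation of a constant band is reported missing (NaN) and the
  band is placed last in the dendrogram ordering.
- ROC/AUC are reported missing for single-class truth and for tasks with
  more than two classes.
- The pooling rule is floor division; an odd trailing element is dropped.

## Known limitations

- Training the full-width network at the full cohort size is a
  multi-hour CPU job; the desk-scale profile is the tested configuration.
- The generator's patient heterogeneity is a single multiplicative factor;
  real inter-patient variation also moves band positions and widths.
- MCR-ALS active-set enumeration scales as 2^K per offending pixel batch;
  for K beyond ~8 the clipped variant is the practical choice.
- No wavenumber recalibration or resampling: datasets must share an axis.
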