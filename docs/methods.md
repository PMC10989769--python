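# Methods

This note documents the models and procedures implemented in `ramavit`,
the default parameters and why they were chosen, what the synthetic-data
generator does and does not emulate, and the known limitations.

## Spectral model and preprocessing

A single-cell Raman spectrum (SCRS) is stored as a strictly ascending
wavenumber axis (cm⁻¹) with matching intensities. The default synthetic
axis is 320–3400 cm⁻¹ at 1 cm⁻¹ spacing; real instruments vary, so all
band positions are configurable and resampling is linear with no
extrapolation.

Preprocessing (`ramavit.preprocess`) is a deterministic chain:

1. **Crop** to 600–3100 cm⁻¹ — keeps the fingerprint region
   (600–1800 cm⁻¹), the cell-silent region (1800–2040 cm⁻¹), and the C–D
   (2040–2300 cm⁻¹) and C–H (2800–3100 cm⁻¹) bands.
2. **Despike**: points more than 6 robust SDs above a 5-point running
   median are replaced by that median (cosmic-ray removal).
3. **Smooth**: Savitzky–Golay, window 11 points, order 3. The window is
   narrow relative to the generator's narrowest fingerprint peaks
   (σ ≥ 4 cm⁻¹), so band areas are preserved to well under 1%.
4. **Baseline**: iterative clipped polynomial fit (fit, clip the working
   spectrum to min(spectrum, fit), repeat ×50), followed by a refit of
   the polynomial by ordinary least squares on non-peak points (residual
   below 3 robust SDs). The refit step matters: the clipped iteration
   alone converges to the *lower envelope* of the noise and oscillates
   slightly between peak-dense and empty regions; refitting on background
   points puts the baseline through the middle of the noise, which makes
   band integrals unbiased. Polynomial order defaults to 4 — on wide
   windows with a peak-dense left third, order-5 fits tilt visibly
   (≈0.05 CDR error on synthetic truth) while order 4 recovers band
   areas to ≤0.1%.
5. **Offset**: subtract the median of the silent region so residual noise
   is centred on zero.
6. **Normalise**: divide by summed positive intensity over 600–3100 cm⁻¹.
   Band *ratios* (CDR) are invariant to this; classification needs the
   common scale.

**SNR** is defined as the peak C–H intensity divided by the noise SD in
the silent region, with 0/0 → 0 so blank spectra fail screening rather
than crash. Quality screening keeps cells with SNR ≥ 5 by default.

## Viability and vitality statistics

With band areas `A_CD` (2040–2300 cm⁻¹) and `A_CH` (2800–3100 cm⁻¹),
negative intensities clipped before trapezoidal integration:

* `CDR = A_CD / (A_CD + A_CH)` ∈ [0, 1]; 0/0 → 0.
* `MAL = CDR_sample − CDR_0h`; `rMAL = MAL / MAL_control` with the
  control measured at log phase (rMAL(control) = 1, rMAL(0 h) = 0).
* `HI = SD(MAL)` across cells, n−1 denominator, defined for n ≥ 2.
* live ⇔ `MAL > margin`, margin 0 by default in `call_viability`.

Because integration clips negative noise, an *empty* band still
accumulates a small positive pedestal. `compute_cdr` therefore measures
the mean clipped level of the silent region — which carries no Raman
bands — and subtracts its contribution from both band areas
("noise-floor correction"; exactly zero for noiseless input). Without
it, truly inactive cells read CDR ≈ 0.01 at realistic noise.

**Live/dead margin.** The strict `MAL > 0` rule is kept as the formal
definition, but for a cell with *zero* uptake the measured MAL is a
zero-mean noise variable, so the strict rule misclassifies half of the
dead cells regardless of SNR. The sample-level pipeline
(`analyze_sample`) therefore defaults to a detection-limit convention,
margin = 3 × SD of the 0-h reference CDR distribution (≈0.003–0.01 at
default noise): a cell is called live only when its CDR gain exceeds what
measurement noise alone produces. Pass `margin=0.0` to recover the
strict rule.

**Counting** follows the hemocytometer convention:
`total = mean(cells per field) × field_factor × dilution / mass`, where
`field_factor` encapsulates chamber geometry. The live count is
`total × viable rate`; species-resolved counts split it by the estimated
proportions and conserve the total exactly. `survival_rate` is a plain
ratio of counts with a warning above 1. `plateau_time` returns the
earliest time after which every consecutive increase of the live-fraction
series is below ε, breaking ties toward the earliest qualifying time.

## Species identification

The classifier is a one-dimensional residual network with 18 weighted
layers: a stem convolution (kernel 21), eight residual blocks of two
convolutions each (kernel 11) — 17 convolutional layers — and one fully
connected softmax head. Channel width doubles and sequence length halves
(stride 2) every two blocks; shortcuts are parameter-free (stride-2
subsampling plus channel zero-padding), so the conv-layer count is
unaffected by the skip paths. Batch normalisation follows each
convolution (not counted as a weighted layer, following the usual ResNet
convention). There is no global average pooling: the flattened final
feature map feeds the head directly, preserving where in the spectrum
each peak lies.

Defaults: input = fingerprint region 600–1800 cm⁻¹ resampled to 300
points and per-spectrum standardised; base width 4 channels (→ 8, 16,
32); Adam, lr 10⁻³, batch 64, 12 epochs, cross-entropy, fixed seed. The
network is implemented in numpy (tap-loop convolutions that run as BLAS
contractions; gradients hand-derived and covered by numerical-gradient
tests). Width and epoch count were sized so that the full 21-class
reference training (3150 spectra) completes in a few minutes on one CPU
core; on the generator's default separability this configuration reaches
≈100% held-out accuracy, so no capacity is sacrificed at desk scale.
Argmax ties resolve to the lowest class index. Training requires ≥ 2
classes and ≥ 2 spectra per class.

Baselines: random forest (200 trees) and RBF-kernel SVM with probability
outputs, over the same resampled features.

**Evaluation** uses stratified random 70/30 splits repeated 3 times
(re-drawn, max 10 attempts, if a class misses the test fold), reporting
per-split accuracy mean ± SD (n−1) and a pooled row-normalised confusion
matrix.

**Proportions and consistency.** Community composition is the class
frequency among (optionally live-only) predicted cells. Consistency with
expected proportions uses the χ² statistic Σ(Oᵢ−Eᵢ)²/Eᵢ with
Eᵢ = n·pᵢ. The default cutoff is the conventional 11.070 — the upper-5%
χ² point at 5 degrees of freedom, kept literal because it is the
established decision value for the five-strain comparison; note that a
five-category test formally has 4 df (cutoff 9.488), so a `df_mode` that
derives the cutoff from k−1 df is provided for other panel sizes.

## Cell segmentation

Edge-based segmentation: Sobel gradient (Otsu threshold by default) or
Canny edges, then morphological closing (disk radius 2), hole filling
and small-object removal. The dilated-convolution network (DCN) is a
six-convolution 3×3 encoder with dilation rates 1, 2, 4, 8, 1 plus a 1×1
two-class head (receptive field ≈ 33 px, larger than any cell), trained
per-pixel with Adam (lr 6·10⁻³, 250 epochs, 12 channels). Impurity
pixels are trained as *background* with loss weight 0.2, teaching the
network to reject debris; cells and background weigh 1.0. Training to
convergence matters here — the bright, small impurity speckles are only
distinguished from cells by context, which the network learns late.

`locate_cells` labels connected components (≥ min_area) and, with
`split_touching`, separates fused blobs by a distance-transform watershed
seeded at distance peaks. Centroids are 0-based (row, col).

Pixel metrics use the standard definitions over TP/FP/FN/TN counts
(truth label 2 collapsed to background first): ACC=(TP+TN)/N,
IoU=TP/(TP+FP+FN), FPR=FP/(FP+TN), FNR=FN/(FN+TP), OER=(FP+FN)/N, so
ACC+OER=1 identically. Empty∪empty conventions: IoU=1, FPR=FNR=0.

## Synthetic-data generator

`ramavit.synth` emulates the study conditions end to end:

* **Fingerprint profiles**: 6–12 Gaussian peaks per species, centres
  620–1780 cm⁻¹, σ 4–12 cm⁻¹, amplitudes 0.2–1.0, drawn deterministically
  from (species, seed) via a stable hash. Reference panels redraw any
  profile whose noiseless fingerprint has cosine similarity ≥ 0.95 with
  an earlier one; real inter-strain spectral distances are unknown, so
  this separability cap is an exposed knob, not a claimed fact.
* **Uptake kinetics**: the C–D area fraction is
  `f = cdr_max · vitality · (1 − e^{−k t})` with k = 1.5 h⁻¹ and
  cdr_max = 0.2, a saturating law that plateaus by 3 h of incubation, in
  line with the assay's observed time course. The C–H band carries the
  complementary (1−f) share of a fixed total area, so the true CDR
  equals f exactly before noise. Dead cells have vitality 0 and hence no
  C–D band.
* **Vitality**: live/dead ~ Bernoulli(live fraction); live-cell vitality
  ~ Beta with the requested mean and concentration 10 (unimodal,
  realistic spread without mass at 0).
* **Noise and baseline**: quadratic baseline drift plus white Gaussian
  noise scaled to a target SNR of 50 (high-quality acquisition after
  screening). Ground truth (live flag, vitality, analytic CDR) travels
  in `meta.extra` for recovery tests.
* **Images**: rods as rotated ellipses (semi-axes 5–9 × 1.5–3 px) placed
  with a 1-px exclusion moat (no touching), impurity speckles (label 2)
  at ~0.2% pixel rate, Gaussian blur σ 1 and sensor noise σ 0.03 on
  64×64 frames; truth masks are exact pre-blur.

What it does *not* emulate: physical Raman cross-sections, instrument
line-shape and wavenumber-calibration drift, fluorescence backgrounds,
cell-cycle or physiological spectral variation within a species, cell
adhesion in images. Passing recovery tests therefore demonstrates the
pipeline's correctness and statistical behaviour under controlled
conditions, not instrument-level performance on real products; accuracy
figures measured on this generator (e.g. near-perfect 21-class ID) are
upper bounds set by its separability knob, not predictions for real
strain panels.

## Numerical and design choices

* Wavenumber units are cm⁻¹ throughout; no unit conversion.
* File dialect: UTF-8 CSV/TSV auto-detected, `#` comments; two-column
  per-cell files or wavenumber × cells matrix files plus a metadata
  manifest; parse errors name file and line.
* Band integrals clip negatives first (areas are nonnegative by
  construction); CDR conventions: 0/0 → 0.
* All randomness flows from explicit integer seeds through
  `numpy.random.Generator`; identical seed + config reproduces outputs
  bit for bit, including network training.
* Degenerate inputs: empty ramanomes are valid and round-trip; rMAL with
  control ≤ 0-h baseline raises ("degenerate control"); plateau-less
  series return the last time with a warning; survival > 1 warns.

## Problem sizes

The self-validation benchmark trains the 21-class CNN on 150 spectra per
class and classifies eight 400-cell mocks; the segmentation benchmark
trains the DCN on twenty 64×64 images and evaluates on four held-out
ones; spectral recovery properties use 1000 simulated spectra. These
sizes run comfortably on a single CPU core and, on the generator's
default conditions, already saturate the attainable accuracy.

## Known limitations

* The strict MAL > 0 viability rule is noise-sensitive at exactly zero
  activity; the pipeline's LOD-style margin (above) is the practical
  default and is reported alongside results.
* The χ² cutoff 11.070 is a fixed convention, not a per-panel critical
  value; use `df_mode` for panels of other sizes.
* The CNN is trained per reference panel; there is no transfer across
  instruments or open-set rejection of species absent from the panel.
* Absolute counts inherit the uncertainty of the microscopy field counts
  and of `field_factor`; the package propagates neither.
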