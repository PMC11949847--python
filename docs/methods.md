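# Methods

This note documents the models, numerical conventions and design choices
behind `gradefusion`, in the spirit of a package methods appendix. It
states no empirical result that the test suite or the acceptance script
does not itself compute.

## The synthetic world

The pipeline is exercised on simulated data whose defaults state the
emulated experimental design: three quality grades, 15 samples per grade,
each sample observed by a nine-sensor MOS e-nose and one RGB image.

**E-nose curve family.** A recording covers 300 s at 1 Hz: baseline
(0–200 s), headspace injection (200–240 s), recovery (240–300 s). The
noise-free fractional response of sensor *s* to grade *g* is

- baseline: `y = 0`
- injection: `y = A[s,g]·(1 − exp(−(t − 200)/τ_rise[s]))`
- recovery: exponential decay from the 240 s value with `τ_fall[s]`,

and the voltage is `V = V0·(1 + y) + ε`, `ε ~ N(0, noise_sd·V0)`. The
saturating-rise / exponential-decay family is the simplest shape consistent
with published MOS-sensor response curves; it is a modeling choice, not a
measured instrument property. Defaults: `V0 = 1 V`; per-sensor full-strength
amplitudes 0.65–1.20 (fractions of baseline) attenuated by grade factors
(1.0, 0.70, 0.45), so Grade1 > Grade2 > Grade3 for every sensor — the
grade-ordered aroma-intensity structure the analysis assumes;
`τ_rise` 10–20 s, `τ_fall` 20–32 s; `noise_sd = 0.01` (a high-SNR bench
instrument). The instrument's true voltage ranges and noise were never
published; these are realistic placeholders exposed in `SyntheticConfig`,
not claims.

**Images.** Each image is a white-ish background densely covered by
rotated ellipse primitives laid on a jittered grid (grid step 0.85·r,
semi-axes 1.0–1.5·r, center jitter ±0.25·r), guaranteeing the central
400×400 crop never sees background. Primitive fill colors are drawn around
a per-grade CIELAB base color (capsules: green / yellow / pale-shriveled;
seeds: black / brown / yellow-red) with sd ≈ 3 Lab units (chroma jitter
scaled by 0.6), then the image is Gaussian-smoothed (σ = 1 px). The
per-grade primitive radius (`texture_scale`) makes co-occurrence texture
grade-dependent. The generator is deliberately primitive-composited rather
than photorealistic: the analysis consumes only channel moments and GLCM
statistics, so the generator targets those feature distributions and
nothing else. Default canvas 512×512: the extractor only reads the central
400×400, so a full-camera-resolution canvas would add runtime without
information. What a green test therefore establishes: the pipeline
machinery (extraction → selection → fusion → evaluation) is correct and
the stated statistical structure is recovered. What it does not establish:
performance on real produce — real capsule morphology, illumination,
drift, humidity and inter-sample chemistry are all outside the generator.

**Determinism.** All randomness flows through one
`numpy.random.Generator` seeded from `SyntheticConfig.seed`; identical
(config, seed) reproduce datasets bit for bit. Voltages are floored at
1e-6 V to keep them strictly positive even at absurd noise settings.

## E-nose features

Fractional normalization uses `V0 =` the per-sensor mean over the final
10 s of the baseline (the method's reference span is a convention; it is
exposed as `baseline_span`). The extraction window "201–240 s" is read as
the 40 samples at t = 201..240 inclusive at 1 Hz. Conventions:

- `T_im` is measured from the window start, first occurrence of the
  maximum on ties. (Measuring from injection onset instead would shift
  every sample equally and carry identical class information.)
- `S_asce` is the mean of instantaneous slopes up to the first maximum —
  for uniform sampling this equals the chord slope — and is defined as 0
  when the maximum is the first window sample (empty ascending segment).
- `INV` uses the trapezoidal rule.
- `S_max ≥ MDCV` always (max ≥ mean); `S_max ≥ S_asce` whenever the
  ascending segment is non-empty.

Features are scale-equivariant: multiplying all voltages by c > 0 leaves
every feature unchanged because `V0` scales too.

## Image features

Color: HSV via the standard hexcone transform (H, S, V ∈ [0,1]); CIELAB
via sRGB → linear RGB → XYZ (D65, 2°) → L*a*b (L ∈ [0,100]), both from
scikit-image. Per channel: mean, sample sd (n−1), skewness `m3/m2^1.5`,
kurtosis `m4/m2²` (normal ⇒ 3; biased central moments, the common toolbox
convention); when `m2 < 1e-12` skewness and kurtosis are defined as 0.
Feature names follow the `<Channel>_<stat>` convention with a*/b* written
`As`/`Bs`.

Texture: grayscale uses the luma weights 0.2989/0.5870/0.1140; [0,1] is
linearly quantized into 8 equal gray bins (the common toolbox default,
configurable). For each of the four unit-distance offsets the raw pair
counts are accumulated per the co-occurrence definition (out-of-bounds
neighbors skipped), symmetrized as `P + Pᵀ`, averaged over directions and
normalized to sum 1. Symmetrizing before averaging makes the marginals
equal, which the texture formulas assume. The 16 descriptors use 1-based
level indices, logs base 2 (entropies in bits), `0·log 0 := 0`,
correlation := 0 when the marginal variance is below 1e-12, and
sum-variance centered on the **sum-average** (the modern convention; the
historical definition centered it on sum-entropy). Homogeneity uses the
`1/(1+|i−j|)` kernel and inverse difference moment `1/(1+(i−j)²)` — the
two names are sometimes conflated in the literature, so the assignment is
fixed here explicitly. Direction averaging makes the full 16-vector
exactly invariant under 90° image rotation.

## CFS

The merit of a subset S of size k is

    M_S = k·r̄_cf / sqrt(k + k(k−1)·r̄_ff)

(with r̄_ff := 0 for k = 1). Some renderings of this formula omit the
radical; without it the index is not the cited CFS merit and collapses for
large k, so the radical form is implemented. Correlations are symmetrical
uncertainty `SU = 2·[H(X)+H(Y)−H(X,Y)]/[H(X)+H(Y)]` (logs base 2, SU := 0
when both entropies vanish) computed on Fayyad–Irani MDL-discretized
features: recursive binary splitting on class-information gain, a split
accepted only when the gain exceeds
`[log2(n−1) + log2(3^k − 2) − (k·E − k1·E1 − k2·E2)]/n`. Features the MDL
criterion leaves uncut become single-bin and have SU = 0 with everything —
CFS then ignores them, which is the intended null behavior.

Search: forward best-first from the empty set with an unbounded open list.
"Five consecutive non-improving subsets" is counted as five consecutive
**node expansions** that fail to strictly improve the incumbent merit
(tolerance 1e-10) — counting evaluated children instead would stop much
earlier on wide tables. Ties break toward smaller subsets, then
lexicographic feature order, making the selection invariant to column
order. Joint-entropy counts are sorted before summation so
`SU(x,y) == SU(y,x)` holds exactly in floating point.

## Classifiers and evaluation

**SVM.** scikit-learn's one-vs-one SVC with per-pair Platt calibration for
probabilities; features are standardized (zero mean, unit variance, fit on
the training part only). Kernels: polynomial `(x·y + 1)^d`, its normalized
variant `K(x,y)/√(K(x,x)K(y,y))`, RBF, and the Pearson VII universal
kernel

    K = 1 / [1 + (2·‖x−y‖·sqrt(2^{1/ω} − 1)/σ)²]^ω,

with defaults ω = σ = 1, C = 1, d = 2. The study never published its
hyperparameters; these toolkit-style defaults are surfaced in
`ClassifierSpec`. With ~10² standardized features, pairwise distances are
large relative to σ = 1 and the PUK Gram matrix approaches identity — the
raw-feature SVM is then near chance while the CFS-reduced SVM recovers;
this mirrors, rather than contradicts, the reported behavior of the
original models.

**Bayesian network.** Features MDL-discretized; the class is a parent of
every feature; K2 search (node order = column order, Cooper–Herskovits
score) may add at most one extra parent per feature from earlier columns.
CPTs use additive smoothing α = 0.5. Bin edges are fixed at fit time, so
prediction never meets an unseen bin.

**Decision tree.** Binary threshold splits on single numeric features
chosen by gain ratio (C4.5 criterion), `min_leaf = 2`; reduced-error
pruning grows on a stratified 75% of the training data and replaces any
subtree whose leaf does no worse on the held-out 25%. Leaf probabilities
are Laplace-smoothed. (scikit-learn's trees offer neither gain ratio nor
reduced-error pruning, hence the in-package implementation.)

**Protocol.** Stratified 70/30 split with per-class
`floor(0.7·n_c)` calibration samples — 15 per grade gives the 10/5
calibration/evaluation marginals. Calibration metrics pool stratified
10-fold CV predictions (fold count reduced with a warning if a class has
fewer than 10 calibration samples); evaluation metrics come from a model
fit on the full calibration set. Probabilistic RMSE is
`sqrt(Σ_samples Σ_classes (p̂ − 1{true})²/(n·C))` — 0 for perfect
probabilities, `sqrt(2/9) ≈ 0.4714` for uniform three-class predictions,
at most `sqrt(2)`. Predicted labels are the row-wise argmax with
first-index tie-break.

## Known limitations

- The generator omits sensor drift, temperature/humidity coupling,
  real morphology and illumination effects; accuracies on the synthetic
  world say nothing quantitative about laboratory data.
- The discretization-based SU treats features marginally; interactions
  detectable only jointly can be discarded by CFS.
- K2 is restricted to one extra parent with a fixed column ordering;
  richer structure searches (genetic, hill-climbing, annealing) are out of
  scope.
- WEKA/MATLAB bit-exactness is a non-goal: conventions are documented
  above and fixed, but internals (SMO updates, J48 heuristics) differ.
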