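# Methods

This note documents the models, numerical choices and open design
decisions behind `usplane`, in the order the pipeline runs them.

## Preprocessing

Images carry a declared range: 8-bit integers 0–255 or reals in
[0, 1]. The chain runs in the fixed order resize → crop → equalize →
despeckle → normalize; each stage can be disabled, which is how the
despeckle ablation is run.

* **Resize** scales by the largest factor that fits the target frame
  when the aspect ratio is preserved and zero-pads bottom/right, so
  output dimensions always equal the targets. Bilinear interpolation
  with Gaussian anti-aliasing on downscale keeps block means within
  one gray level of an area-averaging reference. Default target
  224×224 (a common imaging default; the pipeline skips resizing for
  synthetic images generated at their working size).
* **Crop** takes user-supplied 0-based half-open boxes
  [x, x+w) × [y, y+h); there is no automatic annotation detection.
* **Histogram equalization** maps intensity v to round(255·cdf(v))
  over 256 bins — monotone, so pixel order relations are preserved.
  It is defined only on integer images; the chain therefore equalizes
  before normalizing.
* **Despeckle** is a median filter (default 3×3, edge replication).
  The filter family is a package choice: the median is the standard
  rank-order answer to impulsive multiplicative noise and cannot
  create intensities outside the input range. Window size is
  configurable.
* **Normalization** is the affine map (p − min)/(max − min); a
  constant image maps to all zeros by declared convention.
* **Balancing** reaches an exact per-class target (default 1050) by
  random subsampling without replacement above the target and random
  duplication below it — no synthetic interpolation. Kept records
  preserve their original order; results are bit-identical per seed.

## GLCM features

A normalized symmetric co-occurrence matrix is built per angle at one
distance: pair counts at the rounded displacement
(d·sin θ, d·cos θ) are accumulated in both directions and divided by
the pair total (construction delegated to scikit-image). Defaults:
distance 5, angles {0°, 30°, 45°, 90°, 135°}, 8 gray levels from
uniform binning of the normalized image (1.0 assigned to the top
bin). Eight levels keep the d = 5 matrices well populated on 64×64
frames; 16/32/256 are available.

Nine descriptors per matrix, 45 per image, ordered angle-major. Two
conventions are deliberate and worth flagging:

* **ASM is the quartic sum** Σp⁴ while energy is the classical Σp².
  The quartic form is preserved intentionally (it is a strictly
  sharper concentration measure and keeps the two features distinct);
  classical usage would call Σp² the ASM.
* **Entropy uses log base 10** (configurable to natural log), with
  0·log 0 := 0.

The marginal standard deviation is *not* a feature: under a symmetric
GLCM it is a deterministic monotone transform of the marginal
variance and adds no information; dropping it is what makes the count
nine. Correlation of a matrix with zero marginal deviation is defined
as 0. Marginal moments use the i-marginal, which equals the
j-marginal by symmetry.

## Wrapper feature selection

All three optimizers evolve continuous positions initialized
U(−1, 1); masks arise from the stochastic sigmoid transfer (bit j set
iff sigmoid(x_j) > u_j, u_j ~ U(0, 1); an empty mask is repaired by
forcing the largest-sigmoid bit). The fitness weights (0.9 accuracy,
0.1 sparsity) follow common wrapper practice; the internal evaluator
is a 1-nearest-neighbor classifier on a stratified 70/30 split drawn
once per run from the config seed, making the objective deterministic
and cacheable. The trained network itself can be substituted as
evaluator at higher cost.

* **PSO**: v ← w v + c1 r1 (pbest − x) + c2 r2 (gbest − x), x ← x + v,
  with c1 = c2 = 2, inertia decaying linearly 0.9 → 0.4, fresh r per
  dimension, velocities clamped to ±6 (the sigmoid saturation range).
* **GWO**: the canonical rules A = 2a·r − a, C = 2r with a decaying
  linearly 2 → 0; D_L = |C x_L − x|, guide x_L − A·D_L per leader,
  new position the mean of the three guides. Leaders (α ≥ β ≥ δ by
  fitness) are the best three evaluations seen so far and are held
  fixed within an iteration.
* **Hybrid (PSOGWO)**: the GWO guide points replace the PSO
  attractors inside a three-term velocity,
  v ← w·(v + c1 r1 (x1 − x) + c2 r2 (x2 − x) + c3 r3 (x3 − x)) with
  c3 = 0.5, following the published HPSOGWO scheme in which the
  inertia weight damps the attraction terms as well. The alternative
  reading that applies w to the old velocity only was measured to
  converge roughly an order of magnitude slower on the 5-D sphere
  benchmark (≈10⁻³–10⁻² vs ≈10⁻⁸ after 100 iterations); the
  published form is used.

The global best is tracked over every evaluation, so the per-iteration
best-fitness history is monotone non-decreasing by construction. A
`target_k` mode returns the best mask of exactly k bits for users who
want a fixed feature budget (e.g. 25 of 45); otherwise the subset
size is an emergent outcome — on the synthetic benchmark the hybrid
typically keeps 8–12 of 45.

## The classifier

Fuzzy C-means (fuzzifier m = 2, seeded random membership
initialization, alternating updates until the objective changes by
< 1e−6 or 300 iterations) clusters the z-scored training features.
Features are standardized before clustering because the descriptors
span several orders of magnitude (contrast vs ASM) and would
otherwise dominate the distance geometry; the scaler is stored in the
model. Hidden-unit centers are the plain membership-weighted means
and widths the membership-weighted mean squared distances, floored at
1e−8 so collapsed clusters still define a Gaussian unit.

The output layer is trained in the dual: with Gaussian kernel
K(x̃_i, x̃_j) = exp(−γ‖x̃_i − x̃_j‖²) *on the hidden-layer outputs* (a
deliberate double nonlinearity, exactly as the optimization model is
derived), the problem is a concave QP over the probability simplex
{α, α* ≥ 0, Σα + Σα* = 1}. Notes:

* ε is never solved for explicitly: the simplex normalization
  internalizes the 2λε objective term. An *effective* ε — the largest
  training residual among samples whose dual variables are inactive —
  is reported for diagnostics only.
* Slacks recover as ξ_i = α_i μ n, ξ*_i = α*_i μ n. Looser slack
  penalties (larger μ) never reduce the count of materially active
  slacks, a monotonicity that is tested.
* Prediction uses the underlying Gaussian kernel K, not the 2n×2n
  training block matrix K̃ — the block matrix exists only inside the
  dual; a test-point kernel evaluation necessarily means K.
* Multiclass is one-vs-rest with ±1 targets per class and an argmax
  over the six decision values, ties broken toward the lowest class
  index. A binary sign rule is the two-class special case.
* The Σ(α + α*) = 1 normalization (rather than per-sample box
  constraints) is unusual but implemented exactly as specified; its
  consequence is that dual mass concentrates on few support samples.

**QP solver.** K̃ is positive definite (Gaussian kernel plus the
μn/λ diagonal shift), so the solution is unique. The solver is FISTA
with adaptive restart and exact Euclidean projection onto the
simplex; the step is 1/L with L = 2·λ_max(K̃) from a dense symmetric
eigensolve (cheap at the model sizes used). Termination at KKT
complementarity residual < 1e−8, warning above 1e−6; agreement with a
generic SLSQP solve is ≤ 1e−6 in objective on random instances.

**Defaults** (all config-exposed, chosen as round, well-conditioned
values since nothing pins them): M = 20 hidden units, m = 2, λ = 1,
μ = 0.1, γ = 1/M. Gradient-descent training of a conventional RBF
output layer is deliberately out of scope; only the dual-trained
variant is implemented.

## Metrics

Eight per-class one-vs-rest metrics plus their unweighted macro mean.
FRR and FAR are computed as 1 − sensitivity and 1 − specificity — the
same value as FN/(TP+FN) and FP/(TN+FP) but exact in floating point,
making the complement identities hold to equality. Any 0/0 ratio is
0, and in that degenerate case both a rate and its complement are 0
rather than summing to 1. Classes requested but absent from the truth
labels are flagged and excluded from the macro average with a
warning. F1 and MCC use their standard textbook definitions.

## Synthetic data

**Images.** Each class is an anisotropic Gaussian random field: white
noise convolved with an oriented Gaussian kernel (σ = correlation
length along the major axis, one third of that across, truncated at
3σ), standardized, mapped to 128 ± contrast_scale, multiplied by
(1 + speckle) with zero-mean Gaussian speckle of configurable
variance, and clipped to 0–255. The six default classes step the
correlation length through 2, 4, 6, 8, 10, 12 px and the orientation
through 0°–150° in 30° steps, with contrast 60 and speckle variance
0.1 — strong enough that the despeckle stage matters, weak enough
that classes stay learnable; the ablation experiments regenerate the
same classes at variance 0.3. Short correlation lengths yield high
GLCM contrast at d = 5, long ones low, which is exactly the statistic
the features measure; at 20 images per class, well over 10 of the 45
features separate the classes with ANOVA F > 10. The generator
reproduces the published imbalanced class inventory at 1/10 scale by
default (309, 71, 104, 172, 163, 421), with full-scale counts
available.

What it does *not* emulate: anatomy, acoustic shadowing, attenuation,
depth-dependent resolution, vendor post-processing, or inter-patient
variability. Passing the synthetic benchmark shows the pipeline's
machinery is sound — features discriminate correlation structure,
selection finds compact subsets, the classifier separates them — not
that clinical-grade accuracy would transfer to real scans.

**Planted tables.** Informative column k raises the mean of one
designated class by `effect_size` (unit noise elsewhere); with 6
classes and 5 informative columns this is a one-hot code, so class
centroids are pairwise ≥ effect_size apart and every informative
column is individually necessary — dropping one merges its class
with the baseline. Necessity is the property that makes recovery
scoring meaningful: a sparsity-rewarding wrapper is entitled to drop
redundant columns, so a redundant design cannot be used to test
whether selection finds the signal. The flip side is that the
all-features 1-NN ceiling is modest (≈0.82 holdout at effect 4 with
40 noise columns) because every between-class margin is a single
column wide.

## Problem sizes and seeds

The test suite and the acceptance script run everything at desk
scale, chosen so the full suite completes in a few minutes on one
CPU: 64×64 images, 30 images/class (180 total) for the end-to-end
benchmark, five replicate seeds for every stochastic claim, selection
populations of 20 for 50 iterations (100 on the sphere benchmarks),
and dual QPs of a few hundred variables. All randomness flows from
explicit integer seeds; per-stage seeds in the pipeline derive
affinely from the run seed, and reruns reproduce the mask and model
artifacts byte for byte.

## Known limitations

* Whole-image features only; no patch/tiling mode, no multi-distance
  GLCM stacks, run-length, LBP or wavelet features.
* The wrapper fitness uses a single stratified holdout, not
  cross-validation; selection can overfit small tables.
* The simplex-normalized dual concentrates on few support samples;
  for large n per class a per-sample box formulation would likely be
  better conditioned, but is out of scope.
* No probability calibration, ROC analysis, or confidence intervals.
* The synthetic generator is a texture model, not an ultrasound
  simulator (see above).
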