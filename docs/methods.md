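# Methods

This note documents the models implemented in `hotspotseg`, the choices
made where the design was genuinely open, and what the synthetic
evaluation does and does not establish.

## The phantom generator

Clinical spinal MRI with expert lesion masks is not distributable with
this package, so all training and evaluation use synthetic slices that
reproduce four properties of sagittal T2-weighted spine images:

* **Banding** — alternating vertebra/disc intensity bands, modelled as a
  vertical sinusoid with 5 periods (configurable 3–6), mean 0.375,
  half-amplitude 0.05;
* **Bias field** — a smooth random low-frequency surface (coarse 4×4
  Gaussian grid upsampled by cubic splines), peak amplitude 0.03,
  standing in for coil-sensitivity inhomogeneity;
* **Lesions** — `n_hotspots` non-overlapping bright disks (radius 4–9 px,
  additive contrast 0.35) whose edges are softened by a Gaussian of
  0.8 px to emulate partial-volume blur; the ground-truth mask is the
  exact pre-blur disk;
* **Noise** — additive Gaussian noise, σ = 0.08 by default, clipped with
  the image to [0, 1].  Gaussian noise is a tractable stand-in for the
  Rician statistics of magnitude MRI; at these intensity levels the two
  are close.

Hot spots are bright, matching the radiological convention for
metastatic "hot spots" on T2/bone-scan reading.  Labels follow the
construction: lesion-bearing slices are level I, lesion-free slices are
level III, and level-II ("uncertain") slices carry lesions whose
contrast is drawn just above the noise floor (uniform in [2σ, 3σ]),
so their detectability is genuinely marginal.

Two defaults deserve justification:

* **Band amplitude 0.05.** The level-set segmenter fits a *two-phase*
  piecewise-constant model, so the planted lesion must be the globally
  optimal second phase.  With band half-amplitude `a`, background area
  `N_bg` and lesion area `N_les` at contrast `c`, the banded background
  costs ≈ `2·N_bg·a²` when merged into one phase while the lesion costs
  ≈ `N_les·(c−a)²` when merged into the background; for the default
  geometry the lesion split wins only when `a ≲ 0.05`.  Larger banding
  makes the dark-band/bright-band split the global optimum — a regime in
  which no two-phase method can succeed and which contradicts the
  operating point implied by this method family's published performance.
* **Noise σ = 0.08** (contrast-to-noise ≈ 4.4).  At σ ≤ 0.05 every
  segmenter saturates near Dice 0.95 and the benchmark cannot
  discriminate between them; at σ = 0.08 the documented failure modes
  (threshold speckle for Otsu, boundary leakage and missed seeds for
  region growing) actually operate, reproducing the well-separated
  performance regime this comparison is meant to study.

Image size defaults to 128×128 px; nothing in the methods depends on
the size, and the full train-and-evaluate cycle stays within CPU-minutes.
Everything is drawn from an explicitly seeded generator: identical
(spec, seed) pairs are bit-identical.

**What phantom results do not show.** The phantoms contain no anatomy
other than banding, no partial lesions at slice boundaries, no Rician
noise floor in dark regions, no motion or susceptibility artifacts, and
their lesion/background contrast is stationary.  Passing benchmarks here
demonstrates correctness and the expected *relative* behavior of the
methods, not clinical performance.

## Sparse-coding features

Dictionary learning alternates two exact partial minimizations of
`Σ_i ‖x_i − Σ_j c_ij φ_j‖² + λ Σ_ij |c_ij|`:

* **Codes:** cyclic coordinate descent with soft-thresholding; each
  coordinate update is the exact 1-D lasso minimizer.  Coding stops when
  a full sweep improves the objective by < 1e-9 (relative), which leaves
  each row within ~1e-6 of its lasso optimum on the problem sizes used.
* **Atoms:** sequential rank-1 residual fits projected to the unit
  sphere — for atom j the constrained minimizer of
  `‖R_j − c_j dᵀ‖²` over `‖d‖ = 1` in closed form.  A joint
  least-squares atom update followed by renormalization is the more
  common description but cannot guarantee a monotone objective (the
  renormalization rescales the ℓ1 term arbitrarily); the sequential
  update is exactly monotone, which the test suite asserts on every run.

Patches are mean-subtracted before coding.  This removes the bias field
and makes the features contrast-based; the cost is that featureless
lesion *interiors* look like background, so detection rests on
lesion-edge patches (see scanning below).  Defaults: patch side l = 8,
m = 64 atoms (24 in the desk-scale study configuration), λ = 0.1,
alternation stops at relative objective change < 1e-4.  Image-level
features pool |c| per atom by max and mean over a stride-4 grid
(a 2m vector); pooling magnitudes makes the features invariant to atom
sign flips, and max ≥ mean ≥ 0 by construction.

## Three-level triage

Classic discrete AdaBoost: per round a depth-≤3 CART (scikit-learn
`DecisionTreeClassifier`, Gini splits, weighted samples) is fitted,
weighted error ε_t computed, learner weight α_t = ½·ln((1−ε_t)/ε_t),
and the sample weights multiplicatively updated and renormalized.
Training stops early on ε_t ≥ 0.5 (learner discarded) or ε_t = 0
(perfect learner kept; its α uses ε floored at 1/(2n), the Laplace-style
smoothing, instead of diverging).  T = 100 rounds by default.

The signed vote sum (margin) is thresholded into three levels with a
band ±θ; θ is calibrated as the 10th percentile of |margin| on held-out
data, nudged just below the percentile so samples sitting exactly on it
remain decided.  On cleanly separable phantom cohorts a single depth-3
tree is often perfect, every margin collapses to ±α_1, and the uncertain
band effectively closes — level-II phantoms are then forced into I or
III (the reproduction script's triage accuracy of ≈78% on the 87-slice
cohort is exactly the 68 decided slices correct, all 19 marginal ones
misassigned).  This is a real property of margin-based uncertainty under
perfectly separable training data, not an implementation artifact; on
noisier feature distributions boosting runs many rounds and the band is
graded.

## Multi-instance detection and scanning

MILBoost with bag-level supervision only: instance probabilities
p = σ(m(x)) through a logistic link (the score-to-probability map left
open in most descriptions; the logistic link keeps the gradient of the
log-loss well defined), aggregated per bag by noisy-OR
(default, differentiable) or max (subgradient at the argmax).  Per
round, instance weights w = −∂Loss/∂m(x) are computed, a decision stump
is fitted to sign(w) with weights |w| (exhaustive scan over features and
cut points; ties go to the lowest feature index, then lowest threshold),
and its coefficient comes from a bounded line search on the loss
(β ∈ [0, 10]); a round that cannot improve the loss contributes β = 0.
The loss trace therefore never increases, which the tests re-verify
through an independent loss evaluation.

Bags: one per training image, 60 instances (desk scale), positive bags
drawing half their windows centred inside the ground-truth mask —
*which* instances are lesions is never revealed to the learner.
Negative bags come only from lesion-free images.  Instance features are
the code magnitudes |c| of the window's patch (length m).

Scanning slides the l×l window at stride 2 (clamped to ≤ l so coverage
has no gaps; the final row/column offsets are always included), scores
every window, and assigns each pixel the mean probability of all windows
covering it.  Because features are contrast-based, high scores
concentrate on lesion edges; coverage averaging fills lesion interiors
but also smears support outward by up to a window, so the map
over-covers lesions — the level-set stage is what sharpens this into a
boundary-accurate mask.

## Level-set segmentation

Inside is non-positive: Ω_a = {φ ≤ 0}.  This keeps the probability-map
binarization literal — φ0 = +g where p < ρ, 0 at equality, −g where
p > ρ — with high probability mapping to inside.  Defaults ρ = 0.5
(probability midpoint), g = 0.5, Δt = 0.13, λ_a = λ_b = 1.

Each step refreshes (g_a, g_b) with the exact region means, then takes
one explicit Euler step with velocity
`δ_ε(φ)·[μκ + λ_a(P−g_a)² − λ_b(P−g_b)²]` (signs such that pixels
unlike the inside mean are expelled), with δ_ε the smoothed delta
ε/(π(ε²+φ²)), ε = 1 px, or a sharp ±2-px narrow-band variant by flag.
Numerical choices:

* **Force normalization.** The data force is divided by its maximum
  magnitude each step.  On [0, 1] intensities the raw quadratic force is
  O(1e-2) and the binary ±g profile would need thousands of iterations
  per sign change; normalization is a CFL-style adaptive time step that
  rescales time without touching the descent direction.  A pixel still
  crosses zero only when the move lowers the fitting energy at the
  current means, and the means refresh is itself a descent step, so with
  μ = 0 the energy trace is non-increasing — asserted over hundreds of
  consecutive steps in the tests.
* **No reinitialization.**  φ is evolved directly from its binary ±g
  profile; no signed-distance reinitialization is performed.  With the
  bounded smoothed delta and the small amplitudes used this is stable,
  at the cost that |φ| drifts and the delta slowly widens — irrelevant
  here because evolution stops on mask stability, not on φ itself.
* **Stopping.**  max 500 iterations, or the mask unchanged for 10
  consecutive iterations *and* no pixel currently moving toward a sign
  change could reach it within the remaining budget (under these
  dynamics pixels flip in waves separated by quiet stretches, so mask
  quiescence alone fires long before convergence).
* **Curvature.**  The two-phase energy carries no length penalty, and
  μ = 0 is the literal default of `segment_cv`.  The pipeline
  configuration uses μ = 0.2 (central-difference curvature of the
  normalized gradient): on noisy images the pure data force flips
  isolated noise pixels, which drags g_a down and can cascade into
  large-scale over-segmentation; a small curvature term expels
  high-curvature speckle while leaving lesion-scale boundaries intact.
  μ = 0.2 was calibrated once on a development cohort and frozen.
* **Degenerate starts.**  If nothing exceeds ρ, a 3-px disk around the
  probability maximum seeds the contour (flagged in diagnostics); if a
  region empties mid-evolution, evolution stops with the current mask
  and a diagnostic flag rather than raising.

With λ_a = λ_b the converged decision boundary is the midpoint of the
region means, which makes the mask exactly invariant under affine
intensity rescaling (verified in tests).

## Baselines

* **Otsu** — threshold maximizing between-class variance over a 256-bin
  histogram of [0, 1]; ties go to the lowest qualifying threshold.  For
  the pipeline comparison the histogram is restricted to the detector's
  support dilated by a 10-px disk (whole-slice histograms are dominated
  by banding and swamp small lesions; a whole-image mode remains
  available).  The implementation is an explicit scan, cross-checked in
  the tests against both a brute-force oracle and scikit-image.
* **Region growing** — BFS from seeds, a pixel joining when its
  intensity is within τ = 0.15 of the running region mean (a frozen
  seed-value reference is available, and is the mode under which the
  τ-monotonicity property holds).  Seeds are one per connected component
  of the thresholded probability map (components under 8 px discarded as
  detector noise), placed at the brightest image pixel of the component —
  the natural seed for a bright lesion, which also self-limits the
  damage of a false component.  Fixed FIFO order makes growth
  deterministic.

Both baselines consume the same detection input as the level-set stage,
so the benchmark isolates segmentation quality.

## Evaluation

Dice and Jaccard per case, averaged per method over lesion-bearing
(level-I) cases; the report records that aggregation is per-case mean,
not pixel-pooled.  Two empty masks score 1.0 (correct rejection), empty
vs non-empty scores 0.0.  `D = 2J/(1+J)` holds to machine precision for
every pair, and both scores are symmetric — used as standing test
invariants.  Triage is reported as exact three-level accuracy, the
accuracy with uncertain reassignments (prediction II on a decided gold
case) excluded from the denominator, and binary TPR/FNR/FPR on the
present-vs-absent (I vs III) dichotomy, with empty denominators reported
as not-applicable.

## Problem sizes

The study configuration (`study_config`) uses a 24-atom dictionary on
6,000 patches, 30 triage rounds, 60 MIL rounds with 60 instances per
bag, and a stride-2 scan; cohorts are 34 training slices (20 lesion /
14 clean), 12 calibration slices, an 87-slice triage cohort (45/19/23)
and a 45-slice segmentation suite, all at 128×128.  These sizes keep a
complete train-and-evaluate cycle within a few CPU-minutes; enlarging
the dictionary or cohorts on these phantoms was not observed to change
any qualitative outcome.

## Known limitations

* The uncertain triage band degenerates on perfectly separable cohorts
  (see above); calibrating θ then cannot resurrect it.
* The probability map inherits a one-window-scale outward smear from
  coverage averaging; very small lesions (≲ window side) can merge into
  one component.
* Scanning encodes every window independently; a convolutional
  (shift-tied) dictionary with FFT coding would be faster and is out of
  scope.
* The level-set stage is 2-D, two-phase, single-channel; multi-slice
  stitching and multiphase variants are out of scope.
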