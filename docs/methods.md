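# Methods

This note documents the models, parameter choices and numerical
conventions behind `qdnntex`, and what its synthetic experiments do and
do not establish.

## Preprocessing

Images are 2-D float arrays in `[0, 255]` with `NaN` marking missing
pixels. The stage order is mean imputation → Gaussian smoothing →
min-max intensity normalization → uniform gray-level quantization.

* **Imputation** replaces each missing pixel with the mean of all
  observed pixels. Ordinary PNG/JPEG input has no missing values; the
  stage exists for robustness and is exercised through synthetic
  injection.
* **Smoothing** uses a reflective boundary so the frame does not darken,
  which matters because co-occurrence statistics are sensitive to edge
  gradients. `smooth_sigma` defaults to 1.0 px. Constant images are
  returned unchanged (exactly: the separable filter would otherwise
  leave ~1e-14 rounding residue).
* **Normalization** maps min→0 and max→1; a constant image maps to all
  zeros by convention so the operation is total. Because quantization
  follows normalization, the feature pipeline is invariant under affine
  intensity rescaling.
* **Quantization** uses `L = 32` gray levels by default (configurable to
  256). Full 8-bit co-occurrence matrices are 256 × 256 and far too
  sparse for small images or windows; 32 levels is the usual compromise
  between discriminative power and matrix occupancy.
* Motion correction and slice-timing compensation exist as named
  identity hooks only: they belong to volumetric registration tooling
  and are out of scope for 2-D texture analysis, but keeping the named
  stages preserves the pipeline's structure.

## Co-occurrence features

`compute_glcm` counts ordered pixel pairs at displacement `(d, θ)` with
the raster convention θ=0 → east, π/4 → north-east, π/2 → north,
3π/4 → north-west. Matrices are symmetric by default (transposed counts
added before normalization), making the descriptors consistent across
opposite directions. Six descriptors per matrix — contrast, energy,
correlation, homogeneity, entropy, dissimilarity — over the default grid
of four distances × four angles give a 96-vector in a fixed,
reproducible order (`d{d}_a{angle index}_{name}`).

Numerical conventions: entropy uses base-2 logarithms with an additive
`ε = 1e-12` inside the log (and a leading minus sign, so entropy is
non-negative and increases with texture randomness); correlation returns
0 when a marginal standard deviation vanishes (single-level images) and
is clipped to `[−1, 1]`; energy is the sum of squared probabilities
(angular second moment).

Whole-image matrices are the default. An opt-in sliding-window mode
(odd window size, default 9 when enabled) averages per-window feature
values; windows that cannot host the offset are skipped. Whole-image
extraction was preferred as default because windowed extraction is
quadratically more expensive and the two agree on homogeneous textures.

## Annealing engine

One Metropolis/geometric-cooling engine serves both optimizers, under a
minimization convention (maximizing `obj` minimizes `−obj`):

* acceptance `P = 1` for `ΔE ≤ 0` (ties accepted, which lets the chain
  drift across objective plateaus), else `exp(−ΔE/T)`;
* cooling `T ← γT` each iteration; defaults `T₀ = 1.0`, `γ = 0.95`,
  500 iterations, early stop below `T_min = 1e-6`;
* rejected proposals leave the chain state unchanged; the best-ever
  solution and the full trace (temperature, proposal energy, accepted
  flag, running best) are returned;
* all randomness flows through one seeded generator, so identical seeds
  give bit-identical traces. Temperatures are produced by iterated
  multiplication in a fixed order, so a trace can be checked exactly
  against `T₀·γᵗ` computed the same way.

## Feature-specific simulated annealing

Weights live in `[0, 1]` per feature — features are re-weighted, never
eliminated. The objective `a·accuracy − b·redundancy` uses
`a = 1.0, b = 0.5`; perturbations add i.i.d. `N(0, 0.05²)` to every
coordinate and clip to the unit cube; initial weights are uniform on
`[0, 1]ⁿ`, seeded.

The accuracy term is a **pluggable evaluator**. The default fits class
centroids on a seeded stratified 75 % of the samples and scores nearest-
centroid (Euclidean) accuracy on the remaining 25 %; exact distance ties
resolve to the lowest class index. Centroids are computed directly
(group means + distance argmin) so degenerate all-constant inputs —
e.g. all-zero weights — degrade gracefully to chance instead of
erroring. A full classifier can be plugged in for a slower,
higher-fidelity objective; the default exists because the annealer calls
the evaluator 500 times per fit. The hold-out split is fixed per fit
(seeded once), making the objective deterministic in `w`.

The redundancy term averages `|Pearson r|` over all unordered column
pairs, counting pairs with a constant column as zero while keeping the
full pair count in the denominator — so driving a useless column's
weight to zero genuinely lowers redundancy.

**Known limitation.** When the classes are so well separated that the
accuracy term saturates, the objective surface is nearly flat: the
redundancy term (which also penalizes mutually correlated *informative*
columns) becomes the only gradient, and the annealer's all-coordinate
random walk distinguishes informative from noise columns only
stochastically. The planted-recovery experiment in the acceptance script
measures exactly this: its win rate is high but not certain per seed.

## Quantum network

The register holds `N` input, `M` hidden and `K` output qubits
(`N = 4, M = 2, K = 1` by default; `N + M ≤ 14` enforced for state-
vector tractability; `K` is carried in the architecture but gates-free,
since the readout is classical). The forward pass is:

1. amplitude-encode each min-max-scaled feature `x` as
   `√x·|0⟩ + √(1−x)·|1⟩` (product state, first feature most
   significant);
2. Hadamard layer puts the hidden register into the uniform
   superposition;
3. a controlled-R_y(W[j, i]) for every input qubit `i` (control, active
   on `|1⟩`) and hidden qubit `j` (target), applied in fixed
   (i ascending, j ascending) order — the unitary realization of a dense
   input→hidden weight matrix (all such gates commute, but the order is
   fixed anyway for reproducibility);
4. exact Z-expectations `a_j = P(0) − P(1)` of the hidden qubits (no
   shot noise by design);
5. classical readout `ŷ = sigmoid(Σ_j V_j tanh(a_j))`; tanh respects the
   `[−1, 1]` expectation range and the sigmoid output feeds a clipped
   (1e-12) natural-log binary cross-entropy.

A dense-matrix oracle (explicit `2ⁿ × 2ⁿ` gate matrices) verifies the
simulator to 1e-10 for small registers; a batched float64 path (the
circuit is real-amplitude) accelerates training without changing any
result.

**Expressivity caveat.** Because the controls are active on `|1⟩`, a
sample whose scaled features all equal 1 leaves the hidden register
untouched, so every head outputs exactly 0.5 there, and `ŷ − 0.5`
cannot change sign at all for a single-feature head. A fixed 0.5
threshold on one head is therefore unreliable; the classifier trains one
head per class (also in the binary case) and predicts by argmax of the
head probabilities, which only requires relative ordering.

When more features are available than input qubits, the `N` columns with
the largest supplied relevance weights (the annealed feature weights in
the full pipeline) are selected; ties and the unweighted case fall back
to column order. Per-column min-max scaling to `[0, 1]` follows
selection, so the weights act as a ranking rather than a rescaling —
any constant column factor would be absorbed by the scaling anyway.
Constant training columns scale to 0.5 (the uninformative equal
superposition).

## Training

Simulated annealing over the flattened `(W, V)` vector is the primary
mode: initialization uniform on `(−0.1, 0.1)` (near-identity entangling
layer), Gaussian proposals with σ = 0.1 rad on every coordinate, energy
= mean binary cross-entropy of the forward pass. The optional gradient
mode estimates the batch-loss gradient by central differences (step
1e-4) and applies plain SGD with learning rate 0.01, 200 epochs, batch
size 32, seeded shuffling; `sa+gd` runs annealing first and refines with
gradients. One-vs-rest heads train independently with per-head derived
seeds.

Because proposals random-walk with σ = 0.1, parameter magnitudes much
larger than ~√(iterations)·σ are effectively unreachable within the
default budget; problems that need large readout weights (e.g.
single-feature binary tasks whose high class scales near 1) train
poorly. The four-class texture pipeline operates comfortably in the
small-parameter regime.

## Evaluation

Confusion matrices are `C × C` (rows true, columns predicted).
Binary metrics follow the standard definitions with the convention that
any 0/0 denominator yields 0. Multiclass precision / sensitivity /
specificity are macro one-vs-rest averages; "overall accuracy" (plain
fraction correct) is reported alongside, since the macro one-vs-rest
accuracy of a C-class problem equals `1 − 2·err/C` and is therefore
systematically higher than the plain accuracy. Folds are stratified and
seeded (default k = 5); feature weighting and classifier training see
only training-fold rows.

## Synthetic data

The image generator emulates the *statistical shape* of a four-class
staged-dementia MRI collection: balanced classes, 128 × 128 8-bit
grayscale, class identity carried by texture. Each class is a Gaussian
random field — white noise smoothed with a class-specific kernel sigma
(0.5, 1.0, 2.0, 4.0 px, strictly increasing) and scaled by a
class-specific contrast (1.0, 0.9, 0.8, 0.7) around mid-gray, then
clipped and rounded to 8-bit. Shorter correlation lengths give strictly
larger expected short-range co-occurrence contrast, so per-class mean
contrast is strictly ordered by construction — separability is planted,
making above-chance end-to-end classification achievable and testable.
An optional elliptical mask and missing-pixel injection exercise the
masking and imputation paths. The generator deliberately omits anatomy,
bias fields, Rician noise, JPEG artifacts and 3-D structure: passing
tests demonstrate that the pipeline recovers planted texture
separation, not that it classifies clinical MRI.

The feature-table generator plants `k` informative columns whose
class-conditional means are `class · effect` (unit within-class
standard deviation; adjacent classes separated by `effect` σ) among `m`
i.i.d. standard-normal noise columns, with a recorded ground-truth mask
and shuffled column order. Note the informative columns share one class
direction and are therefore mutually correlated — intentionally so (it
matches "several texture features track the same pathology"), but it
interacts with the redundancy penalty as described above.

## Problem sizes

The default experiment scale — 100 images per class at 128 × 128 with
5-fold cross-validation, and 10 trials of the 400-sample planted-recovery
experiment — was chosen so a complete from-scratch acceptance run finishes
in well under a minute on one CPU while keeping per-fold validation sets
at 80 samples (binomial SE ≈ 0.05 at accuracy 0.5). The test suite uses
smaller sizes for unit-level checks and the full scale only for the
end-to-end property.

## Reproducibility

A single global seed fans out to per-stage seeds through SHA-256 hashing
of the stage name (`derive_seed`), keeping stages statistically
independent but individually reproducible; all derived seeds are below
2³¹. Two runs of the full pipeline under one seed produce byte-identical
feature tables, model files and metrics.
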