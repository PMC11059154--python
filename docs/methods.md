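# Methods

## Optimizer

The snow leopard optimizer is a population metaheuristic over box-bounded
real vectors. Its update rules are given in the README; this note records
the choices the published update rules leave open and how this
implementation resolves them.

**Randomness.** A single seeded `numpy` generator drives a run. Draws are
consumed in a fixed member-major order — for each member in each phase:
one scalar `r`, then the per-dimension guide indices (motion) or one prey
index (preying). Because the classic and fractional variants differ only
in a deterministic position term, runs of the two modes with the same seed
consume identical draw sequences; this is what makes the `σ = 1`
equivalence exact rather than statistical.

**Guide and prey selection.** The guide `k` is redrawn per dimension,
uniformly over the other members. The prey is drawn uniformly from the
members with strictly lower cost than the mover; the incumbent best has no
such member and preys on itself, where the `sign(P_i − P_f) = 0` factor
suppresses the move. `sign(0) = 0` throughout, so exact cost ties never
move a member.

**Step-size integer.** `I = round(1 + r)` uses half-away-from-zero
rounding, giving `I = 2` exactly when `r ≥ 0.5`.

**Boundary handling.** Candidates are clamped (projected) onto the box
before the single objective evaluation. Greedy acceptance requires a
*strictly* lower cost.

**Fatality.** Survival is deterministic elitist truncation: parents and
cubs are pooled, stably sorted by cost (ties keep parents before cubs,
then lower index), and the best `N` survive. A probabilistic death
lottery would match the biological metaphor more closely but makes runs
irreproducible across library versions; determinism was preferred.

**Fractional memory.** The GL weights are generated by the recurrence
`c_1 = σ`, `c_{a+1} = c_a (a − σ)/(a + 1)` (the magnitudes of the
binomial-expansion terms of order σ), truncated at depth `M = 4`. The
sampling step of the underlying discrete derivative is one algorithm
phase. The memory ring stores only accepted position matrices, pushed once
at the end of each motion/preying phase; before the ring fills, missing
slots are padded with the initial positions, so a cold start behaves as if
the population had always been at its initial state. After fatality the
row identities of the population change (survivors are re-ranked), so
lag-`a` memory is aligned by row index, not by member identity — an
inherent property of memory-augmented population methods with selection.

**Defaults.** Population 60 and 120 iterations are the validation-protocol
settings used throughout; `F = 0.375` (the fraction of the prey distance a
leopard paces before lunging); `σ = 0.9` as the default fractional order;
`M = 4`. Population size must be even (breeding pairs members first-with-
last); odd requests are rejected rather than silently adjusted.

## Benchmarks

The registry carries the classic unimodal/multimodal suite (sphere,
rosenbrock, rastrigin, ackley, griewank, schwefel 2.26, step, quartic,
penalized 1/2) in their standard formulations with conventional bounds,
at user-selectable dimension (default 10). Every registered optimum is
verified by evaluation at the stated minimizer to 10⁻¹², except
schwefel 2.26 whose minimizer is transcendental and flagged
`optimum_exact=False`. The trial harness reports the mean and sample
(n−1) standard deviation of final best costs over `R` runs with
consecutive seeds; a failing optimizer adapter leaves a NaN cell and a
warning rather than aborting the table.

## Preprocessing

**Fuzzy denoising.** The published description fixes the signal flow
(memberships → fuzzy entropy → adaptive filtering) but not the membership
shapes, window, or filter family. This implementation uses the simplest
construction satisfying every stated property: the deviation
`δ = |x − median_w(x)|` against the window median (default window 3),
scaled by the image-wide median of δ (a robust spread estimate, floored at
one gray level), squashed through `μ_N = δ²/(δ² + 1)`; `μ_F = 1 − μ_N`;
per-pixel entropy `E = −μ_F ln μ_F − μ_N ln μ_N` with `0·ln 0 = 0` (the
continuous entropy integral discretized as a per-pixel sum). The filter
output is the convex blend `(1 − μ_N)·x + μ_N·median_w(x)`, rounded to
8 bits: constant regions are untouched (μ_N = 0), crisp impulses are
replaced by the local median (μ_N ≈ 1).

**BBHE.** The split level is `X_m = floor(mean)`; the sub-histograms at or
below and above `X_m` are equalized independently through their own
cumulative densities onto `[0, X_m]` and `[X_m+1, 255]`. The range
endpoints are the full dynamic range 0 and 255 (not the observed min/max)
— the standard convention, and the one that makes constant images fixed
points. Mapped values round half-up. The implementation builds a 256-entry
lookup table; tests compare it pixel-for-pixel against an independent
per-pixel counting oracle.

**SMOTE.** Synthetic minority samples are `z_i + γ(z_j − z_i)` with
`γ ~ U(0,1)`, `z_i` drawn uniformly from the minority class and `z_j`
uniformly from its `k = 5` nearest minority neighbors (Euclidean; `k` is
clipped to the available neighbor count). Generation continues until the
class counts are exactly equal. A singleton minority class is an error.
Neighbor search uses scikit-learn; the interpolation itself is authored
here.

## Hyperparameter objective and compact classifier

The tuning objective is `Obj = α₁·loss + α₂·error + α₃·params`. The raw
weights (0.5, 0.7, 0.2) are normalized to sum to one — the configuration
as stated mixes a sum-to-one constraint with weights summing to 1.4, and
normalization reconciles the two. The weights are fixed run configuration,
not decision variables: letting an optimizer choose the weights of its own
objective is degenerate (all mass flows to the easiest term). The three
terms are made commensurate: the loss is the *mean* per-sample
cross-entropy (so it is O(1) like the error rate), and the parameter count
is divided by the largest count the candidate space can decode to, giving
a fraction in (0, 1].

The candidate space is the unit cube [0,1]⁵, decoded deterministically to
conv-block count {1,2,3}, filters per block {4..32}, kernel size {3,5},
dense units {8..64}, and a log-uniform learning rate in [10⁻⁴, 10⁻¹].
`decode(encode(·))` is the identity on the grid. The classifier is a
small 1-D CNN written in numpy (valid-padding conv+ReLU blocks over the
feature vector treated as a one-channel signal, global average pooling,
one dense ReLU layer, softmax), trained with full-batch Adam for a fixed
budget of 80 steps from a seeded He initialization — an evaluation takes a
fraction of a second and is bit-reproducible. Its hand-derived gradients
are verified against central finite differences in the test suite. The
split protocol is a stratified 70/30 train/test split with a pinned
shuffle seed. The parameter count is computed analytically from the
architecture and asserted equal to the built network's actual size.

The six evaluation metrics (accuracy, precision, sensitivity, specificity,
F1, Matthews correlation ×100) follow their closed forms from the TP/TN/
FP/FN tallies; any zero denominator yields 0 together with a degeneracy
flag. The default MCC numerator is the standard `TP·TN − FP·FN`; the
non-standard variant `TP·TN − TP·FN` that appears in some reports is
available behind `alt_numerator=True`.

## Synthetic data

The phantom (64×64 by default) is an elliptical bright region plus a
45° high-intensity band on a dark background; a "tear" blanks a 9-pixel
gap at the band's center, so torn and intact phantoms differ only inside a
known mask. Gaussian or salt-and-pepper noise is applied after structure
rendering and clipped to [0, 255]. The tabular generator draws
class-conditional Gaussians whose means differ along the first feature by
`separation` noise-standard-deviations (default 6, comfortably separable
by a single threshold). All generators are pure functions of
(spec, seed).

These fixtures exercise the operators' contracts — impulse rejection,
contrast stretching, class balancing, learnable structure — but carry none
of the anatomy, intensity statistics, artifacts, or inter-scanner
variability of real MRI; passing tests demonstrate correctness of the
algorithms, not clinical performance.

## Problem sizes and numerical notes

The shipped tests and the acceptance script use sphere(5) at population
60 / 120 iterations (≈0.3 s per run), 8×8 images for oracle equivalence,
64×64 phantoms for denoising, a 250-row table for SMOTE, and a tuning demo
at population 10 / 15 iterations on 600 samples with an 80-step training
budget (≈1.5 min) — sizes chosen so the full suite runs on a single core
in a few minutes. Cross-entropy probabilities are clipped at 10⁻¹² before
the log; trace CSV floats are serialized with 17 significant digits so
round-trips are lossless.

## Known limitations

- The fractional memory is row-aligned, not member-aligned, across
  selection events (see above).
- Elitist truncation makes the algorithm strictly monotone; stagnation at
  a local optimum is possible on deceptive landscapes, and no restart
  mechanism is provided.
- The compact classifier is intentionally small; it is a vehicle for the
  composite objective, not a competitive image model.
- Only box constraints are supported; no discrete or combinatorial search
  spaces.
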