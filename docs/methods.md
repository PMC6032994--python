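# Methods

This note records the modelling assumptions, parameter choices and
numerical conventions behind `forageknn`, and what the synthetic-data-based
tests do and do not establish.

## Fuzzy k-NN

The classifier is the constrained-membership fuzzy k-NN: training pattern
x_j in class c receives membership 0.51 + 0.49·n_c/K in its own class and
0.49·n_j/K elsewhere, where n_j counts class-j members among its K nearest
*other* training points (the pattern itself is excluded — the standard
construction; every membership row sums to exactly 1).  Prediction averages
the k nearest membership rows with weights ‖x − x_j‖^(−2/(m−1)) under the
Euclidean metric.  By default the membership neighborhood K equals the
prediction neighborhood k, so a single tuned k governs both.

Numerical conventions:

* **Zero distances.**  The weight of a neighbor diverges as its distance
  → 0; if any neighbor lies within 10⁻¹² of the query, the prediction is
  the plain average of the membership rows of all such neighbors (the
  continuous limit of the weighting rule).  A query equal to a training
  point therefore returns that point's membership row.
* **Overflow-safe weights.**  Weights are computed as
  (d_min/d_j)^(2/(m−1)) with d_min the nearest distance in the
  neighborhood.  This is algebraically identical to the textbook form
  after normalization but bounded in (0, 1], so small distances or small
  m never overflow.  It also makes the scale invariance of predictions
  explicit.
* **Ties.**  Neighbor ties at the k-th distance are resolved by stable
  sort on (distance, training index); class ties in the final decision go
  to the lowest class id.  Both rules exist purely for determinism.
* **Contracts.**  1 ≤ k ≤ n − 1 and m > 1 are enforced; callers that
  sweep k (the tuner, the inner CV) cap k at n_train − 1.

## Bacterial foraging optimizer

The swarm loop nests elimination–dispersal × reproduction × chemotaxis.
Within a chemotaxis pass each bacterium draws a tumble direction (uniform
in [−1, 1]^d, normalized), takes the step unconditionally, and swims the
same direction while the cost strictly improves, up to `swim_length` extra
steps.  Health is the cost accumulated over a chemotaxis block; the
healthier half of the swarm overwrites the weaker half at reproduction
(stable sort, so ties keep the lower index), which leaves the population
size invariant.  Out-of-bounds moves are clamped to the box boundary, so
every evaluation is feasible.  The best-so-far record is updated on *every*
objective evaluation, including rejected swim candidates, mutants and
dispersal re-placements; the convergence curve stores the best after each
pass and is non-increasing by construction.

Parameters (fractions are of the per-dimension search range):

| parameter | default (benchmark / tuning) | meaning |
|---|---|---|
| swarm_size S | 50 / 8 | bacteria (must be even for fission) |
| chemotaxis_steps N_c | 50 / 25 | passes per reproduction block |
| swim_length N_s | 4 | max extra steps while improving |
| reproduction_steps N_re | 5 / 3 | blocks per dispersal event |
| elimination_events N_ed | 2 | dispersal events per run |
| elimination_prob P_ed | 0.25 | per-bacterium dispersal probability |
| step_size C(i) | 0.1 | chemotaxis step, fraction of range |
| mutation_sigma | 0.1 | initial Gaussian-mutation scale |
| mutation_sigma_final | 1e-6 | terminal mutation scale |

The benchmark profile (50 bacteria, 2 × 5 × 50 = 500 passes) matches the
population-50 / 500-iteration convention of the benchmark literature; the
tuning profile (8 bacteria, 2 × 3 × 25 = 150 passes) is the small-swarm
setting appropriate to a 2-D hyperparameter box.

**Chaotic initialization.**  Initial coordinates come from the logistic
map x ← 4x(1 − x) seeded by a uniform draw (excluding the degenerate
points 0, ¼, ½, ¾, 1 whose orbits collapse), mapped affinely onto the box.
The chaotic orbit is ergodic on (0, 1), giving a space-filling start; the
interpretation of the chaotic sequence as the raw coordinates (rather than
a multiplier on a uniform population) is deliberate, since a multiplicative
reading merely shrinks the population toward the lower bound.

**Gaussian mutation of the best.**  Once per pass a proposal
best + ε, ε ~ N(0, (σ_t · range)²) per dimension, is evaluated and
accepted greedily into the best record.  The scale σ_t anneals
geometrically from `mutation_sigma` to `mutation_sigma_final` across the
pass budget.  The annealing is the package's design: a constant proposal
scale either explores (large σ) or polishes (small σ) but cannot do both,
and with the fixed chemotaxis step C(i)·range the swarm itself has a
resolution floor of order the step length.  The geometric schedule turns
the mutation operator into a (1+1)-style refinement whose terminal
precision is set by `mutation_sigma_final`, which is what allows the
optimizer to reach the published 10⁻⁶-grade spreads on the fixed-dimension
benchmarks while leaving early-run exploration intact.  Setting
`mutation_sigma_final = mutation_sigma` recovers a constant scale;
`use_mutation=False` together with `use_chaos=False` reproduces plain BFO
for ablation.

The swarming (cell-to-cell attractant) term of classical BFO is not
implemented: no parameterization of it is standard, and the optimizer's
published behavior is reported without it.

**Determinism.**  One `numpy.random.Generator` threads through
initialization, tumbles, dispersal and mutation; a fixed seed yields a
bit-identical trajectory, which the tests assert.

## Benchmark suite

The 23 functions use their canonical literature forms (several printed
renderings of these functions circulate with typographical corruption; the
canonical forms are the ones whose minima match the quoted f_min values).
Two conventions worth noting: Schwefel's sine function (F8) has minimum
−418.9829·d, scaling with dimension; and the 3-D Hartmann function (F19)
is defined on [0, 1]³ — its optimum at (0.115, 0.556, 0.853) with value
−3.8628 lies outside the [1, 3]³ box sometimes quoted for it, so the
canonical domain is used.  The noisy quartic (F7) takes an injectable
random source and is deterministic (zero noise) when none is given.
F1–F13 accept a reduced dimension for cheap testing; F14–F23 are fixed.

`reference_minimum` is a deterministic oracle: a regular lattice scan
(default density chosen to keep within a 4-million-point budget, 400 per
axis in 2-D) followed by bounded Nelder–Mead polish from the five best
lattice points with fixed tolerances (xatol = fatol = 10⁻¹²).  It is
bit-for-bit reproducible and used to verify the printed minima; it shares
no code path with the swarm optimizer it cross-checks.

## Hyperparameter tuning and evaluation

The (k, m) search box is k ∈ [1, min(50, n_train − 1)], m ∈ (1.01, 10].
The optimizer works on the continuous box; positions decode by rounding
and clamping k and clamping m.  The inner objective is the mean
misclassification rate over stratified 5-fold splits of the outer training
data; the fold assignment is drawn once per tuning run and reused for every
candidate pair, and evaluated pairs are cached, so the search is
deterministic given its seed and each candidate is judged on identical
splits.

Stratified folds are built by dealing each class's shuffled indices
round-robin, which keeps per-class counts within one across folds and
fails loudly if a class has fewer members than folds.

Outer evaluation reports ACC, sensitivity and specificity in percent from
the confusion counts, and a rank-based (Mann–Whitney, midrank-tied) AUC
scored by the positive-class fuzzy membership — a continuous score, so the
AUC is informative even when the crisp decisions are identical.  Min-max
scaling to [0, 1] is fitted on the outer training split and applied,
unclipped, to the held-out fold.  The Wilcoxon rank-sum comparison helper
uses exact enumeration for small tie-free samples and the tie-corrected
normal approximation otherwise.

## Synthetic data generator

The generator emulates the shape of sustained-vowel feature tables:
class-conditional Gaussian features of unit variance grouped into
equicorrelated blocks (x = √ρ·shared + √(1−ρ)·own per block, default
ρ = 0.6, block size 5 — a stand-in for the strongly collinear jitter and
shimmer measurement families), with the first `n_informative` features
shifted by `effect_size` standard deviations in the positive class.  The
two presets reproduce the row/column/imbalance geometry of the public
vocal datasets: 147 patient + 48 control recordings × 22 features, and
192 + 96 × 26.  Preset defaults (effect_size 1.0, 10 informative
features) give a moderately hard problem — nested-CV accuracy in the
high-80s — which is the regime where tuning matters; effect_size 3 with
all features informative is essentially separable and is used as the
strong-signal condition in the acceptance tests.

What the generator does **not** model: within-subject correlation between
recordings of the same speaker (folds are stratified per recording, not
grouped per subject — a `seed`-controlled grouping could be added but the
evaluation protocol here is deliberately per-sample), heavy-tailed or
skewed marginals typical of jitter measures, and nonlinear class
boundaries.  Passing tests on this generator therefore demonstrate that
the pipeline is correct and leakage-free and that tuning recovers known
structure — not that any particular accuracy will transfer to real
clinical tables.

## Problem sizes used in the shipped checks

The acceptance script runs the deterministic oracle on a 400 × 400 lattice
and 30 seeded optimizer runs per fixed-dimension benchmark at the full
benchmark profile (population 50, 500 passes).  The test suite exercises
nested CV at the full 10 × 5 protocol on a 195-sample synthetic table and
uses reduced swarm budgets elsewhere, which keeps the whole suite in the
low single-digit minutes while every protocol element (both loops, both
profiles, all operators) is exercised at its production configuration at
least once.

## Known limitations

* The tuned k plateaus on easily separable data (many k achieve zero inner
  error); the reported k is then whichever optimum the search met first.
* AUC from fuzzy memberships can saturate at 1.0 while accuracy is below
  100 % (ranking can be perfect when thresholding is not).
* The optimizer's step size does not adapt; very anisotropic objectives
  rely on the mutation schedule for refinement.
* Exact rank-sum p-values are only computed for combined samples of at
  most 12 without ties; beyond that the normal approximation applies.
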