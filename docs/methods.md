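# Methods

## Model and procedure

`swarmselect` performs wrapper feature (gene) selection on a labeled
expression matrix (samples × genes). A candidate solution is a binary
position `X ∈ {0,1}^n`; its quality is

    fitness(X) = w1 · A(X) + w2 · (n − R(X)) / n

with `A(X)` the leave-one-out cross-validated (LOOCV) accuracy of an
RBF-kernel SVM trained on the `R(X)` selected genes and `w1 + w2 = 1`,
`w1 ∈ [0.6, 0.9]`. An empty subset receives fitness 0: evaluating the
formula literally at `R = 0` would award `w2` for selecting nothing.
LOOCV uses a single outer loop (N folds, one held-out sample each); a
training fold that contains a single class predicts that class
constantly. The SVM uses `C = 1`, `gamma = 1/k` with `k` the number of
genes fed to it, and one-against-one multiclass handling
(`sklearn.svm.SVC`); the classifier is pluggable through a
`fit`/`predict` factory for users who want a different wrapper model.

Both optimizer variants share one loop per iteration: evaluate every
particle, update personal/global bests (replacement only on *strict*
fitness improvement; ties keep the incumbent, since the fitness already
penalizes subset size), update the inertia weight, then move particles.
The run terminates only on the iteration budget — no early stopping and
no global-best resets. The inertia weight follows the nonlinear
recurrence

    w(t+1) = (w(t) − 0.4) · (max_iter − t) / max_iter + 0.4

starting at 1.4; applied as a recurrence (not recomputed from the initial
value) it decays faster than a linear ramp and reaches 0.4 exactly when
the iteration index equals the budget.

### Conventional binary PSO (baseline)

Per-dimension velocities are updated with fresh uniform draws `r1^d, r2^d`
per dimension, clamped to `±V_max` with `V_max = v_max_fraction·n`
(default fraction 1/3), and each bit is resampled with probability
`Sig(v^d) = 1/(1+e^(−v^d))` of being 1. At `v = 0` this gives
`P(bit) = 0.5`, which is why the baseline tends to keep about half of all
genes selected on high-dimensional data. The clamp is symmetric in sign:
the transfer analysis requires negative velocities, so a positive lower
bound would be inconsistent; only the magnitude is limited.

### Enhanced variant

Each particle instead carries one scalar, non-negative *speed* `s`,
updated with single per-particle draws `r1, r2` from the distances to its
personal and the global best position. The distance between two binary
positions is `|a − b|`, where `a` counts dimensions the particle lacks
relative to the best and `b` dimensions it holds superfluously. This
quantity is non-negative and zero for identical positions — the two
properties the optimizer relies on — but it is *not* a metric (it can be
zero for different positions and violates the triangle inequality), and
nothing here assumes it is. The speed is clamped to `[0, V_max]`.

Bits are resampled with the inverted rule: `x^d = 0` if
`Sig(α·s) > r3^d`, else 1, with a fresh `r3^d` per dimension and the same
`s` for all dimensions. The steepened sigmoid `Sig(α·s) = 1/(1+e^(−α·s))`
uses slope `α = 5` by default, which reproduces the method's published
operating points (bit-clear probability 0.993307 at `s = 1` and 0.999955
at `s = 2`). Since `s ≥ 0`, `P(bit = 0) ≥ 0.5` at every dimension — the
mechanism that biases the swarm toward small subsets.

### Saturation floor (this package's design choice)

The enhanced speed update has a structural asymmetry relative to the
conventional rule: its attraction terms scale with the position distance
(up to `n`), not with a single bit gap (at most 1). Whenever a particle's
position is far from its bests — in particular right after the strong
zero bias empties a position while the bests are still dense — the speed
jumps to its clamp, `Sig(α·V_max)` rounds to exactly 1.0 in float64, and
every subsequent position is the empty subset: the particle freezes
permanently and the search degenerates to its first few samples. We
measured exactly this on planted-gene data (about 20 unique subset
evaluations out of 1000 scheduled).

The classical remedy in binary swarm optimization is to keep transfer
probabilities away from 0 and 1 (velocities are conventionally clamped
near ±4…6 for precisely this reason). `swarmselect` therefore bounds the
per-dimension bit-*set* probability from below at
`min_set_prob = Sig(−5) ≈ 0.00669` — the complement of the steepened
sigmoid at its saturation scale, i.e. the smallest set probability the
rule can meaningfully express. The floor lives only in the position step
(`epso_position_step`); the sigmoid itself and the speed update are
untouched, so all published worked values are reproduced exactly.
Setting `min_set_prob = 0` restores the literal rule. With the floor, a
pinned particle still proposes about `n·0.0067` genes per move, keeping
the bit process ergodic while preserving the strong zero bias; on the
planted-gene benchmark below this turns a dead search (sparse recovery in
1/10 seeds) into a reliable one (10/10).

## Gain-ratio pre-filter

Each gene is scored independently by its best single binary split:
candidate thresholds are midpoints between consecutive distinct sorted
expression values; the score is the information gain of the best split
divided by the split information (the entropy of the two-way partition
sizes). Constant genes, zero-gain genes and degenerate one-sided splits
score 0; ranking ties are broken by original gene order for
reproducibility. Because only the value order matters, scores are
invariant to monotone transformations of a gene's expression. The
`select_top_k` operation (and the `GainRatioSelector` transformer) keeps
the `min(k, n)` best genes, `k = 500` by default; the swarm's fitness
then uses the reduced gene count as its `n`. Single-split scoring (rather
than full decision-tree induction) is the standard choice for ranking
continuous features; equal-width binning was rejected because it adds an
arbitrary bin count.

## Synthetic data generator

`generate_dataset` draws background genes i.i.d. from `N(0, σ²)`
(default σ = 1) and plants `n_informative` genes on which class `c`
receives an additive mean shift `c · effect_size · σ` — class 0 stays at
baseline, higher classes separate progressively, so "informative gene" is
unambiguous and a single planted gene can separate all classes when the
effect is large. Class sizes are as balanced as divisibility allows; an
optional `class_proportions` parameter introduces imbalance. Default
shape: 30 samples × 100 genes, 3 classes, 5 planted genes, effect size 5.

What this emulates — and does not: the generator reproduces the *shape*
of public expression benchmarks (few samples, many genes, a small
informative subset against noise) but not real microarray distributions
(log-normal intensities, heteroscedasticity, gene–gene correlation, batch
effects, missing values). Tests passing on this generator therefore
demonstrate the optimizer's selection behavior under a clean additive
signal model, not performance on real microarray data; real-data users
should apply the gain-ratio pre-filter and consider the `standardize`
flag (per-gene z-scoring), since the method itself applies no scaling.

## Parameters

| Parameter | Default | Meaning |
| --- | --- | --- |
| `num_particles` | 100 | swarm size (benchmark protocol) |
| `max_iter` | 500 | iteration budget, the only stopping rule |
| `c1`, `c2` | 2, 2 | acceleration constants, each in [0, 2] |
| `w_init`, `w_floor` | 1.4, 0.4 | inertia schedule endpoints |
| `v_max_fraction` | 1/3 | velocity/speed clamp as a fraction of n |
| `w1`, `w2` | 0.8, 0.2 | fitness weights (accuracy vs. size), w2 = 1 − w1 |
| `sigmoid_steepness` | 5 | slope α of the enhanced transfer function |
| `init_bit_prob` | 0.5 | P(initial bit = 1); fair bits match the baseline's own half-selection analysis |
| `speed_init_range` | (0, 1] | initial speeds, strictly positive, small enough not to start saturated |
| `min_set_prob` | Sig(−5) ≈ 0.00669 | saturation floor of the enhanced bit rule (see above) |
| SVM `C`, `gamma` | 1, 1/k | wrapper classifier; k = selected-gene count |
| filter `k` | 500 | genes kept by the gain-ratio pre-filter |

Initialization distributions (fair bits, BPSO velocities uniform on
`[−V_max, V_max]`, speeds uniform on `(0, 1]`) are this package's
choices; the protocol the defaults follow does not specify them.

## Numerical choices and degenerate inputs

- Randomness: one PCG64 generator per run, seeded from the
  configuration; equal (seed, config, dataset) gives bit-identical
  results, including trajectories. Repeated runs derive per-run seeds as
  master seed + run index and record them, so any single run can be
  reproduced alone.
- Fitness evaluations are memoized by exact bit pattern; the cache never
  touches the random stream, so caching cannot change results.
- pbest/gbest ties keep the incumbent; gbest updates only from a strictly
  better pbest.
- Empty subsets: fitness 0 (configurable via `empty_fitness`); LOOCV is
  never called with zero genes.
- Gain-ratio guards: score 0 when gain ≤ 0 or split information ≤ 0;
  split-gain ties keep the lowest threshold.
- Loading rejects missing/non-numeric cells (naming the cell), duplicate
  gene ids and single-class label columns.

## Problem sizes used in the test suite

The full benchmark protocol (100 particles × 500 iterations on matrices
with thousands of genes) is not what the tests run; the suite exercises
the same machinery at desk scale: 30 samples × 100 genes with 5 planted
genes (effect size 5), swarms of 20 particles for 50 iterations, 10
paired seeds per behavioral claim, and 10⁵-draw Monte-Carlo checks of the
transfer probabilities. At this scale the enhanced variant finds strictly
smaller subsets than the baseline in all 10 pairs and recovers a planted
gene at 100% LOOCV in all 10 seeds, while the baseline's initial swarms
select 50 ± 5 of 100 genes.

## Known limitations

- LOOCV inside the fitness is O(N) SVM fits per unique position;
  wall-time grows quickly with samples and particles. The cache mitigates
  this once the swarm converges.
- The enhanced variant's global best often stabilizes early (its sparse
  sampling finds a small accurate subset and the size reward makes it
  hard to beat); trajectories are still logged every iteration.
- `|a − b|` distances compress position information to one scalar; two
  very different positions can have distance 0.
- The generator's additive Gaussian model is deliberately simple; see the
  synthetic-data section for what that implies about external validity.
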