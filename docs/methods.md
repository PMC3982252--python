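# Methods

## Scoring kernels

For genes i, j and binary classes C₁/C₂ (fixed by `class_order`; C₁ is the
first class), the pair probabilities are empirical fractions of the event
x_i < x_j, with the indicator returning 0 on equality (x_i ≥ x_j counts
against "<"; no jitter is added to break expression ties). The score is
Δ = |p₁ − p₂| ∈ [0, 1]. Probabilities are ratios of small integers, so Δ
comparisons are done on the integer numerator |c₁·|C₂| − c₂·|C₁|| — exact tie
detection with no floating tolerance.

Δ ties are broken by a secondary score: each sample's expression vector is
converted to within-sample ranks (average ranks on ties) and the score is
|mean_{C₁}(R_i − R_j) − mean_{C₂}(R_i − R_j)|, unnormalized (no division by
P — the normalization would not change any ordering for fixed P, only the
scale). Remaining double ties resolve by lexicographic gene-id order. Because
only within-sample orderings enter anywhere, every fit and prediction in the
package is invariant under strictly increasing per-sample transforms; this is
asserted end-to-end in the test suite.

## Baselines

* **TSP** — exhaustive O(P²) arg-max of (Δ, secondary, gene-id order); the
  observed relation votes for the class in which it was likelier during
  training (ties vote C₁).
* **k-TSP** — greedy gene-disjoint selection down the same ranking; k is
  chosen among odd values {1, 3, …, k_max} (odd to avoid vote ties; k_max
  = 10) by internal stratified cross-validation (3 inner folds by default),
  ties preferring smaller k. Prediction is unweighted majority; an even split
  falls back to the highest-Δ pair's vote.
* **TST** — exhaustive O(P³) triplet scan. Within a sample the three values
  are ordered with equality broken by gene position, making the six orderings
  a partition. The score is the total-variation distance ½ Σ|p₁(o) − p₂(o)|
  between the class ordering distributions — chosen because it reduces
  exactly to Δ when applied to two genes, keeping the pair/triplet family
  consistent. Intended for small P (benchmarks and oracle duty); prediction
  assigns the class with higher training probability of the observed
  ordering, ties to the larger training class.

## Evolutionary engine

An individual is an ordered list of k ≥ 1 weighted pairs; each pair carries a
relation sign (whether x_i < x_j votes C₁) and a weight r > 0. The sign is
genotypic — mutation can flip it independently of the data — and weights are
exact powers of two (start 1, mutate ×2/÷2), so weighted-vote ties are
exactly detectable in float64. Classification sums weights per class; zero
margin falls back to the majority training class, then C₁.

Fitness is Q_reclass − α(2k + u): Q_reclass is plain training accuracy, u the
unique-gene count, α = 0.005 by default (larger α forces smaller models; the
penalty is the only size control — the initialization bound k ≤ 5 does not
constrain later growth).

Per generation: ranking linear selection (rank t of n drawn with probability
t/(n(n+1)/2); fitness ties rank smaller individuals higher for determinism)
with one elitist copy that is exempt from operators in its generation; each
remaining individual enters crossover with probability 0.5 and mutation with
an independent probability 0.5. Crossover pairs flagged individuals uniformly
at random (an odd leftover skips); with probability 0.9 one uniformly chosen
pair is exchanged between the two parents, otherwise a uniformly chosen pair
of the best-so-far individual overwrites a random pair of the first parent.
Mutation draws one of six variants uniformly: add a dipole pair, remove a
random pair (redrawn when k = 1 so individuals never empty), replace a random
pair by a fresh dipole pair, substitute one gene of a random pair by a
uniform random gene distinct from its partner, multiply or divide a random
weight by 2, or flip a random sign. Operator order is selection → crossover →
mutation. Termination: best-ever fitness unimproved for `stall_generations`
(default 1000) or `max_generations` (default 10000) reached.

Mixed-dipole initialization: one sample from each class is drawn uniformly;
random distinct gene pairs are rejected until the ordering relation differs
between the two samples ((x_iq > x_jq ∧ x_iw ≤ x_jw) or the reverse); the
sign is set so the relation seen in the C₁ sample votes C₁. Initial k is
uniform on {1..5}, all weights 1. If no effective pair exists (e.g. a
constant matrix) the construction fails after `dipole_retry_limit` draws with
an error naming the dipole. On continuous data an effective pair always
separates its two seeding samples; with tied expression values the ≤ branch
of the acceptance relation can admit a pair whose strict-"<" classifier does
not, which is tolerated.

All randomness flows through one `numpy` generator seeded from the config, so
runs are bit-reproducible; model JSON uses a fixed field order so reruns are
byte-identical and diffable.

## Synthetic data

The generator emulates two-class microarray studies: i.i.d. log-normal
background (log-mean log 100, log-sd 1 — a right-skewed positive intensity
scale), M ≈ 100–200 samples split 50/50 by default, P from a few dozen (TST
benchmarks) up to 10⁴⁺. Signal is planted by swapping the two background
draws of a pair within each sample so that x_i < x_j in C₁ and x_i > x_j in
C₂, reversed with noise probability ε; triplets get one full ordering per
class the same way. Swapping preserves each sample's value multiset, so
planted genes have identical marginal distributions in both classes — the
signal is invisible to univariate differential-expression statistics and
lives entirely in the pair ordering. The population Δ of a planted pair is
(1−ε) − ε = 1 − 2ε, used as a closed-form consistency check.

What the generator does not emulate: probe-level noise structure, batch
effects, gene–gene correlation in the background, class imbalance beyond a
single fraction parameter. Passing recovery tests therefore show that the
search finds rank-inversion signal under i.i.d. noise, not that it tolerates
confounded real-world structure.

## Benchmark harness

Repeated stratified k-fold cross-validation (stratification is switchable
off; the default controls fold-to-fold class-ratio variance). Each repeat
re-randomizes folds (seed + repeat index) unless `--no-refold` fixes them and
varies only method seeds. Accuracy is reported as mean ± SD in percent, the
SD taken over all per-fold accuracies; model size is the mean unique-gene
count of the fitted models. Problem sizes in the shipped tests and the
acceptance script (P = 60–200, M = 100, 10 folds × 3 repeats, EA capped at
stall 100–200 / max 1000–2000 generations) are chosen so the planted signals
are comfortably detectable while a full benchmark completes in about a
minute; the defaults on the `EvoConfig` remain the published full-scale
values.

## Known limitations

Binary classes only (multiclass and cost-sensitive fitness are out of scope);
no missing-value handling (NaN is rejected, not imputed); TST is exhaustive
and impractical beyond P ≈ 50; k-TSP's inner CV shrinks the training folds
and can be unstable on very small classes; the evolutionary search is
stochastic — recovery guarantees in the tests are statistical (≥ 80% of
seeded runs), not per-run.
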