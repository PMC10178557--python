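# Methods

## Scope and model

`runsvm` implements a filter–wrapper gene-selection pipeline for
classification of expression matrices with S samples (rows) and F genes
(columns), S ≪ F. The pipeline has four parts: min–max normalization and
stratified folding; ReliefF relevance weighting with top-m filtering; a
Runge–Kutta-style population optimizer (RUN) over continuous positions in
[0,1]^m; and an SVM cross-validation fitness that scores the binarized
positions as gene subsets. A synthetic-data generator with known ground
truth closes the loop for testing.

## ReliefF

The deterministic all-anchors variant is used: every sample is an anchor
once (m = S), instead of random subsampling. With S ≤ ~200 this costs one
S×S Manhattan distance matrix and removes a randomness source. For anchor i
with class prior P:

    W[g] += − Σ_hits |x_i,g − x_h,g| / (S·k_hit)
            + Σ_{c≠class(i)} P(c)/(1−P(class(i))) · Σ_miss_c |x_i,g − x_j,g| / (S·k_c)

Hits are the k nearest same-class neighbors excluding the anchor itself;
misses are the k nearest members of each other class; neighbor ties break by
lower sample index. Inputs must be min–max normalized (enforced as a
contract), so each |diff| ≤ 1 and every weight lies in [−1, 1]. If a class
is smaller than k (+1 for hits), the per-class k is reduced with a warning.
`k_neighbors` defaults to 10, the conventional ReliefF setting.

The retained pool size m defaults to 100 (50 is used in the desk-scale tests
of 100-gene data); the right value is data-dependent and exposed as a flag,
since nothing forces a particular pool size and the wrapper cost scales with
it.

A caveat verified experimentally: *exact* rank invariance under duplicating
every sample holds only when k is comparable to the class size. For small k
each anchor's hit set is dominated by its own zero-distance duplicate, which
rescales hit penalties and can swap near-tied noise genes. The independent
brute-force oracle reproduces the same behavior bit-for-bit; it is a
property of the weighting, not of this implementation.

## The RUN optimizer

Minimizes a black-box objective over a box. Population of N candidates,
T iterations; per candidate and iteration:

1. **RK direction.** Three distinct random partners are drawn. With `yb`/`yw`
   the better/worse of the current solution and the best partner:

       γ  = rand ⊙ (yn − rand ⊙ (r_max − r_min)) · e^(−4t/T)
       Stp = rand ⊙ ((yb − rand·yavg) + γ)
       Δy = 2·rand ⊙ |Stp| + ε            (ε = 1e−12 division guard)
       u  = round(1 + rand)·(1 − rand)
       k1 = (rand·yw − u·yb) / (2Δy)
       k2, k3, k4: same expression with both yw and yb advanced by
                   k1·Δy, k2/2·Δy, k3·Δy and fresh uniform draws
       yRK = k1 + 2k2 + 2k3 + k4 ;  SM = Δy ⊙ yRK / 6

2. **Main update.** `SF = 2(0.5−rand)·a·e^(−b·rand·t/T)` (defaults a = 20,
   b = 12, so |SF| ≤ 20 and its magnitude decays with t — exploration first,
   exploitation later). With anchors `yc = φ·yn + (1−φ)·yr1`,
   `ym = φ·ybest + (1−φ)·yb_iter` (φ ~ U[0,1]), r ∈ {−1,1}, g ~ U[0,2],
   μ = 0.5 + 0.1ξ′, ξ, ξ′ standard normal:

       branch rand<0.5:  y′ = (yc·SF·r·g + yc) + SF·SM + μξ(ym − yc)
       otherwise:        y′ = (ym·SF·r·g + ym) + SF·SM + μξ(yr1 − yr2)

   The result is clipped to the box and accepted only if better (greedy).

3. **Enhanced Solution Quality**, with probability 0.5: three fresh partners
   give `yavg`; `ynew1 = β⊙yavg + (1−β)⊙ybest` (β ~ U[0,1]^d);
   `w = U[0,2]·e^(−c·t/T)` (c = 5·rand) shrinks over iterations;
   r ∈ {−1,0,1}:

       w<1:  ynew2 = w·r·|(ynew1 − yavg) + ξ| + ynew1
       else: ynew2 = w·r·|(u·ynew1 − yavg) + ξ| + (ynew1 − yavg)

   `ynew2` replaces the candidate if better; otherwise, with probability
   min(w,1), `ynew3 = SF·((v·yb − ynew2) + rand·yRK) + (ynew2 − rand·ynew2)`
   (v = 2·rand) is tried, again greedily.

Design points worth stating explicitly:

- **Greedy acceptance also after the main update** (not only inside ESQ).
  This guarantees a non-increasing best-so-far trace for every seed, which
  the test suite asserts as an invariant.
- The symbol `randn` in the update's third term is taken as a standard
  normal draw (its conventional meaning); `v` uses a uniform draw. Both are
  localized in one place each if a variant is wanted.
- **Out-of-bounds handling is clipping** to the violated bound; with the
  [0,1] box this keeps the binary mapping well defined.
- The iteration-best `yb` is fixed at the start of each iteration; the
  global best refreshes immediately after each candidate.
- All draws come from a single `numpy` generator in the fixed order given
  above, so runs are bit-reproducible from the seed. Objective calls are
  counted and bounded by N(1 + 3T).

On the 10-d sphere with N = 30, T = 200 the median final best across seeds
is far below 1e−3 (typically ~1e−90), and the optimizer beats equal-budget
uniform random search on essentially every paired seed; both checks are in
the acceptance suite.

## Wrapper fitness

`mask[j] = position[j] > 0.5` (no sigmoid transfer — positions already live
in [0,1]; the threshold is a flag). An all-below-threshold position falls
back to the single argmax gene, so masks are never empty. Fitness is pooled
CV accuracy: train an SVM on K−1 stratified folds restricted to the masked
genes, predict the held-out fold, count correct predictions over all folds,
report C/S·100. The folds are drawn once per run and fixed, making fitness a
deterministic function of the mask; results are memoized by mask bits. The
optimizer internally minimizes 100 − accuracy.

SVM defaults: RBF kernel, C = 1, and Γ = 1/(d_sel · mean per-gene training
variance) for `gamma="auto"` — computed explicitly per training fold (this
differs from scikit-learn's `"scale"`, which uses the variance of the
flattened matrix and therefore mixes between-gene mean differences into the
width). A degenerate training fold containing one class predicts that class
and logs a warning. Among equally accurate masks the reported subset is the
smallest one visited; the fitness itself carries no size penalty.

The single-level CV protocol estimates the fitness the search optimizes; it
is *not* an unbiased estimate of generalization to unseen samples (genes are
selected on the same folds — the well-known selection-bias caveat). A nested
CV is out of scope by design.

## Experiment protocol

n_runs independent wrapper runs (defaults: 30 runs, N = 30, T = 100,
K = 10) over one fixed ReliefF pool. Per-run seeds come from
`SeedSequence(master).generate_state(2·n_runs)` — a prefix-stable stream, so
earlier runs never change when more are added. Aggregation is best = max,
worst = min, arithmetic mean, and sample (n−1) standard deviation over the
per-run best accuracies (a population-STD flag exists; a single run reports
STD 0). Exports: aggregate stats CSV (`STD,Best,Mean,Worst`), per-run
best-fitness CSV (boxplot data), per-run convergence CSV, selected-genes
lists.

## Synthetic data

Gaussian class-shift model: class c's mean for an informative gene is
`c · effect_size · noise_sd` with N(0, noise_sd²) noise; redundant genes copy
a random informative gene plus N(0, (noise_sd/4)²) jitter (yielding parent
correlations ≥ 0.9); remaining genes are pure noise; classes balanced to ±1
(an imbalance flag exercises fold edge cases). Defaults — 60 samples, 100
genes, 5 informative, 10 redundant, 2 classes, effect_size 2, noise_sd 1 —
are a desk-scale analogue of real microarray studies, preserving the
few-samples / many-genes / few-informative structure at sizes every test can
afford. Tests at this scale demonstrate correctness of the machinery and
recoverability of planted signal; they do not demonstrate accuracy levels on
real arrays, whose marginal distributions, probe artifacts and batch effects
the generator deliberately omits.

Problem sizes used in the test and acceptance suites: oracle equivalence on
S ≤ 12, F ≤ 6 instances; optimizer benchmarks on the 10-d sphere; end-to-end
recovery on 60×100 data with ReliefF top-50 and a 10-agent, 30-iteration,
5-fold wrapper, five runs.

## Numerical and degenerate-input choices

- Min–max normalization maps constant genes to all zeros (never an error);
  ReliefF then gives them weight exactly 0.
- Δy carries a 1e−12 floor, so an all-identical population yields finite RK
  terms rather than a division error.
- Gene-ranking ties break to the lower index everywhere (ReliefF top-m,
  argmax fallback), making orderings deterministic.
- Label encoding is lexicographic in the labels' string form, so the same
  data in a different row order produces the same codes.
- If the smallest class is smaller than K, K is reduced to that size with a
  warning instead of failing.
- CSV float round-trips are exact only when read with a round-trip float
  parser (pandas `float_precision="round_trip"`); the writers emit
  shortest-round-trip representations.

## Known limitations

- Reported accuracies are optimistically biased for generalization (see the
  wrapper section); compare methods with it, don't quote it as expected
  field performance.
- ReliefF weights depend on the normalization; only min–max is provided.
- The optimizer treats the objective as a black box; there is no constraint
  handling beyond box clipping and no parallel-evaluation semantics (the
  evaluation order is fixed and documented).
- Selected subsets vary across seeds when many subsets tie at the same CV
  accuracy — intrinsic to wrapper selection on small S.
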