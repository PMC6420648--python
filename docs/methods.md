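# Methods

## Scope and model

The package implements the generalized (causal) relevance network approach
to GRN inference as a three-stage pipeline — pairwise association, marginal
control (scoring scheme), symmetry breaking by time shifting — together with
thresholded evaluation (AUROC / AUPRC / rAUPRC), a significance filter, and
multi-objective mean-rank Pareto analysis of method variants.  No generative
model of expression is assumed at inference time; all knowledge enters
through pairwise association scores.

## Association measures

* **Correlation** (Pearson, Spearman, Kendall).  Kendall is the tau-a
  statistic 2(n_c − n_d)/(n(n − 1)) without tie correction.  Link weights
  are |μ|: sign is discarded because downstream schemes need nonnegative
  weights and ranking is by association strength.  Zero-variance profiles
  make correlations undefined; when assembling a matrix the affected pairs
  score 0 with a warning instead of aborting.
* **Mutual information.**  Profiles are discretized marginally (equal-width
  or equal-frequency bins, default bin count ⌊√n⌋); the joint distribution
  lives on the product grid of the marginal bins (no 2-D adaptive binning).
  Entropies are in nats.  Estimators: plug-in (`ml`); Miller-Madow, which
  adds (|X| − 1)/(2n) with |X| the number of *occupied* bins; and a
  James-Stein-style shrinkage of cell probabilities toward the uniform
  distribution over the *configured* bin count, with the standard
  data-driven intensity λ* = (1 − Σp̂²)/((n − 1)Σ(1/K − p̂)²) clipped to
  [0, 1] when no λ is supplied.  The two different readings of |X| (occupied
  for the bias term, total for the shrinkage target) are deliberate: the
  former is the asymptotic-bias formula, the latter is the uniform target
  distribution.  MI is clipped at 0.
* **Distances.**  Minkowski L^s norms for s ∈ {1, 2, 10}; distances map to
  similarities via 1/(1 + δ) — bounded, strictly monotone, and
  rank-reversing, which is all the pipeline needs.
* **Dynamic time warping** with symmetric1, symmetric2 and asymmetric step
  patterns (absolute-difference local cost; step weights multiply the
  landing cell's cost).  The asymmetric pattern consumes each query point
  exactly once and is direction-dependent; for an undirected link weight the
  two orientations are averaged.  Infeasible asymmetric alignments (the
  reference more than twice the query length, roughly) raise an error.
* **Symbolic measures.**  Per-step trends (increase / no-change / decrease)
  use a relative no-change tolerance, default 0 (exact equality).  The
  qualitative distance δ_QD averages a difference table over all time-point
  pairs; the default table is Diff(a,a) = 0, opposite trends 1, trend vs
  no-change 1/2 (the table itself is configurable — the canonical source
  names the function but never tabulates it).  Sequence-based measures cut
  the trend stream into overlapping words of length α = 5 for series of 10+
  points and α = ⌊(n−1)/2⌋ for shorter ones; the printed small-n rule in
  the source is not computable as typeset, so the fallback keeps α ≥ 1 and
  is configurable.  Word-stream similarities: exact-match fraction, plug-in
  categorical MI, and their weighted combination (MI normalized by the log
  of the observed joint word alphabet).  The variants tagged with a
  discretization (smf/smw, saf/saw) derive the trend symbols by 3-binning
  the step differences equal-frequency or equal-width instead of the exact
  sign rule — symbol streams are categorical, so this is where a
  discretization choice can meaningfully act.

## Scoring schemes

* **ARACNE.**  Every triplet whose three weights all exceed τ (default 0)
  has its weakest edge tested; in the default `classic` mode the edge is
  removed iff it falls below the second-lowest weight discounted by
  (1 − ε), ε default 0.1.  The literal printed inequality (removal iff the
  weakest is *at least* the discounted second-lowest) is preserved as
  `as_printed` because it degenerates at ε = 0; both modes share the final
  τ cut.  Survivors keep their original weights.
* **CLR.**  Per-gene background mean and population standard deviation over
  the off-diagonal row; default `as_printed` mode z_k = max(0, 1/σ_k −
  Ī_k/(I_kj σ_k)), `zscore` mode the canonical max(0, (I_kj − Ī_k)/σ_k);
  combined as √(z_k² + z_j²).  Zero-spread genes contribute z = 0 with a
  warning.
* **MRNET.**  Per target k, greedy MRMR forward selection: the most
  relevant gene seeds the set unconditionally, then genes join in order of
  s_j = w_jk − mean_{i∈M} w_ji while the best score stays ≥ τ.  The final
  link weight is f_kj = max[(w_jk − r_j), (w_kj − r_k)]/w_kj clipped at 0,
  with the redundancy r_j computed against the *final* selected set minus
  j.  Evaluating redundancies on the final set (rather than freezing each
  gene's score at selection time) is a deliberate convention: it makes the
  degenerate all-equal-weights case come out uniform and keeps f symmetric
  in its two terms; with τ = 0 it is also order-independent.
* **AWE.**  Column normalization c_kj = w_kj/Σ_k w_kj (rows regulate
  columns); nonzero output columns sum to 1 within 1e−12; zero-sum columns
  stay zero.  The only scheme that produces a directed matrix.

Although ARACNE, CLR and MRNET are formulated for mutual information, they
are applied to any nonnegative similarity matrix, which is what lets the
variant grid cross every measure with every scheme.

## Time shifting

Lags ℓ = ±1…±max_lag (default 1 — the shortest supported series have 5
points and each lag step costs overlap) compare μ(x_{1..n−ℓ}, y_{1+ℓ..n})
against its mirror; the side with the larger best |μ| wins and the losing
direction's weight is zeroed.  Equality within 1e−12 is a tie and keeps
both directions (no information to break them).  The shift measure defaults
to Spearman.  Applying the shift after AWE ("ws" variants) follows the
label order scoring → shift and re-zeroes anti-directional entries.
Overlap below 3 points or steady-state input is an error.

## Variant registry

Measure codes live in `src/crn/data/variant_registry.tsv` (editable without
code changes): 3 correlation + 4 MI (equal-frequency ML/MM/shrink,
equal-width ML) + 3 distance + 3 DTW + 6 symbolic = 19 measures.  Time
series pair each measure with the combinations ns, wn, ws, ms, cs, as
(non-AWE schemes produce undirected matrices, so shifting is obligatory for
them; AWE appears with and without shift), giving the asserted 114
variants; steady-state data drop the time-only measures and all shifting
(nn, wn, mn, cn, an — 50 variants; this count is not asserted).  The MI
inventory is the one consistent with both the total of 114 and the
published surviving-variant labels; the source's prose would imply six MI
configurations, which cannot sum to 114.

## Evaluation

Evaluation runs over all ordered gene pairs (i ≠ j, diagonal excluded);
symmetric predictions contribute both directions with equal score.
Thresholding is score ≥ t with ties grouped.  AUROC is the trapezoidal area
(equal to the tie-corrected Mann-Whitney statistic).  The PR curve inserts
every intermediate integer TP count between achievable cuts with linearly
interpolated FPs (precision then varies hyperbolically — the
Davis–Goadrich construction) and carries the first achievable precision to
recall 0; areas are trapezoidal on [0, recall_max], recall_max = 1 for
AUPRC and 0.2 for rAUPRC.  The significance filter applies a one-sided
one-sample t-test of mean metric > baseline per metric (α = 0.05); a
variant survives if significant on ≥ 1 of the three.  Baselines: 0.5
(AUROC), 0.1 (AUPRC), and 0.02 for rAUPRC — the 0.1 precision baseline
restricted to the 0.2 recall span, since a baseline of 0.2 would be
unattainable by construction (rAUPRC ≤ 0.2); the literal 0.2 remains
available as a configuration value.  Zero-variance metric samples are
significant only when strictly above baseline (the t statistic is ±∞
there).

## Ranking

Per task and metric, variants are ranked descending (rank 1 = best, ties
averaged — the convention that keeps rank sums invariant); mean ranks map
to [0, 1] via (r − 1)/(N − 1).  Nondominated sorting uses weak dominance
with a strict improvement somewhere, minimization; fronts are peeled
iteratively.  Dominated hypervolume uses reference point (1, 1, 1) — the
worst corner of the normalized rank space — and an exact sweep/staircase
union computation for three objectives.

## Synthetic benchmark generator

The simulator emulates the statistical shape of the microarray benchmarks
this family of methods is evaluated on; it does not reproduce any external
dataset numerically.

* **Topology.**  Random DAG: genes in random order, each forward pair an
  edge with probability avg_degree/(n − 1) (expected mean total degree =
  avg_degree, default 2.42); signed weights, activation probability 0.75,
  magnitude regulation_strength × U(0.5, 1.5).  `cascade_grn` builds
  explicit unit-delay chains (optionally several, bounded depth) for
  signal-recovery experiments.
* **Dynamics.**  Regulated genes follow x_i(t+1) = σ(Σ_j w_ji (x_j(t) −
  ½)), a saturating logistic response keeping expression in (0, 1);
  regulation_strength (default 6) is the logistic gain scale.  A
  response_rate < 1 would relax toward the target instead of jumping
  (transcript turnover); the default 1 makes a cascade target an exact
  monotone transform of its regulator delayed one step, which is the
  property the time-shift component is designed to exploit.  Unregulated
  input genes follow smoothed-uniform stochastic stimulus trajectories
  (triangular kernel of half-width 3), smooth at the one-step scale yet
  independent between inputs; the system runs through a burn-in and only
  the trailing window is recorded, so no initialization transient is
  visible.  Steady-state data clamp one gene to 0 per record (knockout,
  cycling over genes), draw per-record input levels from U(0.3, 0.7), and
  iterate to a fixed point (tolerance 1e−9, cap 1000 steps with a warning).
* **Noise.**  Each stored value is multiplied by exp(ε), ε ~ N(0, σ²)
  (log-normal, σ ∈ {0, 0.1, 0.5} in the benchmark grid); n_replicates
  (default 6) independent noisy copies are averaged per gene.
* **What it does not capture.**  Real microarray data have correlated
  probe-level noise, unmodelled confounders, combinatorial and
  self-regulation, and gold standards that are themselves incomplete.
  Passing the recovery tests therefore shows the pipeline's components
  compose correctly and respond to noise as expected — not that any variant
  will reach the same accuracy on biological data.

## Problem sizes and numerical choices

The test suite and the acceptance script use deliberately small instances:
10-gene, 10-point cascades over 20–40 seeds for signal recovery; six
simulated 20-gene tasks for the end-to-end protocol (the full 114-variant
sweep over them runs in about a minute); 10⁶ Monte-Carlo samples for the
hypervolume check; 1000 replicates for the filter-size null.  Ties are
broken deterministically everywhere (stable sorts, lowest index first);
score ties in direction inference and dominance are resolved conservatively
(keep both / same front).  All randomness flows from a single integer seed
through independent named streams.

## Known limitations

The registry's exact measure inventory beyond the published surviving
labels is a reconstruction (see above).  The MRNET greedy details and the
time-shift lag aggregation are underdetermined by the sources and are fixed
by the documented conventions.  DTW costs are O(nm) per pair and symbolic
measures enumerate all time-point pairs, so very long series (thousands of
points) would need windowing, which is out of scope.
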