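# crn — causal relevance networks for gene regulatory network inference

`crn` infers gene regulatory networks (GRNs) from expression data with the
generalized *relevance network* approach: score every gene pair with an
association measure, optionally correct the scores for marginal and indirect
effects with a scoring scheme, and, on time-series data, orient the links by
time shifting.  The package is aimed at computational biologists who want to
compare the many possible combinations of these three components on their own
data or on simulated benchmarks, rather than commit to a single method.

## The approach

A network prediction is built in three stages:

1. **Association.**  For profiles *x* = ⟨x₁…x_n⟩ and *y*, compute a pairwise
   association μ(x, y): Pearson / Spearman / Kendall correlation (entered as
   |μ|), mutual information μ_I = H(X) + H(Y) − H(X, Y) under ML,
   Miller-Madow or shrinkage entropy estimators with equal-width or
   equal-frequency binning, Minkowski distances δ_L (s = 1, 2, 10), dynamic
   time warping under three step patterns (distances enter as 1/(1 + δ)),
   or symbolic trend measures over very short series.  The result is a
   symmetric similarity matrix W.
2. **Scoring scheme.**  Transform W to control marginal effects:
   ARACNE (data-processing-inequality pruning of the weakest edge in each
   strong triplet), CLR (z-like comparison of each pair against both genes'
   background, z_kj = √(z_k² + z_j²)), MRNET (max-relevance /
   min-redundancy forward selection per target), AWE (column normalization,
   c_kj = w_kj / Σ_k w_kj, the only directed scheme), or the identity.
3. **Time shifting.**  For time-series data, orient each remaining link by
   comparing the best |μ| under forward and backward lags (Spearman by
   default); undirected schemes make this step obligatory.

Each combination is a *variant*, named `<measure>-<scheme><shift>` —
`cpr-ws` is Pearson + AWE + shift; `sqd-cs` is the symbolic qualitative
distance + CLR + shift.  The registry enumerates 114 variants for
time-series data.

Predictions are judged against a gold standard over all ordered gene pairs
with three thresholded metrics: AUROC, AUPRC (Davis–Goadrich interpolated)
and rAUPRC (the area restricted to recall ≤ 0.2, in [0, 0.2]).  To compare
variants across a task collection, a one-sample t-test filter removes
variants not significantly better than a random classifier on any metric;
the rest are ranked per task and metric, mean ranks are normalized to
(r − 1)/(N − 1), and nondominated sorting partitions the variants into
Pareto fronts, each summarized by its dominated hypervolume.

A built-in simulator generates ground-truth networks (sparse random DAGs or
explicit cascades) with logistic regulation dynamics, stimulus-driven input
genes, multiplicative log-normal noise (σ ∈ {0, 0.1, 0.5}) and averaged
technical replicates, so the whole pipeline is testable without downloads.

## Worked example

Simulate a 10-gene regulatory cascade observed over 10 time points with
σ = 0.1 noise and 6 averaged replicates, infer a network with Pearson + AWE
+ time shifting, and evaluate it:

```sh
crn simulate --genes 10 --timepoints 10 --noise 0.1 --replicates 6 \
    --cascade --seed 7 --out-data X.tsv --out-gold G.tsv
crn infer --data X.tsv --kind time-series --variant cpr-ws --out edges.tsv
crn evaluate --pred edges.tsv --gold G.tsv --data X.tsv --kind time-series
```

which prints

```
auroc   0.770919
auprc   0.533417
raupr   0.200000
```

The cascade's 9 true links rank well among the 90 ordered pairs (AUROC
0.77 under noise); the top-ranked predictions are all true links (`head -2
edges.tsv` shows `g6→g7` and `g5→g6`), which is why the recall-restricted
rAUPRC reaches its maximum of 0.2.  `crn variants` lists the registry,
`crn run-all` sweeps the full grid, and `crn rank` turns a per-task metrics
table into the Pareto-front report (PF-I, Dom-HV, member variants).

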