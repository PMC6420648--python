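import numpy as np
import pytest

from crn import (
    EdgeScoreMatrix,
    GoldStandard,
    auprc,
    confusion_at_threshold,
    evaluate,
    pr_curve_interpolated,
    roc_auc,
    significance_filter,
)

import oracles


def matrix_from_pairs(gene_ids, pair_scores, default=0.0):
    m = len(gene_ids)
    idx = {g: i for i, g in enumerate(gene_ids)}
    s = np.full((m, m), default)
    for (a, b), v in pair_scores.items():
        s[idx[a], idx[b]] = v
    np.fill_diagonal(s, np.nan)
    return EdgeScoreMatrix(gene_ids=gene_ids, scores=s, symmetric=False)


def random_instance(rng, n_genes=5, n_pos=None, ties=False):
    genes = [f"g{i}" for i in range(n_genes)]
    pairs = [(a, b) for a in genes for b in genes if a != b]
    if n_pos is None:
        n_pos = rng.integers(1, len(pairs))
    pos_idx = rng.choice(len(pairs), size=n_pos, replace=False)
    gold = GoldStandard(gene_ids=genes, present={pairs[i] for i in pos_idx})
    if ties:
        values = rng.integers(0, 6, size=len(pairs)) / 5.0
    else:
        values = rng.permutation(len(pairs)) / len(pairs)
    scores = matrix_from_pairs(genes, dict(zip(pairs, values)))
    return scores, gold


def flat(scores, gold):
    idx = {g: i for i, g in enumerate(scores.gene_ids)}
    s, y = [], []
    for a in gold.gene_ids:
        for b in gold.gene_ids:
            if a != b:
                s.append(scores.scores[idx[a], idx[b]])
                y.append(1 if (a, b) in gold.present else 0)
    return np.array(s), np.array(y)


class TestConfusion:
    def test_extreme_thresholds(self, rng):
        scores, gold = random_instance(rng)
        lo = confusion_at_threshold(scores, gold, -np.inf)
        hi = confusion_at_threshold(scores, gold, 2.0)
        assert lo.tp == gold.n_present and lo.fp == gold.n_absent
        assert hi.tn == gold.n_absent and hi.fn == gold.n_present

    def test_three_gene_toy(self, toy_gold):
        scores = matrix_from_pairs(
            ["g1", "g2", "g3"], {("g1", "g2"): 0.9, ("g2", "g1"): 0.1}, default=0.5
        )
        c = confusion_at_threshold(scores, toy_gold, 0.6)
        assert (c.tp, c.fp, c.fn, c.tn) == (1, 0, 0, 5)

    def test_counts_partition_the_universe(self, rng):
        scores, gold = random_instance(rng, ties=True)
        c = confusion_at_threshold(scores, gold, 0.4)
        assert c.tp + c.fp + c.tn + c.fn == gold.universe_size


class TestRocAuc:
    def test_perfect_ranking(self, toy_gold):
        scores = matrix_from_pairs(["g1", "g2", "g3"], {("g1", "g2"): 1.0}, default=0.1)
        assert roc_auc(scores, toy_gold) == 1.0

    def test_all_tied_scores(self, toy_gold):
        scores = matrix_from_pairs(["g1", "g2", "g3"], {}, default=0.3)
        assert roc_auc(scores, toy_gold) == pytest.approx(0.5)

    @pytest.mark.parametrize("ties", [False, True])
    def test_matches_mann_whitney_oracle(self, rng, ties):
        for _ in range(40):
            scores, gold = random_instance(rng, ties=ties)
            s, y = flat(scores, gold)
            assert roc_auc(scores, gold) == pytest.approx(
                oracles.auroc_mann_whitney(s, y)
            )

    def test_degenerate_gold_rejected(self):
        genes = ["g1", "g2"]
        gold = GoldStandard(gene_ids=genes, present=set())
        scores = matrix_from_pairs(genes, {}, default=0.4)
        with pytest.raises(ValueError):
            roc_auc(scores, gold)


class TestPrCurve:
    def test_perfect_ranking_has_unit_precision(self, rng):
        scores, gold = random_instance(rng, n_pos=4)
        s, y = flat(scores, gold)
        # force positives above all negatives, keep scores distinct
        s = np.where(y == 1, s + 2.0, s)
        m = matrix_from_pairs(
            gold.gene_ids,
            dict(
                zip(
                    [(a, b) for a in gold.gene_ids for b in gold.gene_ids if a != b],
                    s,
                )
            ),
        )
        curve = pr_curve_interpolated(m, gold)
        # unit precision everywhere up to full recall (looser cuts beyond
        # full recall add points at recall 1 with no area contribution)
        assert all(p == pytest.approx(1.0) for r, p in curve if r < 1.0)
        assert max(p for r, p in curve if r == 1.0) == pytest.approx(1.0)
        assert auprc(curve, 1.0) == pytest.approx(1.0)
        assert auprc(curve, 0.2) == pytest.approx(0.2)

    def test_single_positive_ranked_last(self):
        genes = ["a", "b", "c", "d"]  # 12 ordered pairs
        pairs = [(x, y) for x in genes for y in genes if x != y]
        gold = GoldStandard(gene_ids=genes, present={pairs[-1]})
        values = {p: 1.0 - 0.05 * i for i, p in enumerate(pairs)}  # positive last
        scores = matrix_from_pairs(genes, values)
        curve = pr_curve_interpolated(scores, gold)
        assert curve[-1] == (1.0, pytest.approx(1.0 / 12.0))

    def test_achievable_points_match_exhaustive_cuts(self, rng):
        for _ in range(30):
            scores, gold = random_instance(rng, n_genes=4, ties=False)  # 12 pairs
            s, y = flat(scores, gold)
            want = oracles.pr_points_exhaustive(s, y)
            got = pr_curve_interpolated(scores, gold)
            # with distinct scores every oracle point appears in the curve
            for r, p in want:
                match = [q for q in got if abs(q[0] - r) < 1e-12]
                assert any(q[1] == pytest.approx(p) for q in match)

    def test_monotone_score_transform_invariance(self, rng):
        scores, gold = random_instance(rng)
        t = evaluate(scores, gold)
        warped = EdgeScoreMatrix(
            gene_ids=scores.gene_ids,
            scores=np.exp(3.0 * scores.scores),
            symmetric=False,
        )
        t2 = evaluate(warped, gold)
        assert t2.auprc == pytest.approx(t.auprc)
        assert t2.raupr == pytest.approx(t.raupr)
        assert t2.auroc == pytest.approx(t.auroc)

    def test_area_bounds(self, rng):
        for _ in range(10):
            scores, gold = random_instance(rng, ties=True)
            curve = pr_curve_interpolated(scores, gold)
            assert auprc(curve, 0.2) <= 0.2 + 1e-12
            assert auprc(curve, 1.0) <= 1.0 + 1e-12

    def test_lowering_a_true_positive_never_raises_auroc(self, rng):
        for _ in range(10):
            scores, gold = random_instance(rng, ties=False)
            base = roc_auc(scores, gold)
            reg, tgt = next(iter(gold.present))
            idx = {g: i for i, g in enumerate(scores.gene_ids)}
            lowered = scores.scores.copy()
            lowered[idx[reg], idx[tgt]] -= 0.5
            m2 = EdgeScoreMatrix(
                gene_ids=scores.gene_ids, scores=lowered, symmetric=False
            )
            assert roc_auc(m2, gold) <= base + 1e-12

    def test_invalid_recall_max(self, rng):
        scores, gold = random_instance(rng)
        curve = pr_curve_interpolated(scores, gold)
        for bad in (0.0, 1.5, -0.1):
            with pytest.raises(ValueError):
                auprc(curve, bad)


class TestSignificanceFilter:
    def test_constant_perfect_variant_survives(self):
        per_task = {
            "auroc": np.full((1, 10), 1.0),
            "auprc": np.full((1, 10), 0.05),
            "raupr": np.full((1, 10), 0.01),
        }
        assert significance_filter(per_task).tolist() == [True]

    def test_variant_at_baseline_excluded(self):
        per_task = {
            "auroc": np.full((1, 10), 0.5),
            "auprc": np.full((1, 10), 0.1),
            "raupr": np.full((1, 10), 0.02),
        }
        assert significance_filter(per_task).tolist() == [False]

    def test_clearly_better_variant_survives_noise(self, rng):
        per_task = {
            "auroc": 0.9 + rng.normal(0, 0.01, size=(1, 10)),
            "auprc": 0.1 + rng.normal(0, 0.01, size=(1, 10)),
            "raupr": 0.02 + rng.normal(0, 0.002, size=(1, 10)),
        }
        assert significance_filter(per_task).tolist() == [True]

    def test_single_task_skips_filter_with_warning(self):
        per_task = {m: np.full((2, 1), 0.5) for m in ("auroc", "auprc", "raupr")}
        with pytest.warns(UserWarning, match="skipped"):
            assert significance_filter(per_task).tolist() == [True, True]
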