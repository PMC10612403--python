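"""Interpretability metrics: top-k F1, PRG curves, max F-Gain, enrichment."""

import math

import numpy as np
import pytest

from attnzyme.evaluation import (
    GoldAnnotation,
    compare_methods,
    enrichment_test,
    max_fgain,
    pooled_pr_and_prg,
    rescale_scores,
    topk_f1_curve,
)
from attnzyme.importance import ImportanceVector


def make_case(scores, gold_positions, seq_id="a"):
    scores = np.asarray(scores, dtype=float)
    iv = [ImportanceVector(seq_id, scores, "m")]
    gold = {seq_id: GoldAnnotation(seq_id, frozenset(gold_positions), len(scores))}
    return iv, gold


# ------------------------------------------------------------ oracles

def prg_auc_oracle(scores, labels):
    """Exhaustive threshold enumeration with explicit loops."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, int)
    pi = labels.mean()
    pts = []
    for t in sorted(set(scores), reverse=True):
        pos = scores >= t
        tp = int((labels[pos] == 1).sum())
        p = tp / pos.sum()
        r = tp / labels.sum()
        pts.append((t, r, p))
    pts.sort(key=lambda x: (x[1], -x[0]))  # recall ascending, threshold desc
    gains = []
    for _, r, p in pts:
        if r <= 0:
            continue
        rg = (r - pi) / ((1 - pi) * r)
        pg = min(max((p - pi) / ((1 - pi) * p), 0.0), 1.0)
        gains.append((rg, pg))
    cleaned = []
    for i, (rg, pg) in enumerate(gains):
        if rg < 0:
            nxt = gains[i + 1] if i + 1 < len(gains) else None
            if nxt is not None and nxt[0] >= 0:
                t = (0.0 - rg) / (nxt[0] - rg)
                cleaned.append((0.0, pg + t * (nxt[1] - pg)))
            continue
        cleaned.append((rg, pg))
    if not cleaned:
        return 0.0
    if cleaned[0][0] > 0:
        cleaned.insert(0, (0.0, cleaned[0][1]))
    auc = 0.0
    for (x0, y0), (x1, y1) in zip(cleaned, cleaned[1:]):
        auc += 0.5 * (y0 + y1) * (x1 - x0)
    return auc


def fgain_oracle(scores, labels):
    """Exhaustive sweep of 'score > threshold' over unique scores and +inf."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, int)
    pi = labels.mean()
    n_gold = labels.sum()
    best = 0.0
    for t in list(np.unique(scores)) + [np.inf]:
        pos = scores > t
        tp = int((labels[pos] == 1).sum())
        denom = pos.sum() + n_gold
        f1 = 2 * tp / denom if denom else 0.0
        if f1 > 0:
            best = max(best, (f1 - pi) / ((1 - pi) * f1))
    return 100.0 * best


def binom_tail_oracle(hits, n, p):
    return sum(math.comb(n, k) * p**k * (1 - p) ** (n - k) for k in range(hits, n + 1))


# ------------------------------------------------------------- top-k F1

class TestTopK:
    def test_perfect_retrieval_at_gold_size(self):
        iv, gold = make_case([0.1, 0.9, 0.2, 0.8, 0.05], {2, 4})
        assert topk_f1_curve(iv, gold, 2)[1] == pytest.approx(1.0)

    def test_partial_hit(self):
        iv, gold = make_case([0, 0, 5, 0, 0, 0, 4, 0, 0, 0], {3})
        assert topk_f1_curve(iv, gold, 2)[1] == pytest.approx(2 / 3)

    def test_disjoint_topk_scores_zero(self):
        iv, gold = make_case([9, 8, 0, 0, 0], {4, 5})
        assert topk_f1_curve(iv, gold, 2)[1] == pytest.approx(0.0)

    def test_ties_break_by_ascending_position(self):
        iv, gold = make_case([1.0, 1.0, 1.0], {1})
        assert topk_f1_curve(iv, gold, 1)[0] == pytest.approx(1.0)

    def test_monotone_decay_beyond_gold_size_for_perfect_ranking(self):
        iv, gold = make_case([9, 8, 7, 0.3, 0.2, 0.1], {1, 2, 3})
        curve = topk_f1_curve(iv, gold, 6)
        assert curve[2] == pytest.approx(1.0)
        assert all(curve[k] >= curve[k + 1] for k in range(2, 5))

    def test_sequence_without_gold_excluded_with_warning(self):
        iv, gold = make_case([1, 2, 3], {1})
        iv.append(ImportanceVector("orphan", [1.0, 2.0], "m"))
        with pytest.warns(UserWarning, match="orphan"):
            topk_f1_curve(iv, gold, 1)


# ------------------------------------------------------------ PRG curves

class TestPRG:
    def test_perfect_ranking_has_unit_auc(self):
        iv, gold = make_case(np.r_[[10, 9], np.linspace(1, 0.1, 18)], {1, 2})
        assert pooled_pr_and_prg(iv, gold).auc == pytest.approx(1.0)

    def test_reversed_ranking_has_zero_auc(self):
        iv, gold = make_case(np.r_[[-10, -9], -np.linspace(1, 0.1, 18)], {1, 2})
        assert pooled_pr_and_prg(iv, gold).auc == pytest.approx(0.0)

    def test_four_residue_example_matches_oracle(self):
        scores = [0.9, 0.8, 0.1, 0.05]
        iv, gold = make_case(scores, {1, 3})
        curve = pooled_pr_and_prg(iv, gold)
        expected = prg_auc_oracle(scores, [1, 0, 1, 0])
        assert curve.auc == pytest.approx(expected, abs=1e-9)
        assert curve.auc == pytest.approx(0.25, abs=1e-9)  # frozen fixture
        assert curve.prevalence == pytest.approx(0.5)

    @pytest.mark.parametrize("seed", range(10))
    def test_random_scores_match_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = 40
        scores = rng.normal(size=n)
        gold_pos = set(rng.choice(n, size=5, replace=False) + 1)
        iv, gold = make_case(scores, gold_pos)
        labels = np.zeros(n, int)
        labels[[p - 1 for p in gold_pos]] = 1
        assert pooled_pr_and_prg(iv, gold).auc == pytest.approx(
            prg_auc_oracle(scores, labels), abs=1e-9
        )

    def test_degenerate_prevalence_rejected(self):
        iv, gold = make_case([1, 2, 3], set())
        with pytest.raises(ValueError):
            pooled_pr_and_prg(iv, gold)
        iv, gold = make_case([1, 2, 3], {1, 2, 3})
        with pytest.raises(ValueError):
            pooled_pr_and_prg(iv, gold)

    def test_per_protein_curves(self):
        iv1, gold1 = make_case([9, 1, 1, 1], {1}, "a")
        iv2, gold2 = make_case([1, 9, 1, 1], {2}, "b")
        pooled, per = pooled_pr_and_prg(iv1 + iv2, {**gold1, **gold2}, per_protein=True)
        assert per["a"].auc == pytest.approx(1.0)
        assert per["b"].auc == pytest.approx(1.0)

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(3)
        scores = rng.normal(size=30)
        gold_pos = {3, 11, 19}
        iv1, gold = make_case(scores, gold_pos)
        iv2, _ = make_case(np.exp(scores) + 3 * scores, gold_pos)
        assert pooled_pr_and_prg(iv1, gold).auc == pytest.approx(
            pooled_pr_and_prg(iv2, gold).auc, abs=1e-12
        )


# ----------------------------------------------------------- max F-Gain

class TestMaxFGain:
    def test_constant_scores_have_zero_gain(self):
        iv, gold = make_case(np.ones(20), {1, 2})
        assert max_fgain(iv, gold)[0] == pytest.approx(0.0)

    def test_perfect_separation_reaches_100(self):
        iv, gold = make_case(np.r_[[10, 9], np.zeros(18)], {1, 2})
        gain, thr = max_fgain(iv, gold)
        assert gain == pytest.approx(100.0)
        assert thr < 9

    def test_ten_residue_toy_matches_sweep_oracle(self):
        scores = [0.9, 0.7, 0.6, 0.5, 0.4, 0.35, 0.3, 0.2, 0.1, 0.05]
        iv, gold = make_case(scores, {1, 5})
        labels = [1, 0, 0, 0, 1, 0, 0, 0, 0, 0]
        gain, thr = max_fgain(iv, gold)
        assert gain == pytest.approx(fgain_oracle(scores, labels), abs=1e-9)
        assert gain == pytest.approx(87.5, abs=1e-9)  # frozen fixture
        assert thr == pytest.approx(0.7)

    @pytest.mark.parametrize("seed", range(10))
    def test_random_scores_match_oracle(self, seed):
        rng = np.random.default_rng(100 + seed)
        n = 30
        scores = np.round(rng.normal(size=n), 2)  # rounding forces ties
        gold_pos = set(rng.choice(n, size=4, replace=False) + 1)
        labels = np.zeros(n, int)
        labels[[p - 1 for p in gold_pos]] = 1
        iv, gold = make_case(scores, gold_pos)
        assert max_fgain(iv, gold)[0] == pytest.approx(
            fgain_oracle(scores, labels), abs=1e-9
        )

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(4)
        scores = rng.normal(size=30)
        iv1, gold = make_case(scores, {5, 6})
        iv2, _ = make_case(2 * scores + 1, {5, 6})
        assert max_fgain(iv1, gold)[0] == pytest.approx(max_fgain(iv2, gold)[0], abs=1e-9)

    def test_empty_gold_rejected(self):
        iv, gold = make_case([1, 2, 3], set())
        with pytest.raises(ValueError):
            max_fgain(iv, gold)


# ------------------------------------------------------------ rescaling

class TestRescale:
    def test_minmax_spans_unit_interval(self):
        x = rescale_scores(np.array([2.0, 4.0, 6.0]), "minmax")
        np.testing.assert_allclose(x, [0.0, 0.5, 1.0])

    def test_zscore_standardises(self):
        x = rescale_scores(np.random.default_rng(0).normal(5, 3, 100), "zscore")
        assert abs(x.mean()) < 1e-12 and abs(x.std() - 1) < 1e-12

    def test_norm_modes(self):
        x = np.array([3.0, -4.0])
        np.testing.assert_allclose(np.abs(rescale_scores(x, "l1")).sum(), 1.0)
        np.testing.assert_allclose(np.linalg.norm(rescale_scores(x, "l2")), 1.0)

    def test_constant_input_maps_to_zeros(self):
        for mode in ("minmax", "zscore"):
            np.testing.assert_allclose(rescale_scores(np.ones(5), mode), 0.0)

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError):
            rescale_scores(np.ones(3), "sqrt")


# ------------------------------------------------------- enrichment test

class TestEnrichment:
    def test_worked_enrichment_examples(self):
        assert enrichment_test(6, 10, 21, 271).p_value == pytest.approx(0.00003)
        assert enrichment_test(2, 10, 10, 907).p_value == pytest.approx(0.00516)

    def test_zero_hits_certain(self):
        assert enrichment_test(0, 10, 21, 271).p_value_full == pytest.approx(1.0)

    def test_strictly_decreasing_in_hits(self):
        ps = [enrichment_test(h, 10, 21, 271).p_value_full for h in range(11)]
        assert all(a > b for a, b in zip(ps, ps[1:]))

    @pytest.mark.parametrize("n", [1, 4, 8, 12])
    def test_matches_exhaustive_enumeration(self, n):
        p = 21 / 271
        for hits in range(n + 1):
            assert enrichment_test(hits, n, 21, 271).p_value_full == pytest.approx(
                binom_tail_oracle(hits, n, p), abs=1e-12
            )

    def test_bounds_validated(self):
        with pytest.raises(ValueError):
            enrichment_test(11, 10, 21, 271)
        with pytest.raises(ValueError):
            enrichment_test(1, 10, 0, 271)

    def test_gain_of_prevalence_is_zero(self):
        # the always-positive classifier's precision equals the prevalence,
        # so its precision-gain vanishes by construction
        pi = 0.0116
        assert (pi - pi) / ((1 - pi) * pi) == 0.0


# -------------------------------------------------------- compare_methods

class TestCompareMethods:
    def test_perfect_method_row(self):
        iv, gold = make_case(np.r_[[10, 9], np.zeros(18)], {1, 2})
        report = compare_methods({"perfect": iv}, gold, shuffle_reps=3, seed=0)
        row = report.rows["perfect"]
        assert row["prg_auc"] == pytest.approx(100.0)
        assert row["max_fgain"] == pytest.approx(100.0)
        assert set(report.baseline) >= {"prg_auc_mean", "prg_auc_std",
                                        "max_fgain_mean", "max_fgain_std"}

    def test_identical_methods_identical_rows(self):
        iv, gold = make_case([5, 1, 4, 1, 1, 1, 1, 1], {1, 3})
        report = compare_methods({"m1": iv, "m2": iv}, gold, shuffle_reps=2, seed=0)
        assert report.rows["m1"]["prg_auc"] == report.rows["m2"]["prg_auc"]
        assert report.rows["m1"]["max_fgain"] == report.rows["m2"]["max_fgain"]

    def test_missing_sequence_error_names_it(self):
        iv, gold = make_case([1, 2, 3], {1}, "a")
        gold["ghost"] = GoldAnnotation("ghost", frozenset({1}), 3)
        with pytest.raises(ValueError, match="ghost"):
            compare_methods({"m": iv}, gold)

    def test_text_table_mentions_columns(self):
        iv, gold = make_case(np.r_[[10, 9], np.zeros(18)], {1, 2})
        text = compare_methods({"m": iv}, gold, shuffle_reps=2, seed=0).as_text()
        assert "PRG-AUC" in text and "F-Gain" in text and "Random" in text
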