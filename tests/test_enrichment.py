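"""GSEA running sum, ssGSEA, stratification, log-rank and BH correction."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from coessnet.enrichment import (
    bh_adjust,
    logrank_test,
    preranked_gsea,
    preranked_gsea_batch,
    rank_scores,
    select_driver_modules,
    ssgsea,
    ssgsea_matrix,
    stratify_patients,
)


def running_sum_oracle(scores, gene_set, weight=1.0):
    """Brute-force evaluation of the weighted KS running sum."""
    ranked = sorted(scores.items(), key=lambda kv: (-kv[1], kv[0]))
    hits = [(g, abs(s) ** weight) for g, s in ranked if g in gene_set]
    denom = sum(w for _, w in hits)
    n, m = len(ranked), len(hits)
    total, best = 0.0, 0.0
    for g, s in ranked:
        if g in gene_set:
            total += (abs(s) ** weight) / denom
        else:
            total -= 1.0 / (n - m)
        if abs(total) > abs(best):
            best = total
    return best


class TestRankScores:
    def test_descending_with_lexicographic_ties(self):
        s = pd.Series({"b": 1.0, "a": 1.0, "c": 2.0})
        assert list(rank_scores(s).index) == ["c", "a", "b"]

    def test_duplicate_genes_rejected(self):
        s = pd.Series([1.0, 2.0], index=["a", "a"])
        with pytest.raises(ValueError):
            rank_scores(s)


class TestPrerankedGsea:
    four = pd.Series({"g1": 4.0, "g2": 3.0, "g3": 2.0, "g4": 1.0})

    def test_top_gene_set_gives_es_one(self):
        res = preranked_gsea(self.four, {"g1"}, n_perm=50, seed=0)
        assert res.es == pytest.approx(1.0)

    def test_bottom_gene_set_gives_es_minus_one(self):
        res = preranked_gsea(self.four, {"g4"}, n_perm=50, seed=0)
        assert res.es == pytest.approx(-1.0)

    def test_full_list_set_gives_es_one(self):
        res = preranked_gsea(self.four, set(self.four.index), n_perm=50, seed=0)
        assert res.es == pytest.approx(1.0)

    def test_matches_running_sum_oracle(self, rng):
        genes = [f"g{i}" for i in range(30)]
        scores = pd.Series(rng.standard_normal(30), index=genes)
        for pick in range(3):
            sub = set(rng.choice(genes, size=6, replace=False))
            res = preranked_gsea(scores, sub, n_perm=10, seed=pick)
            assert res.es == pytest.approx(
                running_sum_oracle(dict(scores), sub), abs=1e-12
            )

    def test_es_bounded_and_scale_invariant(self, rng):
        genes = [f"g{i}" for i in range(25)]
        scores = pd.Series(rng.exponential(size=25), index=genes)
        sub = set(genes[3:9])
        res = preranked_gsea(scores, sub, n_perm=20, seed=0)
        assert -1 <= res.es <= 1
        scaled = preranked_gsea(scores * 13.7, sub, n_perm=20, seed=0)
        assert scaled.es == pytest.approx(res.es)

    def test_nes_sign_matches_es_and_is_reproducible(self, rng):
        genes = [f"g{i}" for i in range(40)]
        scores = pd.Series(np.linspace(5, -5, 40), index=genes)
        res1 = preranked_gsea(scores, set(genes[:8]), n_perm=200, seed=3)
        res2 = preranked_gsea(scores, set(genes[:8]), n_perm=200, seed=3)
        assert res1.nes == res2.nes
        assert np.sign(res1.nes) == np.sign(res1.es)

    def test_empty_intersection_raises(self):
        with pytest.raises(ValueError, match="intersect"):
            preranked_gsea(self.four, {"zz"}, n_perm=10, seed=0)

    def test_doubling_permutations_stable_nes(self):
        rng = np.random.default_rng(11)
        scores = pd.Series(rng.standard_normal(60), index=[f"g{i}" for i in range(60)])
        sub = set(scores.nlargest(10).index)
        n1 = preranked_gsea(scores, sub, n_perm=500, seed=0).nes
        n2 = preranked_gsea(scores, sub, n_perm=1000, seed=0).nes
        assert abs(n1 - n2) / abs(n1) < 0.1


class TestSsgsea:
    def test_top_ranked_set_scores_positive_and_maximal(self):
        sample = pd.Series({f"g{i}": 10.0 - i for i in range(10)})
        top = ssgsea(sample, {"g0", "g1", "g2"})
        others = [
            ssgsea(sample, set(c))
            for c in [("g3", "g4", "g5"), ("g7", "g8", "g9"), ("g0", "g5", "g9")]
        ]
        assert top > 0
        assert all(top > o for o in others)

    def test_matches_direct_summation_oracle(self):
        sample = pd.Series({"a": 3.0, "b": 1.0, "c": 2.0, "d": 5.0, "e": 4.0})
        gene_set = {"d", "c"}
        exponent = 0.25
        # direct summation: order genes by value desc, rank weights rank**0.25
        order = ["d", "e", "a", "c", "b"]
        ranks = {"d": 5, "e": 4, "a": 3, "c": 2, "b": 1}
        hit_w = [ranks[g] ** exponent if g in gene_set else 0.0 for g in order]
        total_hit = sum(hit_w)
        cum_hit = np.cumsum(hit_w) / total_hit
        cum_miss = np.cumsum([0 if g in gene_set else 1 for g in order]) / 3
        expected = float(np.sum(cum_hit - cum_miss))
        assert ssgsea(sample, gene_set, exponent) == pytest.approx(expected, abs=1e-12)

    def test_identical_samples_get_identical_scores(self):
        expr = pd.DataFrame(
            [[1.0, 2.0, 3.0, 4.0]] * 2 + [[4.0, 3.0, 2.0, 1.0]],
            index=["p1", "p2", "p3"],
            columns=list("abcd"),
        )
        scores = ssgsea_matrix(expr, {"a", "b"})
        assert scores["p1"] == scores["p2"]

    def test_empty_intersection_raises(self):
        with pytest.raises(ValueError, match="intersect"):
            ssgsea(pd.Series({"a": 1.0}), {"zz"})


class TestSelectDriverModules:
    def test_top_module_selected_bottom_not(self, rng):
        genes = [f"g{i}" for i in range(100)]
        prop = pd.Series(np.linspace(1.0, 0.0, 100), index=genes)
        pathways = {
            "top": genes[:10],
            "bottom": genes[-10:],
            "spread": genes[::10],
        }
        selected = select_driver_modules(prop, pathways, n_perm=500, seed=0)
        assert "top" in selected
        assert "bottom" not in selected

    def test_no_pathway_passing_returns_empty(self, rng):
        genes = [f"g{i}" for i in range(50)]
        prop = pd.Series(rng.random(50), index=genes)
        selected = select_driver_modules(
            prop, {"s": list(rng.choice(genes, 8, replace=False))}, n_perm=100, seed=0
        )
        assert selected == []


class TestStratifyPatients:
    def make_expr(self, n_patients, rng):
        genes = [f"g{i}" for i in range(20)]
        activity = np.linspace(-2, 2, n_patients)
        expr = rng.normal(0, 0.1, size=(n_patients, 20))
        expr[:, :5] += activity[:, None]
        return pd.DataFrame(expr, index=[f"p{i}" for i in range(n_patients)], columns=genes)

    def test_even_count_splits_in_half(self, rng):
        expr = self.make_expr(4, rng)
        groups = stratify_patients(expr, {"g0", "g1", "g2", "g3", "g4"})
        assert (groups["group"] == "up").sum() == 2

    def test_odd_count_median_goes_down(self, rng):
        expr = self.make_expr(5, rng)
        groups = stratify_patients(expr, {"g0", "g1", "g2", "g3", "g4"})
        assert (groups["group"] == "up").sum() == 2
        assert (groups["group"] == "down").sum() == 3

    def test_patient_order_irrelevant(self, rng):
        expr = self.make_expr(6, rng)
        g1 = stratify_patients(expr, {"g0", "g1"})
        g2 = stratify_patients(expr.iloc[::-1], {"g0", "g1"})
        assert (g1["group"].sort_index() == g2["group"].sort_index()).all()

    def test_high_module_patients_are_up(self, rng):
        expr = self.make_expr(10, rng)
        groups = stratify_patients(expr, {"g0", "g1", "g2", "g3", "g4"})
        # activity increases with patient index
        assert (groups.loc[["p8", "p9"], "group"] == "up").all()


class TestLogrank:
    def test_mirrored_groups_give_chi2_zero(self):
        surv = pd.DataFrame(
            {
                "time": [5, 10, 15, 5, 10, 15],
                "event": [1, 0, 1, 1, 0, 1],
                "group": ["up"] * 3 + ["down"] * 3,
            }
        )
        chi2, p = logrank_test(surv)
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_matches_hand_computed_oracle(self):
        # independent O-E / V computation over pooled event times
        surv = pd.DataFrame(
            {
                "time": [1, 2, 3, 4, 5, 6, 7, 8],
                "event": [1, 1, 1, 0, 1, 1, 0, 1],
                "group": ["a", "a", "a", "a", "b", "b", "b", "b"],
            }
        )
        n_a, n_b = 4, 4
        o_minus_e, var = 0.0, 0.0
        at_risk_a, at_risk_b = n_a, n_b
        for _, row in surv.sort_values("time").iterrows():
            n = at_risk_a + at_risk_b
            if row["event"] == 1:
                d = 1
                e_a = d * at_risk_a / n
                if n > 1:
                    var += d * (at_risk_a / n) * (at_risk_b / n) * (n - d) / (n - 1)
                o_minus_e += (1 if row["group"] == "a" else 0) - e_a
            if row["group"] == "a":
                at_risk_a -= 1
            else:
                at_risk_b -= 1
        expected_chi2 = o_minus_e**2 / var
        chi2, p = logrank_test(surv)
        assert chi2 == pytest.approx(expected_chi2, abs=1e-6)
        assert p == pytest.approx(stats.chi2.sf(expected_chi2, df=1), abs=1e-6)

    def test_separated_groups_significant(self, rng):
        surv = pd.DataFrame(
            {
                "time": np.r_[rng.exponential(5, 20), rng.exponential(50, 20)],
                "event": np.r_[np.ones(20), np.zeros(20)],
                "group": ["early"] * 20 + ["late"] * 20,
            }
        )
        chi2, p = logrank_test(surv)
        assert p < 0.05

    def test_time_rescaling_and_label_swap_invariance(self, rng):
        surv = pd.DataFrame(
            {
                "time": rng.exponential(10, 30),
                "event": rng.integers(0, 2, 30),
                "group": ["x"] * 15 + ["y"] * 15,
            }
        )
        if surv["event"].sum() == 0:
            surv.loc[0, "event"] = 1
        chi2, _ = logrank_test(surv)
        scaled = surv.assign(time=surv["time"] * 365.25)
        assert logrank_test(scaled)[0] == pytest.approx(chi2, abs=1e-9)
        swapped = surv.assign(group=surv["group"].map({"x": "y", "y": "x"}))
        assert logrank_test(swapped)[0] == pytest.approx(chi2, abs=1e-9)

    def test_zero_events_raise(self):
        surv = pd.DataFrame(
            {"time": [1, 2], "event": [0, 0], "group": ["a", "b"]}
        )
        with pytest.raises(ValueError, match="zero events"):
            logrank_test(surv)


class TestBhAdjust:
    def test_single_p_unchanged(self):
        assert bh_adjust([0.03])[0] == pytest.approx(0.03)

    def test_hand_worked_step_up(self):
        out = bh_adjust([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(out, [0.04, 0.04, 0.04, 0.04])

    def test_matches_hand_rolled_step_up_oracle(self, rng):
        p = rng.random(25)
        order = np.argsort(p)
        adj = np.empty_like(p)
        n = len(p)
        running = 1.0
        for rank_idx in range(n - 1, -1, -1):
            i = order[rank_idx]
            running = min(running, p[i] * n / (rank_idx + 1))
            adj[i] = running
        assert np.allclose(bh_adjust(p), adj)

    def test_all_ones_stay_one(self):
        assert np.allclose(bh_adjust([1.0, 1.0, 1.0]), 1.0)

    def test_output_at_least_input(self, rng):
        p = rng.random(40)
        assert (bh_adjust(p) >= p - 1e-12).all()

    def test_out_of_range_raises(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])


def test_batch_fdr_separates_signal_from_noise(rng):
    genes = [f"g{i}" for i in range(120)]
    prop = pd.Series(np.linspace(1.0, 0.0, 120), index=genes)
    sets = {"signal": genes[:12]}
    for k in range(5):
        sets[f"noise{k}"] = list(rng.choice(genes, 12, replace=False))
    table = preranked_gsea_batch(prop, sets, n_perm=300, seed=0)
    assert table.loc["signal", "fdr"] < 0.05
    assert table.loc["signal", "nes"] > 0
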