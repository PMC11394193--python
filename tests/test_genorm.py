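import math
import statistics

import numpy as np
import pytest

from refstab import (genorm_full, genorm_ranking, m_values,
                     pairwise_variation_matrix, relative_quantity, v_curve)
from refstab.genorm import normalization_factor
from conftest import make_cq_table, random_rel_quant


# --- independent brute-force oracle (pure python, double loops) ------------

def brute_pairwise(qdf):
    genes, cols = list(qdf.index), list(qdf.columns)
    out = {}
    for j in genes:
        for k in genes:
            if j == k:
                out[(j, k)] = 0.0
                continue
            ratios = [math.log2(qdf.loc[j, s] / qdf.loc[k, s]) for s in cols]
            out[(j, k)] = statistics.stdev(ratios)
    return out


def brute_m(qdf):
    genes = list(qdf.index)
    v = brute_pairwise(qdf)
    return {j: sum(v[(j, k)] for k in genes if k != j) / (len(genes) - 1)
            for j in genes}


def brute_v_curve(qdf, ranking):
    cols = list(qdf.columns)

    def nf(genes, s):
        return statistics.geometric_mean([qdf.loc[g, s] for g in genes])

    out = {}
    for n in range(2, len(ranking)):
        logs = [math.log2(nf(ranking[:n], s) / nf(ranking[: n + 1], s))
                for s in cols]
        out[n] = statistics.stdev(logs)
    return out


class TestPairwiseVariation:
    def test_constant_ratio_gives_zero(self):
        t = make_cq_table({"A": [20.0, 21.0, 22.0], "B": [18.0, 19.0, 20.0]},
                          groups=["GM"] * 3)
        v = pairwise_variation_matrix(relative_quantity(t))
        assert v.loc["A", "B"] == pytest.approx(0.0, abs=1e-12)

    def test_hand_value(self, three_gene_table):
        v = pairwise_variation_matrix(relative_quantity(three_gene_table))
        assert v.loc["A", "B"] == pytest.approx(1.0)
        assert v.loc["A", "C"] == pytest.approx(2.0)
        assert v.loc["B", "C"] == pytest.approx(1.0)
        np.testing.assert_allclose(v, v.T)
        np.testing.assert_allclose(np.diag(v), 0.0)

    def test_matches_brute_force_on_random_panels(self, rng):
        for _ in range(10):
            q = random_rel_quant(rng, 5, 6)
            v = pairwise_variation_matrix(q)
            brute = brute_pairwise(q.values)
            for j in q.genes:
                for k in q.genes:
                    assert v.loc[j, k] == pytest.approx(brute[(j, k)],
                                                        abs=1e-9)


class TestMValues:
    def test_hand_panel(self, three_gene_table):
        m = m_values(relative_quantity(three_gene_table))
        assert m["A"] == pytest.approx(1.5)
        assert m["B"] == pytest.approx(1.0)
        assert m["C"] == pytest.approx(1.5)

    def test_all_constant_ratios_give_zero_m(self):
        t = make_cq_table({"A": [20.0, 21.0], "B": [18.0, 19.0],
                           "C": [22.0, 23.0]}, groups=["GM", "GM"])
        m = m_values(relative_quantity(t))
        np.testing.assert_allclose(m, 0.0, atol=1e-12)

    def test_two_gene_collapse(self):
        t = make_cq_table({"A": [20.0, 20.0, 20.0], "B": [20.0, 21.0, 22.0]},
                          groups=["GM"] * 3)
        q = relative_quantity(t)
        m = m_values(q)
        v = pairwise_variation_matrix(q)
        assert m["A"] == m["B"] == pytest.approx(v.loc["A", "B"])

    def test_single_gene_rejected(self, three_gene_table):
        q = relative_quantity(three_gene_table).subset_genes(["A"])
        with pytest.raises(ValueError):
            m_values(q)


class TestRanking:
    def test_hand_trace_with_tie(self, three_gene_table):
        res = genorm_ranking(relative_quantity(three_gene_table))
        # A and C tie at M=1.5; lexicographic removal takes A (rank 3);
        # the final pair B,C is ordered by full-panel M: B=1.0 < C=1.5
        assert res.rank["A"] == 3
        assert res.rank["B"] == 1
        assert res.rank["C"] == 2
        assert res.trace[0]["tie"] == ["A", "C"]
        assert res.trace[-1]["final_pair_order"] == ["B", "C"]

    def test_designed_unstable_gene_removed_first(self, musc_q):
        res = genorm_ranking(musc_q)
        assert res.rank["ACTB"] == 10
        assert res.rank["GAPDH"] >= 8

    def test_mean_m_non_increasing_over_steps(self, rng):
        for _ in range(20):
            q = random_rel_quant(rng, 6, 8)
            res = genorm_ranking(q)
            means = [step["m"].mean() for step in res.trace]
            assert all(b <= a + 1e-12 for a, b in zip(means, means[1:]))


class TestVCurve:
    def test_identical_genes_give_zero_v(self):
        t = make_cq_table({f"G{i}": [20.0, 21.0, 22.0] for i in range(4)},
                          groups=["GM"] * 3)
        q = relative_quantity(t)
        v, n_opt, warn = v_curve(q, list(q.genes))
        np.testing.assert_allclose(v, 0.0, atol=1e-12)
        assert n_opt == 2 and warn is None

    def test_matches_brute_force(self, rng):
        for _ in range(10):
            q = random_rel_quant(rng, 5, 6)
            ranking = genorm_ranking(q).ordered_genes()
            v, _, _ = v_curve(q, ranking)
            brute = brute_v_curve(q.values, ranking)
            for n in brute:
                assert v[n] == pytest.approx(brute[n], abs=1e-9)

    def test_musc_panel_needs_two_genes(self, musc_q):
        res = genorm_full(musc_q)
        assert res.v_values[2] < 0.15
        assert res.optimal_n == 2

    def test_no_v_below_threshold_warns_and_reports_k(self, rng):
        q = random_rel_quant(rng, 4, 6)
        with pytest.warns(UserWarning, match="below"):
            v, n_opt, warn = v_curve(q, genorm_ranking(q).ordered_genes(),
                                     threshold=1e-6)
        assert n_opt == 4 and warn is not None


class TestInvariances:
    def test_loading_shift_invariance(self, rng):
        # adding a per-sample constant to every gene's Cq leaves M and V
        # untouched (to 1e-9): this is what normalization is meant to absorb
        cq = rng.uniform(16, 28, size=(5, 6))
        shifts = rng.uniform(-2, 2, size=6)
        genes = [f"G{i}" for i in range(5)]
        groups = ["X"] * 3 + ["Y"] * 3
        t1 = make_cq_table({g: list(cq[i]) for i, g in enumerate(genes)},
                           groups=groups, bio_reps=[1, 2, 3, 1, 2, 3])
        t2 = make_cq_table(
            {g: list(cq[i] + shifts) for i, g in enumerate(genes)},
            groups=groups, bio_reps=[1, 2, 3, 1, 2, 3])
        q1, q2 = relative_quantity(t1), relative_quantity(t2)
        np.testing.assert_allclose(m_values(q1), m_values(q2), atol=1e-9)
        r1, r2 = genorm_ranking(q1), genorm_ranking(q2)
        v1, _, _ = v_curve(q1, r1.ordered_genes())
        v2, _, _ = v_curve(q2, r2.ordered_genes())
        np.testing.assert_allclose(v1, v2, atol=1e-9)

    def test_per_gene_shift_invariance(self, rng):
        cq = rng.uniform(16, 28, size=(4, 5))
        gene_shifts = rng.uniform(-3, 3, size=4)
        genes = [f"G{i}" for i in range(4)]
        t1 = make_cq_table({g: list(cq[i]) for i, g in enumerate(genes)},
                           groups=["GM"] * 5)
        t2 = make_cq_table(
            {g: list(cq[i] + gene_shifts[i]) for i, g in enumerate(genes)},
            groups=["GM"] * 5)
        np.testing.assert_allclose(m_values(relative_quantity(t1)),
                                   m_values(relative_quantity(t2)),
                                   atol=1e-12)

    def test_normalization_factor_is_geometric_mean(self, musc_q):
        nf = normalization_factor(musc_q, ["RPL14", "RPS15A"])
        manual = np.sqrt(musc_q.values.loc["RPL14"]
                         * musc_q.values.loc["RPS15A"])
        np.testing.assert_allclose(nf, manual, atol=1e-12)
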