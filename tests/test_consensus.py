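import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from refstab import (PipelineConfig, StabilityResult, compare_normalizations,
                     comprehensive_ranking, ddct_fold_change,
                     geometric_mean_rank, run_pipeline, simulate_cq_panel,
                     simulate_musc_panel)
from refstab.published import (published_comprehensive_order,
                               published_mean_ranks, published_method_ranks)
from refstab.synthetic import SimTruth
from refstab.io_model import collapse_technical_replicates
from conftest import make_cq_table


def stab(method, ranks: dict[str, int]) -> StabilityResult:
    s = pd.Series({g: float(r) for g, r in ranks.items()})
    return StabilityResult(method, s, pd.Series(ranks))


class TestGeometricMeanRank:
    def test_published_triplets(self):
        ranks = published_method_ranks()
        mean = geometric_mean_rank(ranks)
        assert mean["RPL14"] == pytest.approx((1 * 1 * 4) ** (1 / 3))
        assert round(mean["RPL14"], 2) == 1.59
        assert round(mean["ACTB"], 2) == 10.00

    def test_equal_ranks_identity(self):
        for r in (1, 3, 7):
            ranks = pd.DataFrame({"m1": [r], "m2": [r], "m3": [r]},
                                 index=["g"])
            assert geometric_mean_rank(ranks)["g"] == pytest.approx(r)

    def test_missing_rank_names_gene_and_method(self):
        ranks = pd.DataFrame({"m1": [1.0, 2.0], "m2": [np.nan, 1.0]},
                             index=["g1", "g2"])
        with pytest.raises(ValueError, match=r"g1.*m2"):
            geometric_mean_rank(ranks)

    def test_arithmetic_mode(self):
        ranks = pd.DataFrame({"m1": [1], "m2": [4]}, index=["g"])
        assert geometric_mean_rank(ranks, "arithmetic")["g"] == 2.5
        assert geometric_mean_rank(ranks)["g"] == pytest.approx(2.0)


class TestComprehensiveRanking:
    def three_method_results(self):
        ranks = published_method_ranks()
        return [stab(m, dict(ranks[m])) for m in ranks.columns]

    def test_published_three_method_consensus(self):
        cons = comprehensive_ranking(self.three_method_results())
        assert cons.ordered_genes() == published_comprehensive_order()
        np.testing.assert_allclose(cons.mean_rank.round(2),
                                   published_mean_ranks()[cons.mean_rank.index],
                                   atol=1e-9)

    def test_single_method_rejected(self):
        with pytest.raises(ValueError, match=">= 2"):
            comprehensive_ranking(self.three_method_results()[:1])

    def test_inconsistent_gene_sets_rejected(self):
        a = stab("m1", {"g1": 1, "g2": 2})
        b = stab("m2", {"g1": 1, "g3": 2})
        with pytest.raises(ValueError, match="inconsistent"):
            comprehensive_ranking([a, b])

    def test_symmetric_in_method_order(self):
        results = self.three_method_results()
        ref = comprehensive_ranking(results).final_rank
        for perm in itertools.permutations(results):
            got = comprehensive_ranking(list(perm)).final_rank
            pd.testing.assert_series_equal(ref, got, check_names=False)

    def test_improving_one_rank_never_worsens_mean_rank(self):
        base = {"g1": 3, "g2": 1, "g3": 2}
        better = {"g1": 2, "g2": 1, "g3": 3}
        other = {"g1": 2, "g2": 3, "g3": 1}
        m0 = comprehensive_ranking([stab("a", base), stab("b", other)])
        m1 = comprehensive_ranking([stab("a", better), stab("b", other)])
        assert m1.mean_rank["g1"] <= m0.mean_rank["g1"]

    def test_tie_broken_by_best_single_method_rank(self):
        a = stab("m1", {"g1": 1, "g2": 4, "g3": 2, "g4": 3})
        b = stab("m2", {"g1": 4, "g2": 1, "g3": 3, "g4": 2})
        cons = comprehensive_ranking([a, b])
        # g1/g2 tie at gmean 2, g3/g4 tie at sqrt(6); best-rank then
        # lexicographic ordering decides
        assert cons.ordered_genes() == ["g1", "g2", "g3", "g4"]


class TestCompareNormalizations:
    def spiked_tables(self):
        # target follows the differentiation response; the unstable
        # normalizer shares it, so normalizing by it masks the change
        base = {f"R{i}": 17.0 + i * 0.5 for i in range(3)}
        base.update({"BAD": 16.0, "TGT": 22.0})
        effects = {
            "TGT": {"GM": 0.0, "DM1": 0.5, "DM5": 1.2},
            "BAD": {"GM": 0.0, "DM1": 0.5, "DM5": 1.2},
        }
        truth = SimTruth(base, effects, 0.3, 0.15, seed=12)
        table, _ = simulate_cq_panel(truth, 3, 3, 3)
        collapsed, _ = collapse_technical_replicates(table)
        return {
            "stable": ddct_fold_change(collapsed, "TGT", ["R0"], "GM"),
            "unstable": ddct_fold_change(collapsed, "TGT", ["BAD"], "GM"),
        }

    def test_flat_groups_give_f_zero_p_one(self):
        # identical group means (noise mirrored across groups), nonzero
        # within-group variance: between-group mean square is exactly 0
        vals = np.array([0.1, -0.05, -0.05, 0.1, -0.05, -0.05]) + 20.0
        t = make_cq_table({"T": list(vals), "R": [20.0] * 6, "S": [18.0] * 6},
                          groups=["GM"] * 3 + ["DM1"] * 3,
                          bio_reps=[1, 2, 3, 1, 2, 3])
        fc = ddct_fold_change(t, "T", ["R"], "GM")
        cmp = compare_normalizations({"R": fc})["R"]
        assert cmp.f_statistic == pytest.approx(0.0, abs=1e-12)
        assert cmp.p_value == pytest.approx(1.0, abs=1e-9)

    def test_two_group_anova_equals_pooled_t_test(self, rng):
        folds = rng.uniform(0.5, 2.0, size=8)
        t = make_cq_table(
            {"T": list(20.0 - np.log2(folds)), "R": [20.0] * 8,
             "S": [18.0] * 8},
            groups=["GM"] * 4 + ["DM1"] * 4, bio_reps=[1, 2, 3, 4, 1, 2, 3, 4])
        fc = ddct_fold_change(t, "T", ["R"], "GM")
        cmp = compare_normalizations({"R": fc})["R"]
        a = fc.per_sample.loc[fc.per_sample["group"] == "GM", "fold"]
        b = fc.per_sample.loc[fc.per_sample["group"] == "DM1", "fold"]
        tt = stats.ttest_ind(a, b, equal_var=True)
        assert cmp.f_statistic == pytest.approx(tt.statistic ** 2, rel=1e-9)
        assert cmp.p_value == pytest.approx(tt.pvalue, rel=1e-9)

    def test_unstable_normalizer_masks_true_group_difference(self):
        comps = compare_normalizations(self.spiked_tables())
        stable, unstable = comps["stable"], comps["unstable"]

        def pair_label(cmp, a, b):
            rows = cmp.pairwise
            hit = rows[((rows["group_a"] == a) & (rows["group_b"] == b))
                       | ((rows["group_a"] == b) & (rows["group_b"] == a))]
            return hit["label"].iloc[0]

        assert pair_label(stable, "GM", "DM5") in ("*", "**")
        assert pair_label(unstable, "GM", "DM5") == "ns"
        assert stable.p_value < 0.05

    def test_degenerate_groups_rejected(self):
        t = make_cq_table({"T": [20.0, 21.0], "R": [20.0, 20.0],
                           "S": [19.0, 19.0]},
                          groups=["GM", "DM1"], bio_reps=[1, 1])
        fc = ddct_fold_change(t, "T", ["R"], "GM")
        with pytest.raises(ValueError, match="2 replicates"):
            compare_normalizations({"R": fc})


class TestRunPipeline:
    def test_musc_panel_end_to_end(self, tmp_path):
        table, truth = simulate_musc_panel(21)
        bundle = run_pipeline(PipelineConfig(), table, out_dir=tmp_path)
        cons = bundle.consensus
        assert len(cons.final_rank) == 10
        assert cons.final_rank["ACTB"] == 10
        stable_ranks = {cons.final_rank[g] for g in truth.stable_genes}
        assert stable_ranks == set(range(1, 9))
        assert (tmp_path / "consensus.csv").exists()
        assert (tmp_path / "report.log").exists()

    def test_rerun_is_byte_identical(self, tmp_path):
        table, _ = simulate_musc_panel(4)
        d1, d2 = tmp_path / "a", tmp_path / "b"
        run_pipeline(PipelineConfig(), table, out_dir=d1)
        run_pipeline(PipelineConfig(), table, out_dir=d2)
        for name in ("genorm.csv", "genorm_v.csv", "normfinder.csv",
                     "bestkeeper.csv", "deltact.csv", "consensus.csv"):
            assert (d1 / name).read_bytes() == (d2 / name).read_bytes()

    def test_single_group_falls_back_to_ungrouped(self):
        base = {f"G{i}": 18.0 + i * 0.4 for i in range(5)}
        truth = SimTruth(base, {}, 0.2, 0.1, seed=6)
        table, _ = simulate_cq_panel(truth, 1, 6, 2, group_names=("GM",))
        bundle = run_pipeline(PipelineConfig(), table)
        assert not bundle.normfinder.grouped

    def test_stage_name_in_errors(self):
        t = make_cq_table({"A": [20.0, 21.0], "B": [19.0, 20.0]},
                          groups=["GM", "GM"], bio_reps=[1, 2])
        with pytest.raises(RuntimeError, match="stage"):
            run_pipeline(PipelineConfig(), t)    # 2 genes: genorm refuses
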