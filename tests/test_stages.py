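import numpy as np
import pytest

import carriermod as cm
from carriermod.stages import (
    AnalysisRanking,
    SelectionConfig,
    _quotas,
    combine_stages,
    select_snps,
)


def literal_selection_oracle(rankings, ld, config):
    """Direct re-application of the published selection rules, written as
    plain loops independent of the implementation."""
    quotas = _quotas(config.budget, config.proportions)
    chosen = []
    group = {}
    for r in sorted(rankings, key=lambda x: x.analysis_id):
        gate = config.p_gate_main if r.analysis_id in (1, 2) else config.p_gate_other
        quota = quotas[r.analysis_id - 1]
        taken = 0
        for snp, p in zip(r.snp_ids, r.p_values):
            if taken >= quota:
                break
            if snp in chosen:
                continue
            anchor = next(
                (s for s in chosen if ld.get(frozenset((snp, s)), 0.0) >= config.r2_cap),
                None,
            )
            if anchor is not None:
                if p >= gate or group.get(anchor, 0) >= config.max_correlated:
                    continue
                group[anchor] = group.get(anchor, 0) + 1
            chosen.append(snp)
            taken += 1
    return chosen


class TestSelectSNPs:
    def twelve_snp_toy(self):
        r1 = AnalysisRanking(
            1,
            [f"a{i}" for i in range(8)],
            [1e-7, 5e-7, 1e-6, 5e-6, 1e-5, 5e-5, 1e-3, 1e-2],
        )
        r2 = AnalysisRanking(
            2,
            ["a0", "b0", "b1", "b2", "b3"],
            [1e-7, 2e-7, 8e-7, 2e-6, 5e-1],
        )
        ld = {
            frozenset(("a0", "a1")): 0.95,  # admitted: P gates pass
            frozenset(("a0", "a2")): 0.93,  # admitted (second in group)
            frozenset(("a0", "a3")): 0.96,  # blocked: group already has 2
            frozenset(("a4", "a6")): 0.91,  # blocked: P above the gate
            frozenset(("b0", "b1")): 0.99,  # admitted in analysis 2
        }
        cfg = SelectionConfig(budget=9, proportions=(0.6, 0.4))
        return [r1, r2], ld, cfg

    def test_rule_replay_oracle(self):
        rankings, ld, cfg = self.twelve_snp_toy()
        picked = select_snps(rankings, ld, cfg)
        oracle = literal_selection_oracle(rankings, ld, cfg)
        got_first_pass = [s.snp_id for s in picked if s.rule != "spill"]
        assert got_first_pass[: len(oracle)] == oracle

    def test_correlated_admissions_annotated(self):
        rankings, ld, cfg = self.twelve_snp_toy()
        picked = {s.snp_id: s for s in select_snps(rankings, ld, cfg)}
        assert picked["a1"].rule == "correlated_admission"
        assert picked["a2"].rule == "correlated_admission"
        assert "a3" not in picked  # third member of the LD group blocked

    def test_no_duplicate_selections(self):
        rankings, ld, cfg = self.twelve_snp_toy()
        picked = select_snps(rankings, ld, cfg)
        ids = [s.snp_id for s in picked]
        assert len(ids) == len(set(ids))
        # a0 ranked first in both analyses: provenance from analysis 1
        a0 = next(s for s in picked if s.snp_id == "a0")
        assert a0.analysis_id == 1

    def test_budget_at_least_all_candidates_selects_everything(self):
        r1 = AnalysisRanking(1, ["x1", "x2"], [0.1, 0.2])
        r2 = AnalysisRanking(2, ["x2", "x3"], [0.05, 0.3])
        cfg = SelectionConfig(budget=3, proportions=(0.5, 0.5))
        picked = select_snps([r1, r2], {}, cfg)
        assert sorted(s.snp_id for s in picked) == ["x1", "x2", "x3"]

    def test_invariant_to_ranking_input_order(self):
        rankings, ld, cfg = self.twelve_snp_toy()
        a = [(s.snp_id, s.analysis_id) for s in select_snps(rankings, ld, cfg)]
        b = [(s.snp_id, s.analysis_id) for s in select_snps(rankings[::-1], ld, cfg)]
        assert a == b

    def test_quota_rounding_largest_remainder(self):
        # remainder goes to the largest fractional part; ties to the lowest
        # analysis index
        assert _quotas(10, (0.615, 0.20, 0.025, 0.025, 0.025, 0.005, 0.005, 0.10)) == [
            6, 2, 1, 0, 0, 0, 0, 1,
        ]
        assert sum(_quotas(32557, (0.615, 0.20, 0.025, 0.025, 0.025, 0.005, 0.005, 0.10))) == 32557


class TestCombineStages:
    def build_stage(self, seed, n, beta=0.2):
        cfg = cm.SimConfig(
            n_families=n, sibship_size_distribution=(1.0,), maf=(0.3,),
            true_log_hr_bc=(beta,), seed=seed, missing_rate=0.0,
            ascertainment="random",
        )
        rec, geno, _ = cm.simulate_cohort(cfg)
        return rec, geno

    def test_single_stage_is_bitwise_identical_to_plain_analysis(self, breast_curve):
        rec, geno = self.build_stage(0, 300)
        pooled = combine_stages({"icogs": (rec, geno)}, "snp1", "breast", breast_curve)
        direct = cm.RetrospectiveHazardsModel.from_cohort(rec, geno, "snp1", "breast", breast_curve)
        sp, sd = pooled.score_test(), direct.score_test()
        assert sp.U == sd.U
        assert sp.V_kin == sd.V_kin
        assert sp.p_value == sd.p_value

    def test_scores_and_information_add_across_stages(self, breast_curve):
        rec1, g1 = self.build_stage(1, 250)
        rec2raw, g2 = self.build_stage(2, 250)
        rec2 = []
        for r in rec2raw:  # disjoint ids
            r.sample_id = "T" + r.sample_id
            r.family_id = "T" + r.family_id
            rec2.append(r)
        g2 = cm.GenotypeMatrix(
            samples=["T" + s for s in g2.samples], snps=g2.snps, values=g2.values
        )
        pooled = combine_stages(
            {"s1": (rec1, g1), "s2": (rec2, g2)}, "snp1", "breast", breast_curve
        )
        st = pooled.score_test()
        st1 = cm.RetrospectiveHazardsModel.from_cohort(rec1, g1, "snp1", "breast", breast_curve).score_test()
        st2 = cm.RetrospectiveHazardsModel.from_cohort(rec2, g2, "snp1", "breast", breast_curve).score_test()
        assert st.U == pytest.approx(st1.U + st2.U, rel=1e-12)
        assert st.V_kin == pytest.approx(st1.V_kin + st2.V_kin, rel=1e-12)

    def test_overlapping_samples_rejected_with_ids(self, breast_curve):
        rec, geno = self.build_stage(3, 50)
        with pytest.raises(ValueError, match=rec[0].sample_id):
            combine_stages(
                {"s1": (rec, geno), "s2": (rec, geno)}, "snp1", "breast", breast_curve
            )

    def test_monomorphic_stage_contributes_nothing(self, breast_curve):
        rec1, g1 = self.build_stage(4, 250)
        rec2raw, g2 = self.build_stage(5, 100)
        rec2 = []
        for r in rec2raw:
            r.sample_id = "T" + r.sample_id
            r.family_id = "T" + r.family_id
            rec2.append(r)
        mono = cm.GenotypeMatrix(
            samples=["T" + s for s in g2.samples], snps=g2.snps,
            values=np.zeros_like(g2.values),
        )
        pooled = combine_stages(
            {"s1": (rec1, g1), "s2": (rec2, mono)}, "snp1", "breast", breast_curve
        )
        st1 = cm.RetrospectiveHazardsModel.from_cohort(rec1, g1, "snp1", "breast", breast_curve).score_test()
        st = pooled.score_test()
        assert st.U == pytest.approx(st1.U, rel=1e-12)
        assert st.V_kin == pytest.approx(st1.V_kin, rel=1e-12)

    def test_combined_chi2_beats_single_stages_on_average(self, breast_curve):
        chis_comb, chis_1, chis_2 = [], [], []
        for seed in range(50):
            rec1, g1 = self.build_stage(100 + seed, 300, beta=0.25)
            rec2raw, g2 = self.build_stage(200 + seed, 300, beta=0.25)
            rec2 = []
            for r in rec2raw:
                r.sample_id = "T" + r.sample_id
                r.family_id = "T" + r.family_id
                rec2.append(r)
            g2 = cm.GenotypeMatrix(
                samples=["T" + s for s in g2.samples], snps=g2.snps, values=g2.values
            )
            pooled = combine_stages(
                {"s1": (rec1, g1), "s2": (rec2, g2)}, "snp1", "breast", breast_curve
            )
            chis_comb.append(pooled.score_test().chi2)
            chis_1.append(
                cm.RetrospectiveHazardsModel.from_cohort(rec1, g1, "snp1", "breast", breast_curve).score_test().chi2
            )
            chis_2.append(
                cm.RetrospectiveHazardsModel.from_cohort(rec2, g2, "snp1", "breast", breast_curve).score_test().chi2
            )
        assert float(np.mean(chis_comb)) > float(np.mean(chis_1))
        assert float(np.mean(chis_comb)) > float(np.mean(chis_2))
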