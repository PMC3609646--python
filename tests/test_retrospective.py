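import math

import numpy as np
import pytest

import carriermod as cm
from carriermod.retrospective import MonomorphicSNPError, RetrospectiveHazardsModel


def brute_force_loglik(times, events, g, p, rates, beta, age0=18):
    """Independent plain-Python evaluation: constrained baseline by direct
    iteration, explicit survival products, genotype enumeration in the
    denominator."""
    pi = [(1 - p) ** 2, 2 * p * (1 - p), p * p]
    rr = [1.0, math.exp(beta), math.exp(2 * beta)]
    T = len(rates)
    lam0 = []
    cur = pi[:]
    for t in range(T):
        denom = sum(cur[k] * rr[k] for k in range(3))
        l0 = rates[t] / denom if denom > 0 else 0.0
        lam0.append(l0)
        new = [cur[k] * (1 - l0 * rr[k]) for k in range(3)]
        s = sum(new)
        cur = [x / s for x in new]

    def f(t_idx, ev, k):
        prod = 1.0
        upto = t_idx if ev else t_idx + 1
        for u in range(upto):
            prod *= 1 - lam0[u] * rr[k]
        if ev:
            prod *= lam0[t_idx] * rr[k]
        return prod

    total = 0.0
    for ti, ev, gi in zip(times, events, g):
        t_idx = min(int(math.floor(ti)) - age0, T - 1)
        num = f(t_idx, ev, int(gi)) * pi[int(gi)]
        den = sum(f(t_idx, ev, k) * pi[k] for k in range(3))
        total += math.log(num / den)
    return total


def build_model(times, events, g, curve, **kw):
    return RetrospectiveHazardsModel(
        times=np.array(times, float),
        events=np.array(events, bool),
        genotypes=np.array(g, float),
        incidence=curve,
        **kw,
    )


class TestLikelihood:
    def test_three_person_enumeration_oracle(self, breast_curve):
        times = [45.3, 60.0, 38.0]
        events = [True, False, True]
        g = [2, 0, 1]
        m = build_model(times, events, g, breast_curve)
        p = m._freq["ALL"]
        for beta in (-0.4, 0.0, 0.3, 0.7):
            expected = brute_force_loglik(times, events, g, p, breast_curve.rate, beta)
            assert m.loglik(beta) == pytest.approx(expected, abs=1e-10)

    def test_null_loglik_independent_of_phenotypes(self, breast_curve):
        g = [0, 1, 2, 1]
        m1 = build_model([40, 50, 60, 35], [True, False, True, False], g, breast_curve)
        m2 = build_model([70, 30, 45, 55], [False, True, False, True], g, breast_curve)
        assert m1.loglik(0.0) == pytest.approx(m2.loglik(0.0), abs=1e-12)

    def test_missing_genotype_contributes_nothing(self, breast_curve):
        m1 = build_model([45, 60, 38], [1, 0, 1], [2, 0, 1], breast_curve)
        m2 = build_model(
            [45, 60, 38, 52], [1, 0, 1, 1], [2, 0, 1, np.nan], breast_curve
        )
        assert m1.loglik(0.3) == pytest.approx(m2.loglik(0.3), abs=1e-12)


class TestScoreTest:
    def test_score_equals_likelihood_derivative(self, breast_curve):
        """The analytic score is the exact derivative of the plug-in
        retrospective log-likelihood at the null."""
        cfg = cm.SimConfig(
            n_families=70, sibship_size_distribution=(1.0,), maf=(0.3,), seed=11,
            missing_rate=0.0, ascertainment="proband_affected",
        )
        rec, geno, _ = cm.simulate_cohort(cfg)
        rec = rec[:50]
        m = RetrospectiveHazardsModel.from_cohort(
            rec, geno.subset_samples([r.sample_id for r in rec]), "snp1",
            "breast", breast_curve,
        )
        st = m.score_test()
        eps = 1e-5
        fd = (m.loglik(eps) - m.loglik(-eps)) / (2 * eps)
        assert abs(st.U - fd) / abs(fd) < 1e-6

    def test_duplication_algebra(self, breast_curve):
        """Duplicating every sample with phi = 0.5 pairs doubles the
        variance and halves the chi-square, with U unchanged."""
        rng = np.random.default_rng(3)
        n = 120
        g = rng.choice([0.0, 1.0, 2.0], p=[0.49, 0.42, 0.09], size=n)
        times = rng.uniform(25, 75, n)
        events = rng.random(n) < 0.4
        g2 = np.repeat(g, 2)
        t2 = np.repeat(times, 2)
        e2 = np.repeat(events, 2)
        ignore = build_model(t2, e2, g2, breast_curve)
        st_ignore = ignore.score_test()
        phi = np.kron(np.eye(n), np.full((2, 2), 0.5))
        adjusted = build_model(t2, e2, g2, breast_curve, kinship=phi)
        st_adj = adjusted.score_test()
        assert st_adj.U == pytest.approx(st_ignore.U, rel=1e-12)
        assert st_adj.V_kin == pytest.approx(2 * st_ignore.V_kin, rel=1e-10)
        assert st_adj.chi2 == pytest.approx(st_ignore.chi2 / 2, rel=1e-10)

    def test_kinship_variance_equals_singleton_sandwich(self, breast_curve):
        rng = np.random.default_rng(4)
        n = 80
        g = rng.choice([0.0, 1.0, 2.0], p=[0.36, 0.48, 0.16], size=n)
        m = build_model(rng.uniform(25, 75, n), rng.random(n) < 0.5, g, breast_curve)
        st = m.score_test()
        assert st.V_kin == pytest.approx(st.V_rob, abs=1e-10 * max(1, st.V_kin))

    def test_monomorphic_signalled_distinctly(self, breast_curve):
        with pytest.raises(MonomorphicSNPError):
            build_model([40, 50, 60], [1, 0, 1], [1, 1, 1], breast_curve).score_test()

    def test_dosage_column_accepted_identically(self, breast_curve):
        rng = np.random.default_rng(5)
        n = 60
        g = rng.choice([0.0, 1.0, 2.0], size=n)
        times = rng.uniform(25, 75, n)
        events = rng.random(n) < 0.4
        hard = build_model(times, events, g, breast_curve).score_test()
        soft = build_model(times, events, g + 0.0, breast_curve).score_test()
        assert hard.U == pytest.approx(soft.U)
        # genuinely fractional dosages run through the same path
        d = np.clip(g + rng.normal(0, 0.1, n), 0, 2)
        st = build_model(times, events, d, breast_curve).score_test()
        assert np.isfinite(st.chi2)


class TestEstimation:
    def test_grid_search_oracle(self, small_cohort, breast_curve):
        records, geno, _ = small_cohort
        m = RetrospectiveHazardsModel.from_cohort(
            records, geno, "snp1", "breast", breast_curve
        )
        res = m.fit()
        grid = np.arange(-0.7, 0.7001, 1e-3)
        lls = np.array([m.loglik(float(b)) for b in grid])
        best = grid[np.argmax(lls)]
        assert res.converged
        assert abs(best - res.params[0]) <= 2e-3

    def test_allele_relabelling_equivariance(self, small_cohort, breast_curve):
        """Swapping allele labels (g -> 2-g) flips the sign of the log-HR
        and leaves the score chi-square unchanged."""
        records, geno, _ = small_cohort
        m1 = RetrospectiveHazardsModel.from_cohort(
            records, geno, "snp1", "breast", breast_curve
        )
        flipped = cm.GenotypeMatrix(
            samples=geno.samples, snps=geno.snps, values=2.0 - geno.values
        )
        m2 = RetrospectiveHazardsModel.from_cohort(
            records, flipped, "snp1", "breast", breast_curve
        )
        s1, s2 = m1.score_test(), m2.score_test()
        assert s1.chi2 == pytest.approx(s2.chi2, abs=1e-8)
        assert s1.p_value == pytest.approx(s2.p_value, abs=1e-8)
        r1, r2 = m1.fit(), m2.fit()
        assert r1.params[0] == pytest.approx(-r2.params[0], abs=1e-6)

    def test_score_and_mle_sign_agree(self, breast_curve):
        for seed in range(12):
            cfg = cm.SimConfig(
                n_families=300, sibship_size_distribution=(1.0,), maf=(0.3,),
                true_log_hr_bc=(0.25,), seed=seed, missing_rate=0.0,
                ascertainment="random",
            )
            rec, geno, _ = cm.simulate_cohort(cfg)
            m = RetrospectiveHazardsModel.from_cohort(
                rec, geno, "snp1", "breast", breast_curve
            )
            res = m.fit()
            if abs(res.params[0]) > 0.01:
                assert np.sign(m.score_test().U) == np.sign(res.params[0])

    def test_null_simulations_centre_the_hr_at_one(self, breast_curve):
        hrs = []
        for seed in range(60):
            cfg = cm.SimConfig(
                n_families=400, sibship_size_distribution=(1.0,), maf=(0.3,),
                seed=seed, missing_rate=0.0, ascertainment="random",
            )
            rec, geno, _ = cm.simulate_cohort(cfg)
            m = RetrospectiveHazardsModel.from_cohort(
                rec, geno, "snp1", "breast", breast_curve
            )
            hrs.append(m.fit().hr_per_allele)
        assert 0.97 <= float(np.median(hrs)) <= 1.03

    def test_genotype_specific_model_lrt(self, small_cohort, breast_curve):
        records, geno, _ = small_cohort
        m = RetrospectiveHazardsModel.from_cohort(
            records, geno, "snp1", "breast", breast_curve
        )
        res = m.fit(model="genotype_specific")
        lr, p = res.lr_test()
        assert lr >= 0 and 0 <= p <= 1
        assert res.hr_het > 0 and res.hr_hom > 0

    def test_profile_frequency_reduces_ascertainment_bias(self, breast_curve):
        """Under all-affected ascertainment the plug-in sample frequency is
        inflated and biases the log-HR down; profiling the frequency out of
        the retrospective likelihood removes the bias."""
        plug, prof = [], []
        logb = np.log(1.3)
        for seed in range(15):
            cfg = cm.SimConfig(
                n_families=2500, sibship_size_distribution=(1.0,), maf=(0.3,),
                true_log_hr_bc=(logb,), seed=seed, missing_rate=0.0,
                ascertainment="proband_affected",
            )
            rec, geno, _ = cm.simulate_cohort(cfg)
            rec = rec[:2000]
            gm = geno.subset_samples([r.sample_id for r in rec])
            m = RetrospectiveHazardsModel.from_cohort(rec, gm, "snp1", "breast", breast_curve)
            plug.append(m.fit().params[0])
            prof.append(m.fit(profile_freq=True).params[0])
        bias_plug = abs(float(np.mean(plug)) - logb)
        bias_prof = abs(float(np.mean(prof)) - logb)
        assert bias_prof < bias_plug
        assert bias_prof < 0.04
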