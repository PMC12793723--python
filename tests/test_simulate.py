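"""Simulator mechanisms: structure, transmission, traits, linkage, oracles."""

from types import SimpleNamespace

import numpy as np
import pytest

from triotmt import simulate as sim
from triotmt import triodata as td


class TestParents:
    def test_fst_calibration(self):
        cfg = sim.SimConfig(n_trios=200, n_snps=10000, n_subpops=4, fst=0.2)
        pop = sim.simulate_parents(cfg, np.random.default_rng(1))
        assert sim.realized_fst(pop) == pytest.approx(0.2, abs=0.02)

    def test_single_subpopulation_hardy_weinberg(self):
        cfg = sim.SimConfig(n_trios=4000, n_snps=50, n_subpops=1, fst=0.0)
        rng = np.random.default_rng(2)
        pop = sim.simulate_parents(cfg, rng)
        p = pop.ancestral_freq
        freqs = np.stack([(pop.Zm == g).mean(axis=1) for g in (0, 1, 2)])
        hwe = np.stack([(1 - p) ** 2, 2 * p * (1 - p), p**2])
        np.testing.assert_allclose(freqs, hwe, atol=0.04)

    def test_one_hot_admixture_reduces_to_single_subpop(self):
        cfg = sim.SimConfig(n_trios=50, n_snps=200, n_subpops=4, fst=0.2)
        w = np.zeros((50, 4))
        w[:, 0] = 1.0
        cfg = cfg.with_(admixture_weights=w)
        pop = sim.simulate_parents(cfg, np.random.default_rng(3))
        np.testing.assert_allclose(pop.freq_m, np.repeat(pop.subpop_freq[:, :1], 50, axis=1))

    def test_k1_with_fst_is_error(self):
        with pytest.raises(ValueError):
            sim.SimConfig(n_subpops=1, fst=0.2)


class TestTransmission:
    def test_deterministic_homozygotes(self, rng):
        am, ap, g = sim.transmit(np.zeros((1, 100), dtype=int),
                                 np.full((1, 100), 2), rng)
        assert not am.any()
        assert (ap == 1).all()
        assert (g == 1).all()

    def test_heterozygote_is_fair_coin(self, rng):
        am, _, _ = sim.transmit(np.ones((1, 100000), dtype=int),
                                np.ones((1, 100000), dtype=int), rng)
        assert am.mean() == pytest.approx(0.5, abs=0.005)


class TestQuantitativeTrait:
    def test_noise_only_variance(self):
        cfg = sim.SimConfig(n_trios=4000, n_snps=5, n_causal=0, h2=0.0,
                            beta=0.0, sigma_e=1.5)
        rng = np.random.default_rng(5)
        pop = sim.simulate_parents(cfg, rng)
        _, _, g = sim.transmit(pop.Zm, pop.Zp, rng)
        y, truth = sim.simulate_quantitative(g, pop, cfg, rng)
        assert y.var() == pytest.approx(1.5**2, rel=0.1)
        assert (truth.delta_tmt == 0).all()

    def test_additive_effects_give_delta_equal_a(self):
        cfg = sim.SimConfig(n_trios=500, n_snps=30, n_causal=5, h2=0.5,
                            effect_ratio=1.0)
        rng = np.random.default_rng(6)
        pop = sim.simulate_parents(cfg, rng)
        _, _, g = sim.transmit(pop.Zm, pop.Zp, rng)
        y, truth = sim.simulate_quantitative(g, pop, cfg, rng)
        a0, a1, a2 = truth.alphas
        assert a2 - a1 == pytest.approx(a1 - a0)  # additive shape
        np.testing.assert_allclose(truth.delta_tmt[truth.causal], a1 - a0)
        assert truth.h2_realized == pytest.approx(0.5, abs=0.02)

    def test_empty_causal_with_h2_is_error(self):
        cfg = sim.SimConfig(n_trios=50, n_snps=5, n_causal=0, h2=0.4)
        rng = np.random.default_rng(7)
        pop = sim.simulate_parents(cfg, rng)
        _, _, g = sim.transmit(pop.Zm, pop.Zp, rng)
        with pytest.raises(ValueError, match="empty causal"):
            sim.simulate_quantitative(g, pop, cfg, rng)


class TestBinaryTrait:
    def test_threshold_is_prevalence_quantile(self):
        cfg = sim.SimConfig(n_trios=1000, n_snps=20, n_causal=2, h2=0.3,
                            prevalence=0.5)
        rng = np.random.default_rng(8)
        pop = sim.simulate_parents(cfg, rng)
        _, _, g = sim.transmit(pop.Zm, pop.Zp, rng)
        y, truth = sim.simulate_binary(g, pop, cfg, rng)
        assert truth.threshold == pytest.approx(np.median(truth.latent))
        assert y.mean() == pytest.approx(0.5, abs=0.01)

    def test_null_binary_has_zero_tdt_oracle(self):
        cfg = sim.SimConfig(n_trios=400, n_snps=3, n_causal=1, h2=0.0,
                            beta=0.0, prevalence=0.3)
        rng = np.random.default_rng(9)
        pop = sim.simulate_parents(cfg, rng)
        delta = sim.oracle_delta_tdt(pop, cfg, [0], (0.0, 0.0, 0.0),
                                     n_reps=300, rng=rng)
        assert delta[0] == pytest.approx(0.0, abs=0.02)


class TestConfounded:
    def test_kappa_formula(self, rng):
        cfg = sim.SimConfig(n_trios=4, lam=10.0, b=0.0, s=1.0)
        zm = np.array([1.0, 2.0, 0.0, 1.0])
        zp = np.array([1.0, 2.0, 0.0, 0.0])
        g = np.array([1.0, 2.0, 0.0, 0.0])
        _, truth = sim.simulate_confounded(zm, zp, g, cfg, rng)
        # both parents het -> 0; (2,2): 2+2-10 = -6; (0,0): -10; het anywhere -> 0
        np.testing.assert_allclose(truth["kappa"], [0.0, -6.0, -10.0, 0.0])

    def test_confounder_correlates_with_genotype_under_null(self):
        cfg = sim.SimConfig(n_trios=20000, n_snps=1, b=0.0, s=1.0)
        rng = np.random.default_rng(10)
        pop = sim.simulate_parents(cfg, rng)
        _, _, g = sim.transmit(pop.Zm, pop.Zp, rng)
        y, truth = sim.simulate_confounded(pop.Zm, pop.Zp, g, cfg, rng)
        assert truth["delta_tmt"] == 0.0
        r = np.corrcoef(g[0], truth["kappa"][0])[0, 1]
        assert abs(r) > 0.05  # a per-locus regression of Y on G is biased


class TestLinkedPair:
    @pytest.mark.parametrize("eta,theta", [(0.8, 0.1), (0.5, 0.3), (0.3, 0.5),
                                           (0.9, 0.4), (0.0, 0.0), (1.0, 0.2)])
    def test_joint_law_closed_form_matches_enumeration(self, eta, theta):
        closed = sim.joint_transmission_probs(eta, theta)
        enum = sim.enumerate_joint_transmission(eta, theta)
        for key in closed:
            assert closed[key] == pytest.approx(enum[key], abs=1e-12)
        assert sum(closed.values()) == pytest.approx(1.0)

    def test_quarter_iff_eta_or_theta_half(self):
        for eta in (0.2, 0.5, 0.8):
            for theta in (0.1, 0.5):
                probs = sim.joint_transmission_probs(eta, theta)
                flat = all(abs(v - 0.25) < 1e-12 for v in probs.values())
                assert flat == (eta == 0.5 or theta == 0.5)

    def test_marginal_is_half(self):
        for eta in (0.0, 0.25, 0.7, 1.0):
            for theta in (0.0, 0.2, 0.9):
                probs = sim.joint_transmission_probs(eta, theta)
                p_c1 = probs[(0, 1)] + probs[(1, 1)]
                assert p_c1 == pytest.approx(0.5)

    def test_worked_value(self):
        probs = sim.joint_transmission_probs(0.8, 0.1)
        assert probs[(1, 1)] == pytest.approx(0.37)

    def test_empirical_transmissions_match_law(self):
        cfg = sim.SimConfig(n_trios=60000, eta_cd=0.8, theta_cd=0.1, b=0.5)
        rng = np.random.default_rng(12)
        ts, y, truth = sim.simulate_linked_pair(cfg, rng)
        # condition on double-heterozygous mothers
        mask = (ts.Zm[0] == 1) & (ts.Zm[1] == 1)
        ac = truth["Am"][0][mask]
        ad = truth["Am"][1][mask]
        probs = sim.joint_transmission_probs(0.8, 0.1)
        for (d_, c_), expected in probs.items():
            obs = ((ad == d_) & (ac == c_)).mean()
            assert obs == pytest.approx(expected, abs=0.02)

    def test_double_het_coupling_probability(self):
        hfreq = sim._haplotype_freqs(0.8)
        coupling = hfreq[0] * hfreq[3] / (hfreq[0] * hfreq[3] + hfreq[1] * hfreq[2])
        assert coupling == pytest.approx(0.8)


class TestOracles:
    def test_flat_effects_all_zero(self):
        pop = SimpleNamespace(Zm=np.array([[1, 0]]), Zp=np.array([[1, 2]]), n_snps=1)
        assert sim.oracle_delta_tmt(pop, (2.0, 2.0, 2.0), [0])[0] == 0.0
        assert sim.oracle_ace((2.0, 2.0, 2.0), [1, 0], [1, 2]) == (0.0, 0.0)

    def test_ace_worked_value(self):
        # alphas (0,1,2), P(Ap=1)=0.3 -> ACE(Am->Y) = 0.7 + 0.3 = 1
        zp = np.array([1, 1, 1, 0, 0, 0, 0, 0, 1, 0])  # mean Zp/2 = 0.2... adjust
        zp = np.array([2, 1, 0, 0, 1, 0, 1, 0, 1, 0])  # sum=6 -> P(Ap=1)=0.3
        ace_m, _ = sim.oracle_ace((0.0, 1.0, 2.0), np.zeros(10), zp)
        assert ace_m == pytest.approx(1.0)

    def test_are_differs_from_ace_under_confounding(self):
        """A structure-confounded trait with no causal effect has zero ACE
        but nonzero regression effect."""
        rng = np.random.default_rng(13)
        cfg = sim.SimConfig(n_trios=20000, n_snps=1, n_causal=0, h2=0.0,
                            beta=3.0, admixture_concentration=0.1, env_mix=1.0)
        pop = sim.simulate_parents(cfg, rng)
        am, ap, g = sim.transmit(pop.Zm, pop.Zp, rng)
        y, truth = sim.simulate_quantitative(g, pop, cfg, rng)
        eff = sim.oracle_effects(pop, truth.alphas, 0, y=y, am=am[0], ap=ap[0])
        assert eff["ace_m"] == 0.0
        assert abs(eff["are_m"]) > 0.05

    def test_potential_outcomes_shift_by_effect(self):
        y = np.array([1.0, 2.0])
        g = np.array([1, 2])
        ap = np.array([1, 1])
        y0, y1 = sim.potential_outcomes(y, g, ap, (0.0, 1.0, 3.0))
        # gamma = y - alpha[g]; Ym(0)=a1+gamma, Ym(1)=a2+gamma when Ap=1
        np.testing.assert_allclose(y1 - y0, [2.0, 2.0])


class TestCohortIO:
    def test_vcf_fam_round_trip(self, tmp_path, small_cohort):
        ts, pheno, _ = small_cohort
        vcf = tmp_path / "c.vcf"
        fam = tmp_path / "c.fam"
        ph = tmp_path / "c.pheno.tsv"
        sim.to_vcf(ts, vcf)
        sim.to_fam(ts, fam)
        td.write_phenotypes(pheno, ts.trio_ids, ph)
        back = td.load_trios(str(vcf), str(fam))
        np.testing.assert_array_equal(back.G, ts.G)
        np.testing.assert_array_equal(back.Zm, ts.Zm)
        np.testing.assert_array_equal(back.Zp, ts.Zp)
        pv = td.load_phenotypes(ph, back.trio_ids)
        np.testing.assert_allclose(pv.values, pheno.values)
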