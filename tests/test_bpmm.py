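"""The MCMC engine: conjugacy, GLS agreement, diagnostics, heterogeneity."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from phylometa import bpmm
from phylometa.bpmm import (ChainSet, MCMCSettings, ModelSpec, fit_binomial,
                            fit_gaussian, gelman_rubin, heterogeneity,
                            higgins_sigma2_m, r2_marginal, summarize)
from phylometa.phylo import phylo_correlation, simulate_yule

from conftest import replicate_settings


def _toy(k, seed, slope=0.5, s2p=0.05, s2r=0.02):
    rng = np.random.default_rng(seed)
    cov = phylo_correlation(simulate_yule(k, seed=seed))
    x = rng.normal(0, 1, k)
    v = 1.0 / (rng.integers(10, 100, k) - 3)
    y = (1.0 + slope * x
         + rng.multivariate_normal(np.zeros(k), s2p * cov.matrix)
         + rng.normal(0, np.sqrt(s2r), k)
         + rng.normal(0, np.sqrt(v)))
    table = pd.DataFrame({"species_id": cov.taxa, "y": y, "x": x, "v": v})
    return table, cov


class TestGaussianSampler:
    def test_conjugate_shrinkage_negligible(self):
        # identical observations, variances fixed at zero: the intercept
        # posterior collapses onto the (unshrunk) observed value
        cov = phylo_correlation(simulate_yule(4, seed=0))
        table = pd.DataFrame({"species_id": cov.taxa, "y": [0.3] * 4,
                              "v": [0.04] * 4})
        st = replicate_settings(1, fix_sigma2_phylo=0.0, fix_sigma2_resid=0.0)
        cs = fit_gaussian(ModelSpec("y", mev="v"), table, cov, st)
        s = summarize(cs, "(Intercept)")
        mcse = cs.draws("(Intercept)").std() / np.sqrt(s.ess)
        assert abs(s.pm - 0.3) < 3 * mcse + 1e-10
        # with prior variance 1e10 the shrinkage factor is < 1e-10
        assert s.pm == pytest.approx(0.3, abs=0.02)

    def test_matches_gls_oracle_with_fixed_variances(self):
        table, cov = _toy(6, seed=5)
        s2p, s2r = 0.05, 0.02
        st = replicate_settings(2, fix_sigma2_phylo=s2p, fix_sigma2_resid=s2r)
        cs = fit_gaussian(ModelSpec("y", fixed_terms=["x"], mev="v"), table, cov, st)
        X = np.column_stack([np.ones(6), table["x"]])
        V = s2p * cov.matrix + s2r * np.eye(6) + np.diag(table["v"])
        Vi = np.linalg.inv(V)
        bhat = np.linalg.solve(X.T @ Vi @ X + np.eye(2) / 1e10, X.T @ Vi @ table["y"])
        for j, name in enumerate(["(Intercept)", "x"]):
            d = cs.draws(name)
            s = summarize(cs, name)
            mcse = d.std() / np.sqrt(s.ess)
            assert abs(d.mean() - bhat[j]) < 3 * mcse

    def test_seed_determinism(self):
        table, cov = _toy(8, seed=9)
        spec = ModelSpec("y", fixed_terms=["x"], mev="v")
        st = replicate_settings(4, n_chains=2)
        c1 = fit_gaussian(spec, table, cov, st)
        c2 = fit_gaussian(spec, table, cov, st)
        for a, b in zip(c1.chains, c2.chains):
            pd.testing.assert_frame_equal(a, b)

    def test_draw_count_contract(self):
        table, cov = _toy(6, seed=3)
        st = MCMCSettings(iterations=1230, burn_in=230, thin=7, n_chains=2, seed=1)
        cs = fit_gaussian(ModelSpec("y", mev="v"), table, cov, st)
        assert all(len(c) == (1230 - 230) // 7 for c in cs.chains)

    def test_variance_draws_positive(self):
        table, cov = _toy(10, seed=11)
        cs = fit_gaussian(ModelSpec("y", fixed_terms=["x"], mev="v"),
                          table, cov, replicate_settings(0))
        assert (cs.draws("sigma2_phylo") > 0).all()
        assert (cs.draws("sigma2_resid") > 0).all()

    def test_singular_design_raises(self):
        table, cov = _toy(6, seed=3)
        table["x2"] = 2 * table["x"]
        with pytest.raises(ValueError, match="collinear"):
            fit_gaussian(ModelSpec("y", fixed_terms=["x", "x2"], mev="v"),
                         table, cov, replicate_settings(0))

    def test_nonpositive_mev_raises(self):
        table, cov = _toy(6, seed=3)
        table.loc[0, "v"] = 0.0
        with pytest.raises(ValueError, match="positive"):
            fit_gaussian(ModelSpec("y", mev="v"), table, cov, replicate_settings(0))


class TestBinomialSampler:
    def test_intercept_near_zero_for_half_successes(self):
        cov = phylo_correlation(simulate_yule(4, seed=2))
        table = pd.DataFrame({"species_id": cov.taxa, "succ": [50] * 4,
                              "tr": [100] * 4})
        st = replicate_settings(3, iterations=12000, burn_in=2000, thin=10,
                                binomial_residual_fix=0.01, fix_sigma2_phylo=0.0)
        cs = fit_binomial(ModelSpec("succ", family="binomial", trials="tr"),
                          table, cov, st)
        assert abs(summarize(cs, "(Intercept)").pm) < 0.15

    def test_seed_determinism(self):
        rng = np.random.default_rng(0)
        cov = phylo_correlation(simulate_yule(10, seed=4))
        table = pd.DataFrame({"species_id": cov.taxa,
                              "succ": rng.integers(0, 20, 10), "tr": [20] * 10})
        spec = ModelSpec("succ", family="binomial", trials="tr")
        st = replicate_settings(5)
        c1 = fit_binomial(spec, table, cov, st)
        c2 = fit_binomial(spec, table, cov, st)
        pd.testing.assert_frame_equal(c1.chains[0], c2.chains[0])

    def test_successes_above_trials_raise(self):
        cov = phylo_correlation(simulate_yule(4, seed=2))
        table = pd.DataFrame({"species_id": cov.taxa, "succ": [30, 1, 1, 1],
                              "tr": [20] * 4})
        with pytest.raises(ValueError, match="trials"):
            fit_binomial(ModelSpec("succ", family="binomial", trials="tr"),
                         table, cov, replicate_settings(0))

    def test_boundary_responses_warn_of_separation(self):
        cov = phylo_correlation(simulate_yule(4, seed=2))
        table = pd.DataFrame({"species_id": cov.taxa, "succ": [0] * 4,
                              "tr": [20] * 4})
        with pytest.warns(UserWarning, match="separation"):
            fit_binomial(ModelSpec("succ", family="binomial", trials="tr"),
                         table, cov, replicate_settings(0, iterations=1100,
                                                        burn_in=100, thin=10))


class TestSummarize:
    def _chainset(self, draws):
        df = pd.DataFrame({"theta": draws})
        return ChainSet(spec=None, design=None, settings=None,
                        chains=[df], seeds=[0])

    def test_pmcmc_finite_sample_floor(self):
        cs = self._chainset(np.linspace(1.0, 2.0, 400))
        assert summarize(cs, "theta", test_value=0.0).pmcmc == pytest.approx(2 / 400)

    def test_pmcmc_symmetric_draws_near_one(self):
        rng = np.random.default_rng(0)
        cs = self._chainset(rng.normal(0, 1, 4001))
        assert summarize(cs, "theta", test_value=0.0).pmcmc > 0.9

    def test_shift_equivariance_against_test_value(self):
        rng = np.random.default_rng(1)
        d = rng.normal(1.2, 0.4, 2000)
        s1 = summarize(self._chainset(d), "theta", test_value=1.0)
        s2 = summarize(d - 1.0, test_value=0.0)
        assert s1.pmcmc == s2.pmcmc
        assert s1.pm - 1.0 == pytest.approx(s2.pm)

    def test_unknown_quantity_raises(self):
        cs = self._chainset(np.zeros(10))
        with pytest.raises(KeyError):
            summarize(cs, "nope")


class TestGelmanRubin:
    def _chains(self, means, n=1000):
        dfs = [pd.DataFrame({"b": np.random.default_rng(i).normal(m, 1, n)})
               for i, m in enumerate(means)]
        return ChainSet(spec=None, design=None, settings=None,
                        chains=dfs, seeds=list(range(len(means))))

    def test_same_distribution_converges(self):
        assert gelman_rubin(self._chains([0, 0, 0]))["b"] < 1.1

    def test_separated_chains_flagged(self):
        assert gelman_rubin(self._chains([0, 100]))["b"] > 1.5

    def test_affine_invariance(self):
        cs = self._chains([0, 0.3, -0.2])
        base = gelman_rubin(cs)["b"]
        for df in cs.chains:
            df["b"] = 5.0 * df["b"] - 7.0
        assert gelman_rubin(cs)["b"] == pytest.approx(base, rel=1e-10)

    def test_single_chain_raises(self):
        with pytest.raises(ValueError):
            gelman_rubin(self._chains([0.0]))


class TestHeterogeneity:
    def _chainset(self, s2p, s2r, mev):
        df = pd.DataFrame({"sigma2_phylo": s2p, "sigma2_resid": s2r})
        return ChainSet(spec=None, design=None, settings=None, chains=[df],
                        seeds=[0], mev=np.asarray(mev, float))

    def test_closed_form_values(self):
        # sigma_p2 = sigma_r2 = 1 and sigma_m2 = 2 -> H2 = 0.5, I2 = 0.5
        cs = self._chainset([1.0] * 10, [1.0] * 10, [2.0] * 5)
        rep = heterogeneity(cs)
        assert rep.sigma_m2 == pytest.approx(2.0)
        assert rep.h2.pm == pytest.approx(0.5)
        assert rep.i2_total.pm == pytest.approx(0.5)

    def test_no_measurement_error_gives_total_one(self):
        cs = self._chainset([0.5] * 10, [0.5] * 10, [1.0] * 5)
        rep = heterogeneity(cs, mev=np.full(5, 1e-30))
        assert rep.i2_total.pm == pytest.approx(1.0)

    def test_higgins_typical_variance_equal_weights(self):
        # with equal v_i the Higgins typical variance is v itself
        assert higgins_sigma2_m(np.full(7, 0.25)) == pytest.approx(0.25)
        assert higgins_sigma2_m(np.array([0.1, 0.4]), method="mean") == pytest.approx(0.25)

    def test_bounds_hold_in_every_draw(self):
        rng = np.random.default_rng(3)
        cs = self._chainset(rng.gamma(1, 1, 500), rng.gamma(1, 1, 500),
                            rng.uniform(0.01, 1, 20))
        rep = heterogeneity(cs)
        assert 0.0 <= rep.h2.ci_lower and rep.h2.ci_upper <= 1.0
        assert 0.0 <= rep.i2_total.ci_lower and rep.i2_total.ci_upper <= 1.0

    def test_missing_mev_raises(self):
        cs = self._chainset([1.0], [1.0], [1.0])
        cs.mev = None
        with pytest.raises(ValueError):
            heterogeneity(cs)


class TestR2Marginal:
    def test_zero_slopes_give_zero(self):
        table, cov = _toy(8, seed=13)
        cs = fit_gaussian(ModelSpec("y", fixed_terms=["x"], mev="v"),
                          table, cov, replicate_settings(0))
        for c in cs.chains:
            c["x"] = 0.0
        assert r2_marginal(cs).pm == pytest.approx(0.0, abs=1e-12)

    def test_matches_reimplementation_oracle(self):
        table, cov = _toy(8, seed=17)
        cs = fit_gaussian(ModelSpec("y", fixed_terms=["x"], mev="v"),
                          table, cov, replicate_settings(1))
        X = cs.design.matrix
        draws = cs.chains[0]
        expected = []
        for _, row in draws.iterrows():
            fitted = X @ row[["(Intercept)", "x"]].to_numpy(float)
            vf = fitted.var(ddof=1)
            expected.append(vf / (vf + row["sigma2_phylo"] + row["sigma2_resid"]))
        assert r2_marginal(cs).pm == pytest.approx(np.mean(expected), abs=1e-12)

    def test_intercept_only_returns_zero_with_note(self):
        table, cov = _toy(6, seed=19)
        cs = fit_gaussian(ModelSpec("y", mev="v"), table, cov, replicate_settings(0))
        s = r2_marginal(cs)
        assert s.pm == 0.0 and "convention" in s.note

    def test_near_one_when_noise_vanishes(self):
        cov = phylo_correlation(simulate_yule(10, seed=23))
        x = np.linspace(-1, 1, 10)
        table = pd.DataFrame({"species_id": cov.taxa, "y": 2 * x + 0.5,
                              "x": x, "v": np.full(10, 1e-6)})
        st = replicate_settings(2, fix_sigma2_phylo=1e-12, fix_sigma2_resid=1e-12)
        cs = fit_gaussian(ModelSpec("y", fixed_terms=["x"], mev="v"), table, cov, st)
        assert r2_marginal(cs).pm > 0.999
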