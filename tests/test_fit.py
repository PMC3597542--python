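"""Constraint extraction and maximum entropy inference."""

import numpy as np
import pytest
from scipy.special import expit

from sdme import fit as fitmod
from sdme import maxent, popdata
from sdme.fit import ConstraintSet, FitConfig
from sdme.maxent import FieldSpec, MaxEntModel
from sdme.popdata import SpikeRaster


def _random_t2(rng, n, T, j_scale=0.4):
    lam = rng.normal(-1.5, 0.8, (n, T))
    J = rng.normal(0, j_scale, (n, n))
    J = 0.5 * (J + J.T)
    np.fill_diagonal(J, 0)
    return MaxEntModel("T2", FieldSpec("time_indexed", lam=lam), J)


def _exact_constraints(model, model_class=None):
    """Feasible constraint set from a model's exact moments."""
    m1, m2 = maxent.moments_all(model)
    cls = model_class or model.model_class
    cs = ConstraintSet(model_class=cls, n_neurons=model.n_neurons,
                       dt=model.dt, n_samples=10 ** 9,
                       means=m1.mean(axis=1), p=m1)
    if cls in ("static2", "T2", "S2"):
        m2 = m2.copy()
        np.fill_diagonal(m2, m1.mean(axis=1))
        cs.m2 = m2
    return cs


class TestExtractConstraints:
    def test_split_halves_consistent(self, exp6):
        cs_all = fitmod.extract_constraints(exp6["raster"], model_class="T2")
        cs_tr = fitmod.extract_constraints(exp6["train"], model_class="T2")
        cs_te = fitmod.extract_constraints(exp6["test"], model_class="T2")
        pooled = 0.5 * (cs_tr.m2 + cs_te.m2)
        np.testing.assert_allclose(pooled, cs_all.m2, atol=1e-12)
        # per-bin rates of the halves agree within sampling error
        # (3 sigma per bin; allow the expected few-per-thousand exceedances)
        R = exp6["train"].n_repeats
        se = 3 * np.sqrt(np.maximum(cs_all.p * (1 - cs_all.p), 5e-3) * 2 / R)
        assert np.mean(np.abs(cs_tr.p - cs_te.p) < se) > 0.985

    def test_s1_targets_equal_ln_rates(self, exp6):
        cs = fitmod.extract_constraints(exp6["train"], exp6["ln"], "S1")
        for i, nl in enumerate(exp6["ln"].nonlinearities):
            np.testing.assert_allclose(cs.cond_means[i],
                                       nl.rates * exp6["train"].dt, atol=1e-10)

    def test_sampled_constraints_match_exact_moments(self, rng):
        model = _random_t2(rng, 5, 8)
        spikes = maxent.sample_raster(model, 4000, seed=rng)
        cs = fitmod.extract_constraints(SpikeRaster(spikes), model_class="T2")
        m1, m2 = maxent.moments_all(model)
        se1 = 3 * np.sqrt(np.maximum(m1 * (1 - m1), 1e-4) / 4000)
        assert np.all(np.abs(cs.p - m1) < se1)
        iu = np.triu_indices(5, 1)
        se2 = 3 * np.sqrt(np.maximum(m2[iu] * (1 - m2[iu]), 1e-4) / (4000 * 8))
        assert np.all(np.abs(cs.m2[iu] - m2[iu]) < se2)

    def test_infeasible_coincidences_rejected(self):
        with pytest.raises(ValueError):
            ConstraintSet(model_class="static2", n_neurons=2, dt=0.02,
                          n_samples=100, means=np.array([0.2, 0.2]),
                          m2=np.array([[0.2, 0.35], [0.35, 0.2]]))


class TestFit:
    def test_recovers_known_t2_model_from_exact_moments(self, rng):
        # convexity: unique solution, so exact targets => exact recovery
        truth = _random_t2(rng, 8, 20)
        cs = _exact_constraints(truth)
        cfg = FitConfig(rate_tol=5e-4, coinc_tol=5e-4, max_iter=3000)
        model, trace = fitmod.fit(cs, config=cfg)
        assert trace.converged
        assert np.max(np.abs(model.J - truth.J)) < 0.05
        m1_fit, _ = maxent.moments_all(model)
        m1_true, _ = maxent.moments_all(truth)
        assert np.max(np.abs(m1_fit - m1_true) / np.maximum(m1_true, 1e-3)) < 0.01

    def test_null_couplings_from_independent_truth(self, rng):
        # constraints from a conditionally independent truth, fitted pairwise
        truth = _random_t2(rng, 6, 15, j_scale=0.0)
        cs = _exact_constraints(truth, model_class="T2")
        model, trace = fitmod.fit(cs)
        assert trace.converged
        assert np.max(np.abs(model.J)) < 0.05

    def test_t1_fit_equals_closed_form(self, rng):
        p = rng.uniform(0.02, 0.6, (5, 100))
        cs = ConstraintSet(model_class="T1", n_neurons=5, dt=0.02,
                           n_samples=10 ** 9, means=p.mean(axis=1), p=p)
        model, trace = fitmod.fit(cs)
        assert trace.converged
        closed = maxent.t1_from_psth(p / 0.02, 0.02)
        np.testing.assert_allclose(model.fields.lam, closed.fields.lam,
                                   atol=1e-10)

    def test_convexity_same_solution_from_different_inits(self, rng):
        truth = _random_t2(rng, 5, 10)
        cs = _exact_constraints(truth)
        cfg = FitConfig(rate_tol=1e-4, coinc_tol=1e-4, max_iter=4000)
        m1, _ = fitmod.fit(cs, config=cfg)
        perturbed = MaxEntModel("T2", FieldSpec(
            "time_indexed", lam=rng.normal(0, 1, (5, 10))),
            np.zeros((5, 5)), dt=cs.dt)
        m2, _ = fitmod.fit(cs, config=cfg, init_model=perturbed)
        assert np.max(np.abs(m1.J - m2.J)) < 0.02
        assert np.max(np.abs(m1.fields.lam - m2.fields.lam)) < 0.05

    def test_mc_path_approximates_exact(self, rng):
        truth = _random_t2(rng, 5, 6, j_scale=0.5)
        cs = _exact_constraints(truth)
        cfg = FitConfig(rate_tol=0.02, coinc_tol=0.05, max_iter=60,
                        mc_samples=30000, mc_spacing=5, seed=0)
        model, trace = fitmod.fit(cs, config=cfg, force_mc=True)
        assert trace.rate_err[-1] < 0.1
        assert np.max(np.abs(model.J - truth.J)) < 0.5


class TestFitStatic:
    def test_independent_exact_moments_give_zero_couplings(self, rng):
        p = rng.uniform(0.1, 0.5, 4)
        m2 = np.outer(p, p)
        np.fill_diagonal(m2, p)
        cs = ConstraintSet(model_class="static2", n_neurons=4, dt=0.02,
                           n_samples=10 ** 9, means=p, m2=m2)
        model, trace = fitmod.fit(cs)
        assert trace.converged
        np.testing.assert_allclose(model.J, 0.0, atol=1e-6)

    def test_means_matched_on_sampled_raster(self, exp6):
        cfg = FitConfig(rate_tol=0.002, coinc_tol=0.01)
        model, trace = fitmod.fit_static(exp6["train"], config=cfg)
        assert trace.converged
        m1, _ = maxent.moments_exact(model)
        target = exp6["train"].pooled().mean(axis=0)
        assert np.all(np.abs(m1 - target) / target < 0.01)

    def test_perfectly_coupled_pair_degenerate(self):
        cs = ConstraintSet(model_class="static2", n_neurons=2, dt=0.02,
                           n_samples=10 ** 6, means=np.array([0.5, 0.5]),
                           m2=np.array([[0.5, 0.5], [0.5, 0.5]]))
        # exact coincidence = min(marginals): coupling diverges; with a
        # tight tolerance the fit runs into the parameter cap and flags it
        # (divergence is logarithmic, hence the generous iteration budget)
        cfg = FitConfig(max_iter=15000, rate_tol=1e-7, coinc_tol=1e-7,
                        lr_J=2.0)
        model, trace = fitmod.fit(cs, config=cfg)
        assert trace.degenerate
        assert np.abs(model.J[0, 1]) == pytest.approx(cfg.param_cap)


class TestEntropyOrdering:
    def test_s2_mean_conditional_entropy_below_s1(self, exp6_s2):
        # pairwise constraints are pooled across contexts, so the maxent
        # nesting argument bounds the context-averaged conditional entropy
        # (the noise entropy), not each context individually
        from sdme import infotheory
        T = exp6_s2["S2"].n_contexts
        s2 = np.mean([infotheory.entropy_exact(exp6_s2["S2"], t).value_bits
                      for t in range(T)])
        s1 = np.mean([infotheory.entropy_exact(exp6_s2["S1"], t).value_bits
                      for t in range(T)])
        assert s2 <= s1 + 1e-9


class TestCompareCouplings:
    def test_identity_and_scaling(self, rng):
        J = rng.normal(0, 1, (5, 5))
        J = 0.5 * (J + J.T)
        np.fill_diagonal(J, 0)
        out = fitmod.compare_couplings(J, J)
        assert out["slope"] == pytest.approx(1.0)
        assert out["pearson_r"] == pytest.approx(1.0)
        out2 = fitmod.compare_couplings(0.5 * J, J)
        assert out2["slope"] == pytest.approx(0.5)
        assert out2["pearson_r"] == pytest.approx(1.0)

    def test_s2_vs_static_on_synthetic(self, exp6, exp6_s2):
        static, _ = fitmod.fit_static(exp6["train"])
        out = fitmod.compare_couplings(exp6_s2["S2"].J, static.J)
        assert "sign_agreement" in out and 0.0 <= out["sign_agreement"] <= 1.0
        assert np.isfinite(out["pearson_r"])
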