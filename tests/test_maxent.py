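"""Model algebra: energies, partition functions, moments, samplers."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sdme import maxent
from sdme.maxent import FieldSpec, MaxEntModel


def random_model(rng, n, j_scale=0.5, model_class="static2"):
    h = rng.normal(-0.5, 1.0, n)
    J = rng.normal(0, j_scale, (n, n))
    J = 0.5 * (J + J.T)
    np.fill_diagonal(J, 0)
    return MaxEntModel(model_class, FieldSpec("static", alpha=h), J)


def brute_force_energy(h, J, sigma):
    """Term-by-term summation oracle, independent of the vectorized path."""
    e = 0.0
    n = len(sigma)
    for i in range(n):
        e -= h[i] * sigma[i]
        for j in range(i + 1, n):
            e -= J[i, j] * sigma[i] * sigma[j]
    return e


class TestEnergy:
    def test_silent_and_single_spike(self, rng):
        m = random_model(rng, 4)
        assert maxent.energy(m, np.zeros(4)) == 0.0
        sig = np.zeros(4)
        sig[2] = 1
        assert maxent.energy(m, sig) == pytest.approx(-m.fields.alpha[2])

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.integers(0, 2 ** 6 - 1), st.integers(0, 10 ** 6))
    def test_matches_brute_force(self, code, seed):
        rng = np.random.default_rng(seed)
        m = random_model(rng, 6)
        sig = maxent.decode_words(np.int64(code), 6).astype(float)
        assert maxent.energy(m, sig) == pytest.approx(
            brute_force_energy(m.fields.alpha, m.J, sig), abs=1e-10)

    def test_context_required_for_time_models(self):
        m = MaxEntModel("T1", FieldSpec("time_indexed", lam=np.zeros((2, 3))),
                        np.zeros((2, 2)))
        with pytest.raises(ValueError):
            maxent.energy(m, np.ones(2), None)


class TestLogZ:
    def test_free_model(self):
        m = MaxEntModel("static1", FieldSpec("static", alpha=np.zeros(5)),
                        np.zeros((5, 5)))
        assert maxent.logZ_exact(m) == pytest.approx(5 * np.log(2))

    def test_single_neuron(self):
        m = MaxEntModel("static1", FieldSpec("static", alpha=np.array([0.7])),
                        np.zeros((1, 1)))
        assert maxent.logZ_exact(m) == pytest.approx(np.log(1 + np.exp(0.7)))

    def test_matches_itertools_enumeration(self, rng):
        # independent oracle: explicit loop over all states
        m = random_model(rng, 5)
        z = sum(np.exp(-brute_force_energy(m.fields.alpha, m.J, np.array(s)))
                for s in itertools.product([0, 1], repeat=5))
        assert maxent.logZ_exact(m) == pytest.approx(np.log(z))

    def test_cap_enforced(self):
        n = maxent.ENUM_CAP + 1
        m = MaxEntModel("static1", FieldSpec("static", alpha=np.zeros(n)),
                        np.zeros((n, n)))
        with pytest.raises(ValueError, match="sampling"):
            maxent.logZ_exact(m)


class TestMoments:
    def test_independent_logistic(self, rng):
        h = rng.normal(0, 1, 6)
        m = MaxEntModel("static1", FieldSpec("static", alpha=h),
                        np.zeros((6, 6)))
        m1, m2 = maxent.moments_exact(m)
        np.testing.assert_allclose(m1, 1 / (1 + np.exp(-h)), atol=1e-12)
        np.testing.assert_allclose(np.diag(m2), m1, atol=1e-12)

    def test_two_neuron_hand_enumeration(self):
        # h=0, J12=ln 3: state weights 1,1,1,3 -> <s1 s2> = 3/6
        J = np.array([[0.0, np.log(3)], [np.log(3), 0.0]])
        m = MaxEntModel("static2", FieldSpec("static", alpha=np.zeros(2)), J)
        _, m2 = maxent.moments_exact(m)
        assert m2[0, 1] == pytest.approx(0.5)

    def test_normalization_every_class(self, rng, exp6_s2):
        for model in [random_model(rng, 5), exp6_s2["S1"], exp6_s2["S2"]]:
            t = None if model.fields.variant == "static" else 3
            p = np.exp(maxent.log_prob_exact(model, t))
            assert p.sum() == pytest.approx(1.0, abs=1e-10)


class TestT1ClosedForm:
    def test_half_probability_zero_field(self):
        psth = np.full((3, 4), 0.5 / 0.02)
        m = maxent.t1_from_psth(psth, 0.02)
        np.testing.assert_allclose(m.fields.lam, 0.0, atol=1e-12)

    def test_moments_reproduce_rates(self, rng):
        p = rng.uniform(0.05, 0.9, (4, 6))
        m = maxent.t1_from_psth(p / 0.02, 0.02)
        m1, _ = maxent.moments_all(m)
        np.testing.assert_allclose(m1, p, atol=1e-10)

    def test_extreme_rates_clipped(self):
        p = np.array([[0.0, 1.0]]) / 0.02 * 1.0
        m = maxent.t1_from_psth(p, 0.02, n_samples=100)
        assert m.meta["clipped_bins"] == 2
        assert np.all(np.isfinite(m.fields.lam))


class TestNesting:
    def test_s2_with_zero_couplings_equals_s1(self, exp6_s2):
        s2 = exp6_s2["S2"]
        s1_like = MaxEntModel("S1", s2.fields, np.zeros_like(s2.J), dt=s2.dt)
        for t in (0, 5, 11):
            np.testing.assert_allclose(
                maxent.log_prob_exact(s1_like, t),
                maxent.log_prob_exact(
                    MaxEntModel("S2", s2.fields, np.zeros_like(s2.J),
                                dt=s2.dt), t),
                atol=1e-12)

    def test_t2_with_zero_couplings_equals_t1(self, rng):
        lam = rng.normal(-1, 1, (4, 5))
        t1 = MaxEntModel("T1", FieldSpec("time_indexed", lam=lam),
                         np.zeros((4, 4)))
        t2 = MaxEntModel("T2", FieldSpec("time_indexed", lam=lam),
                         np.zeros((4, 4)))
        for t in range(5):
            np.testing.assert_allclose(maxent.log_prob_exact(t1, t),
                                       maxent.log_prob_exact(t2, t), atol=1e-12)


class TestSampler:
    def test_single_neuron_frequency(self):
        h = np.array([0.8])
        m = MaxEntModel("static1", FieldSpec("static", alpha=h),
                        np.zeros((1, 1)))
        s, _ = maxent.gibbs_sample(m, None, n_samples=20000, spacing=5, seed=0)
        p = 1 / (1 + np.exp(-0.8))
        se = np.sqrt(p * (1 - p) / 20000)
        assert abs(s.mean() - p) < 3 * se

    def test_free_model_uncorrelated(self):
        m = MaxEntModel("static2", FieldSpec("static", alpha=np.zeros(4)),
                        np.zeros((4, 4)))
        s, _ = maxent.gibbs_sample(m, None, n_samples=20000, spacing=5, seed=1)
        c = np.corrcoef(s.T)
        iu = np.triu_indices(4, 1)
        assert np.all(np.abs(c[iu]) < 3 / np.sqrt(20000))

    def test_tv_distance_to_enumeration(self, rng):
        m = random_model(rng, 5)
        s, _ = maxent.gibbs_sample(m, None, n_samples=30000, spacing=20, seed=2)
        codes = maxent.encode_words(s)
        hist = np.bincount(codes, minlength=32) / len(codes)
        p = np.exp(maxent.log_prob_exact(m))
        assert 0.5 * np.abs(hist - p).sum() < 0.02

    def test_recorded_energies_consistent(self, rng):
        m = random_model(rng, 4)
        s, e = maxent.gibbs_sample(m, None, n_samples=500, spacing=3, seed=3)
        recomputed = np.array([maxent.energy(m, x) for x in s.astype(float)])
        np.testing.assert_allclose(e, recomputed, atol=1e-9)


class TestEncodingAndIO:
    @settings(deadline=None, max_examples=20, derandomize=True)
    @given(st.integers(0, 2 ** 10 - 1))
    def test_encode_decode_roundtrip(self, code):
        w = maxent.decode_words(np.int64(code), 10)
        assert int(maxent.encode_words(w)) == code

    def test_lsb_convention(self):
        w = np.zeros(5, dtype=np.uint8)
        w[0] = 1
        assert int(maxent.encode_words(w)) == 1

    def test_json_roundtrip(self, tmp_path, rng, exp6_s2):
        for model in [random_model(rng, 4), exp6_s2["S2"]]:
            path = tmp_path / "m.json"
            maxent.save_model(model, path)
            back = maxent.load_model(path)
            assert back.model_class == model.model_class
            np.testing.assert_allclose(back.J, model.J)
            if model.fields.variant == "generator_binned":
                for a, b in zip(back.fields.h, model.fields.h):
                    np.testing.assert_allclose(a, b)

    def test_asymmetric_couplings_rejected(self):
        J = np.array([[0.0, 1.0], [0.5, 0.0]])
        with pytest.raises(ValueError):
            MaxEntModel("static2", FieldSpec("static", alpha=np.zeros(2)), J)
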