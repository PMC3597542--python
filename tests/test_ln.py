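"""Linear-nonlinear front end: STA, generator signals, binning, Bayes f."""

import numpy as np
import pytest
from scipy.special import expit

from sdme import ln, popdata, synthdata
from sdme.popdata import SpikeRaster, StimulusTrace


def _white_stim(rng, n, dt=0.02):
    """White Gaussian stimulus already on the bin grid (update rate 1/dt)."""
    return StimulusTrace(rng.normal(0, 1, n), update_rate=1 / dt, D=40)


def _ln_neuron_raster(rng, stim, taps, gain, offset, n_bins, dt=0.02):
    f = ln.LinearFilter(taps)
    x, _ = ln.generator_signal(f, stim, dt, n_bins)
    p = expit(offset + gain * x)
    spikes = (rng.random((1, n_bins, 1)) < p[None, :, None]).astype(np.uint8)
    return SpikeRaster(spikes, dt=dt), x, p


class TestSTA:
    def test_recovers_known_filter_on_white_noise(self, rng):
        n_bins = 100_000
        stim = _white_stim(rng, n_bins)
        true_k = synthdata._biphasic_kernel(40, peak=5.0, trough=18.0, rng=rng)
        raster, _, _ = _ln_neuron_raster(rng, stim, true_k, gain=1.5,
                                         offset=-2.5, n_bins=n_bins)
        sta = ln.spike_triggered_average(raster, stim, D=40)[0]
        r = np.corrcoef(sta.taps, true_k)[0, 1]
        assert r > 0.95

    def test_stimulus_independent_spiking_gives_null_sta(self, rng):
        n_bins = 20_000
        stim = _white_stim(rng, n_bins)
        spikes = (rng.random((1, n_bins, 1)) < 0.2).astype(np.uint8)
        sta = ln.spike_triggered_average(SpikeRaster(spikes), stim, D=40,
                                         normalize=False)[0]
        n_spk = spikes.sum()
        # each tap is a mean of ~n_spk unit-variance draws
        assert np.linalg.norm(sta.taps) ** 2 < 3 * 40 / n_spk

    def test_zero_spike_neuron_named_in_error(self, rng):
        spikes = np.zeros((1, 100, 2), dtype=np.uint8)
        spikes[0, ::7, 0] = 1
        with pytest.raises(ValueError, match="neuron 1"):
            ln.spike_triggered_average(SpikeRaster(spikes),
                                       _white_stim(rng, 100), D=10)

    def test_d1_is_mean_luminance_at_spikes(self, rng):
        n_bins = 5000
        stim = _white_stim(rng, n_bins)
        s = stim.resample(0.02, n_bins)
        spikes = (rng.random((1, n_bins, 1)) < expit(s - 1)).astype(np.uint8)
        sta = ln.spike_triggered_average(SpikeRaster(spikes), stim, D=1,
                                         normalize=False)[0]
        mask = spikes[0, :, 0] > 0
        assert sta.taps[0] == pytest.approx(s[mask].mean() - s.mean(), abs=1e-9)


class TestGeneratorSignal:
    def test_delta_filter_returns_stimulus(self, rng):
        stim = _white_stim(rng, 200)
        k = np.zeros(5)
        k[0] = 1.0  # lag-0 delta
        x, burn = ln.generator_signal(ln.LinearFilter(k), stim, 0.02, 200)
        s = stim.resample(0.02, 200)
        np.testing.assert_allclose(x, s, atol=1e-12)
        assert burn[:4].all() and not burn[4:].any()

    def test_linearity_and_zero_filter(self, rng):
        stim = _white_stim(rng, 300)
        k1, k2 = rng.normal(0, 1, (2, 12))
        x1, _ = ln.generator_signal(ln.LinearFilter(k1), stim, 0.02, 300)
        x2, _ = ln.generator_signal(ln.LinearFilter(k2), stim, 0.02, 300)
        x12, _ = ln.generator_signal(ln.LinearFilter(k1 + k2), stim, 0.02, 300)
        np.testing.assert_allclose(x12, x1 + x2, atol=1e-10)
        x0, _ = ln.generator_signal(ln.LinearFilter(np.zeros(12)), stim, 0.02, 300)
        np.testing.assert_allclose(x0, 0.0, atol=1e-15)


class TestAdaptiveBins:
    def test_stage1_equal_occupancy(self, rng):
        x = rng.normal(0, 1, 1003)
        edges = ln.adaptive_bin_edges(x, None, K=10, refine=False)
        occ = np.histogram(x, bins=edges)[0]
        assert occ.sum() == 1003
        assert occ.max() - occ.min() <= 2  # within +-1 of 1003/10

    def test_rank_invariance_under_monotone_transform(self, rng):
        x = rng.normal(0, 1, 500)
        e1 = ln.adaptive_bin_edges(x, None, K=8, refine=False)
        e2 = ln.adaptive_bin_edges(np.exp(x), None, K=8, refine=False)
        i1 = np.clip(np.digitize(x, e1[1:-1]), 0, 7)
        i2 = np.clip(np.digitize(np.exp(x), e2[1:-1]), 0, 7)
        np.testing.assert_array_equal(i1, i2)

    def test_k1_spans_range(self, rng):
        x = rng.normal(0, 2, 100)
        edges = ln.adaptive_bin_edges(x, None, K=1)
        assert edges[0] <= x.min() and edges[-1] >= x.max()

    def test_k_reduced_on_few_distinct_values(self):
        x = np.array([0.0, 0.0, 1.0, 1.0, 2.0])
        edges = ln.adaptive_bin_edges(x, None, K=10, refine=False)
        assert len(edges) - 1 <= 3

    def test_refinement_keeps_k_and_covers(self, rng):
        x = rng.normal(0, 1, 4000)
        spk = (rng.random(4000) < expit(2 * x - 1)).astype(float)
        edges = ln.adaptive_bin_edges(x, spk, K=10, refine=True)
        assert len(edges) == 11
        assert edges[0] <= x.min() and edges[-1] >= x.max()
        assert np.all(np.diff(edges) > 0)


class TestNonlinearity:
    def test_law_of_total_expectation(self, rng):
        x = rng.normal(0, 1, 3000)
        sp = (rng.random(3000) < expit(x)).astype(float)
        edges = ln.adaptive_bin_edges(x, sp, K=8, refine=False)
        nl = ln.fit_nonlinearity(x, sp, edges, dt=0.02)
        # sum_bins f(bin) P(bin) equals the overall mean rate exactly
        p_bin = nl.counts / nl.counts.sum()
        assert float(nl.rates @ p_bin) == pytest.approx(sp.mean() / 0.02,
                                                        abs=1e-9)

    def test_independent_spiking_flat(self, rng):
        x = rng.normal(0, 1, 20000)
        sp = (rng.random(20000) < 0.3).astype(float)
        edges = ln.adaptive_bin_edges(x, sp, K=5, refine=False)
        nl = ln.fit_nonlinearity(x, sp, edges, dt=0.02)
        # 3.5 sigma per-bin bound (5 simultaneous comparisons)
        se = 3.5 * np.sqrt(0.3 * 0.7 / 4000) / 0.02
        assert np.all(np.abs(nl.rates - 0.3 / 0.02) < se)

    def test_hard_threshold_neuron_step(self, rng):
        x = rng.normal(0, 1, 30000)
        p_above = 0.6
        sp = ((x > 0.5) & (rng.random(30000) < p_above)).astype(float)
        edges = np.array([-5, -1, 0.0, 0.5, 1.0, 5.0])
        nl = ln.fit_nonlinearity(x, sp, edges, dt=0.02)
        np.testing.assert_allclose(nl.rates[:3], 0.0, atol=1e-12)
        se = 3 * np.sqrt(p_above * 0.4 / 3000) / 0.02
        assert abs(nl.rates[3] - p_above / 0.02) < se
        assert abs(nl.rates[4] - p_above / 0.02) < se

    def test_empty_bin_pseudocount_flagged(self, rng):
        x = rng.normal(0, 1, 100)
        edges = np.array([-10.0, -8.0, 0.0, 10.0])  # first bin empty
        nl = ln.fit_nonlinearity(x, np.zeros(100), edges, dt=0.02)
        assert nl.filled[0] and not nl.filled[2]
        assert nl.rates[0] > 0


class TestPredict:
    def test_training_bin_means_reproduced(self, exp6):
        lnm = exp6["ln"]
        train = exp6["train"]
        p_t = train.spikes.mean(axis=0).T
        for i in range(lnm.n_neurons):
            nl = lnm.nonlinearities[i]
            idx = nl.bin_of(lnm.x[i])
            for k in range(nl.K):
                if np.any(idx == k):
                    assert p_t[i][idx == k].mean() / train.dt == pytest.approx(
                        nl.rates[k], rel=1e-9)

    def test_conservation_of_mean_rate(self, exp6):
        lnm = exp6["ln"]
        train = exp6["train"]
        pred = ln.predict_rate(lnm, exp6["stim"], train.n_bins)
        np.testing.assert_allclose(
            pred.rates.mean(axis=1),
            train.spikes.mean(axis=(0, 1)) / train.dt, rtol=1e-9)

    def test_constant_stimulus_constant_rate(self, rng, exp6):
        stim = StimulusTrace(np.full(300, 147.0), 30.0, D=40)
        pred = ln.predict_rate(exp6["ln"], stim, 200)
        assert np.all(pred.rates == pred.rates[:, :1])

    def test_ground_truth_psth_recovery(self, rng):
        # uncoupled ground truth: LN fit recovers the true rates
        truth, stim, raster = synthdata.synth_experiment(
            N=4, n_repeats=300, duration_s=8.0, seed=11, coupling_scale=0.0)
        lnm = ln.fit_ln(raster, stim, D=40, K=10)
        pred = ln.predict_rate(lnm, stim, raster.n_bins)
        x = synthdata.generator_signals(truth, stim, raster.dt, raster.n_bins)
        true_rates = expit(truth.fields_from_x(x)) / raster.dt
        for i in range(4):
            r = np.corrcoef(pred.rates[i], true_rates[i])[0, 1]
            assert r > 0.9
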