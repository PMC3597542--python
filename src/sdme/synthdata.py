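"""Ground-truth synthetic population emulating a retinal FFF experiment.

The stimulus is spatially uniform Gaussian flicker: 8-bit quantized
luminance draws (mean 147, std 33 in luminance units) updated at 30 Hz.
The population is a set of coupled linear-nonlinear neurons: biphasic
OFF-type temporal filters (D = 40 taps, unit norm), a logistic
nonlinearity on the generator signal x_i(t) = k_i . s_t, and symmetric
positive-mean couplings decaying with distance on a square grid.  Fields
linear in x keep the ground truth exactly inside the coupled
stimulus-dependent model class, so parameter recovery is well-posed.

Per (time bin, repeat) one codeword is drawn independently from
P(sigma | t) of the ground-truth model — exactly by enumeration for
N <= 20, by Metropolis sampling above.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import maxent
from .maxent import FieldSpec, MaxEntModel
from .popdata import SpikeRaster, StimulusTrace

STIM_MEAN = 147.0      # luminance units
STIM_STD = 33.0
STIM_LEVELS = 256      # 8-bit quantization
STIM_RATE_HZ = 30.0    # effective update rate (60 Hz frames shown twice)
DEFAULT_TAPS = 40
GRID_PITCH_UM = 100.0


@dataclass
class GroundTruth:
    """A reproducible coupled-LN population."""

    filters: np.ndarray        # (N, D), unit norm, most-recent-first
    gain: np.ndarray           # logistic gain per neuron (on x)
    offset: np.ndarray         # logistic offset per neuron
    J: np.ndarray              # (N, N) couplings
    positions: np.ndarray      # (N, 2) micrometres
    seed: int

    @property
    def n_neurons(self) -> int:
        return self.filters.shape[0]

    def fields_from_x(self, x: np.ndarray) -> np.ndarray:
        """Ground-truth fields h_i(t) = offset_i + gain_i * x_i(t)."""
        return self.offset[:, None] + self.gain[:, None] * x

    def model(self, x: np.ndarray) -> MaxEntModel:
        """The exact generating model attached to generator signals x (N, T),
        expressed with time-indexed fields."""
        return MaxEntModel("T2", FieldSpec("time_indexed",
                                           lam=self.fields_from_x(x)), self.J)


def gaussian_fff(duration_s: float, update_rate_hz: float = STIM_RATE_HZ,
                 mean: float = STIM_MEAN, std: float = STIM_STD,
                 levels: int = STIM_LEVELS, seed: int = 0) -> StimulusTrace:
    """I.i.d. Gaussian luminance quantized to ``levels`` gray values.

    Draws are rounded to the integer grid 0..levels-1 and clipped at the
    ends, emulating an 8-bit display.
    """
    if levels < 2:
        raise ValueError("levels must be >= 2")
    rng = np.random.default_rng(seed)
    n = int(np.round(duration_s * update_rate_hz))
    raw = rng.normal(mean, std, size=n)
    lum = np.clip(np.round(raw), 0, levels - 1)
    return StimulusTrace(lum, update_rate_hz, D=DEFAULT_TAPS)


def _biphasic_kernel(D: int, peak: float, trough: float, rng) -> np.ndarray:
    """OFF-type biphasic temporal kernel, most-recent-first, unit norm."""
    lags = np.arange(D, dtype=float)
    k = -np.exp(-0.5 * ((lags - peak) / (0.18 * D)) ** 2) \
        + 0.6 * np.exp(-0.5 * ((lags - trough) / (0.25 * D)) ** 2)
    k += 0.02 * rng.standard_normal(D)
    return k / np.linalg.norm(k)


def make_population(N: int, D: int = DEFAULT_TAPS, coupling_scale: float = 0.5,
                    decay_length_um: float = 150.0, seed: int = 0,
                    mean_rate_hz: float = 3.0, dt: float = 0.02,
                    gain_z: float = 1.5, coupling_jitter: float = 0.5,
                    x_std: float = STIM_STD) -> GroundTruth:
    """Reproducible ground truth with distance-decaying positive couplings.

    Neurons sit on a sqrt(N) x sqrt(N) grid at 100 um pitch; the mean
    coupling at distance d is ``coupling_scale * exp(-d / decay_length_um)``
    with Gaussian jitter of std ``coupling_jitter * coupling_scale`` (so a
    zero coupling scale yields exactly J = 0).  Logistic offsets are
    set so the uncoupled baseline spike probability per bin matches
    ``mean_rate_hz * dt``; gains are scaled so one generator-signal
    standard deviation (``x_std``, the stimulus std for unit-norm filters
    on white stimuli) moves the field by about ``gain_z``.
    """
    if N < 1:
        raise ValueError("N must be >= 1")
    rng = np.random.default_rng(seed)
    side = int(np.ceil(np.sqrt(N)))
    grid = np.array([(i % side, i // side) for i in range(N)], dtype=float)
    positions = grid * GRID_PITCH_UM
    filters = np.array([
        _biphasic_kernel(D, peak=0.12 * D + rng.uniform(-2, 2),
                         trough=0.45 * D + rng.uniform(-3, 3), rng=rng)
        for _ in range(N)])
    p0 = mean_rate_hz * dt
    offset = np.log(p0 / (1 - p0)) + 0.2 * rng.standard_normal(N)
    gain = (gain_z / x_std) * (1.0 + 0.2 * rng.standard_normal(N))
    d = np.linalg.norm(positions[:, None, :] - positions[None, :, :], axis=-1)
    J = coupling_scale * np.exp(-d / decay_length_um)
    J += coupling_scale * coupling_jitter * rng.standard_normal((N, N))
    J = 0.5 * (J + J.T)
    np.fill_diagonal(J, 0.0)
    return GroundTruth(filters=filters, gain=gain, offset=offset, J=J,
                       positions=positions, seed=seed)


def generator_signals(truth: GroundTruth, stimulus: StimulusTrace,
                      dt: float, n_bins: int) -> np.ndarray:
    """Centered generator signals x_i(t) = k_i . (s_t - mean s) on the dt
    grid, shape (N, T)."""
    D = truth.filters.shape[1]
    stim = StimulusTrace(stimulus.luminance, stimulus.update_rate, D=D)
    W = stim.windows(dt, n_bins)
    W = W - W.mean(axis=0, keepdims=True)
    return truth.filters @ W.T


def simulate(truth: GroundTruth, stimulus: StimulusTrace, n_repeats: int,
             dt: float = 0.02, seed: int = 0,
             duration_s: float | None = None) -> SpikeRaster:
    """Repeat-structured raster: an independent codeword per (t, repeat)
    drawn from the ground-truth conditional distribution."""
    if duration_s is None:
        duration_s = len(stimulus.luminance) / stimulus.update_rate
    n_bins = int(np.round(duration_s / dt))
    x = generator_signals(truth, stimulus, dt, n_bins)
    model = truth.model(x)
    spikes = maxent.sample_raster(model, n_repeats, seed=seed)
    return SpikeRaster(spikes, dt=dt, positions=truth.positions)


def synth_experiment(N: int = 10, n_repeats: int = 600, duration_s: float = 10.0,
                     dt: float = 0.02, seed: int = 7, **pop_kwargs):
    """One-call fixture: (truth, stimulus, raster) with derived sub-seeds."""
    stim = gaussian_fff(duration_s, seed=seed % (2 ** 31 - 3) + 1)
    truth = make_population(N, dt=dt, seed=(seed * 7 + 1) % (2 ** 31 - 1),
                            **pop_kwargs)
    raster = simulate(truth, stim, n_repeats, dt=dt,
                      seed=(seed * 13 + 2) % (2 ** 31 - 1),
                      duration_s=duration_s)
    return truth, stim, raster
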