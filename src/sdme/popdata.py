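"""Spike rasters, stimuli, and the empirical statistics that the models
constrain or are evaluated against.

A raster is a binary tensor over (repeat, time bin, neuron); the bin width
``dt`` (default 20 ms) defines the codeword timescale.  Pooled moments,
the trial-shuffle significance null, the signal/noise correlation
decomposition, per-neuron drift and the odd/even train/test split all
live here.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

DEFAULT_DT = 0.02  # s


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class SpikeRaster:
    """Binary population activity over (repeat, time bin, neuron)."""

    spikes: np.ndarray  # uint8 (R, T, N) in {0, 1}
    dt: float = DEFAULT_DT
    positions: np.ndarray | None = None  # (N, 2) in micrometres
    drop_initial_repeats: int = 0

    def __post_init__(self):
        self.spikes = np.asarray(self.spikes)
        if self.spikes.ndim != 3:
            raise ValueError("spikes must be (repeat, time, neuron)")
        vals = np.unique(self.spikes)
        if not np.all(np.isin(vals, [0, 1])):
            raise ValueError("raster entries must be binary")
        self.spikes = self.spikes.astype(np.uint8)
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.drop_initial_repeats:
            self.spikes = self.spikes[self.drop_initial_repeats:]
            self.drop_initial_repeats = 0
        if self.positions is not None:
            self.positions = np.asarray(self.positions, dtype=float)
            if self.positions.shape[0] != self.spikes.shape[2]:
                raise ValueError("positions must have one row per neuron")

    @property
    def n_repeats(self) -> int:
        return self.spikes.shape[0]

    @property
    def n_bins(self) -> int:
        return self.spikes.shape[1]

    @property
    def n_neurons(self) -> int:
        return self.spikes.shape[2]

    def pooled(self) -> np.ndarray:
        """All codeword samples, shape (R*T, N)."""
        return self.spikes.reshape(-1, self.n_neurons)


@dataclass
class StimulusTrace:
    """Full-field luminance sequence with its update rate and window size D."""

    luminance: np.ndarray
    update_rate: float  # Hz
    D: int = 40

    def __post_init__(self):
        self.luminance = np.asarray(self.luminance, dtype=float).ravel()
        if self.update_rate <= 0:
            raise ValueError("update_rate must be positive")
        if self.D < 1:
            raise ValueError("D must be >= 1")

    def resample(self, dt: float, n_bins: int) -> np.ndarray:
        """Zero-order-hold resampling of the luminance onto the dt bin grid.

        Bin b takes the luminance value in force at time (b + 0.5) * dt.
        """
        t_mid = (np.arange(n_bins) + 0.5) * dt
        idx = np.minimum((t_mid * self.update_rate).astype(int),
                         len(self.luminance) - 1)
        return self.luminance[idx]

    def windows(self, dt: float, n_bins: int) -> np.ndarray:
        """(n_bins, D) matrix of the D most recent held-luminance values
        ending at each bin (most-recent-first); leading bins are padded by
        edge replication and flagged as burn-in by callers."""
        s = self.resample(dt, n_bins)
        pad = np.concatenate([np.full(self.D - 1, s[0]), s])
        idx = np.arange(n_bins)[:, None] + (self.D - 1) - np.arange(self.D)[None, :]
        return pad[idx]


@dataclass
class PSTH:
    """Trial-averaged firing rates r_i(t) in spikes/s, shape (N, T)."""

    rates: np.ndarray
    dt: float

    def __post_init__(self):
        self.rates = np.asarray(self.rates, dtype=float)
        if np.any(self.rates < -1e-12) or np.any(self.rates > 1.0 / self.dt + 1e-9):
            raise ValueError("rates must lie in [0, 1/dt]")


@dataclass
class CorrelationSet:
    """Total/signal/noise second-order structure of a raster.

    ``corr_*`` are Pearson correlation coefficients, ``cov_*`` covariances;
    noise = total - signal elementwise by construction.
    """

    cov_total: np.ndarray
    corr_total: np.ndarray
    corr_signal: np.ndarray | None = None
    corr_noise: np.ndarray | None = None
    cov_signal: np.ndarray | None = None
    cov_noise: np.ndarray | None = None
    cutoff: float | None = None
    significant: np.ndarray | None = None
    constant_neurons: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=int))


# ---------------------------------------------------------------------------
# construction
# ---------------------------------------------------------------------------

def binarize(spike_counts_or_times, dt: float, *, duration: float | None = None,
             positions=None) -> SpikeRaster:
    """Build a binary raster from spike counts or spike-time lists.

    Accepts either an integer count tensor (repeat, time, neuron) — any bin
    with one *or more* spikes maps to 1 — or a nested list
    ``times[repeat][neuron] -> array of spike times in seconds`` together
    with ``duration``.  Bins are half-open ``[b*dt, (b+1)*dt)``, so a spike
    exactly on a boundary belongs to the later bin.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if isinstance(spike_counts_or_times, np.ndarray) or (
            np.ndim(spike_counts_or_times) == 3
            and not isinstance(spike_counts_or_times[0][0], (list, np.ndarray))):
        counts = np.asarray(spike_counts_or_times)
        if np.any(counts < 0):
            raise ValueError("spike counts must be non-negative")
        return SpikeRaster((counts >= 1).astype(np.uint8), dt=dt, positions=positions)
    trains = spike_counts_or_times
    if duration is None:
        raise ValueError("duration required for spike-time input")
    n_bins = int(np.ceil(duration / dt))
    n_rep = len(trains)
    n_neu = len(trains[0])
    spikes = np.zeros((n_rep, n_bins, n_neu), dtype=np.uint8)
    for r in range(n_rep):
        for i in range(n_neu):
            tt = np.asarray(trains[r][i], dtype=float)
            if tt.size == 0:
                continue
            if np.any(tt < 0) or np.any(tt > duration):
                raise ValueError("spike times outside raster duration")
            b = np.floor(tt / dt).astype(int)
            b = b[b < n_bins]
            spikes[r, b, i] = 1
    return SpikeRaster(spikes, dt=dt, positions=positions)


def estimate_psth(raster: SpikeRaster) -> PSTH:
    """PSTH r_i(t): mean over repeats of sigma_i(t, r), divided by dt."""
    rates = raster.spikes.mean(axis=0).T / raster.dt  # (N, T)
    return PSTH(rates, raster.dt)


# ---------------------------------------------------------------------------
# moments and correlations
# ---------------------------------------------------------------------------

def _corr_from_pooled(x: np.ndarray):
    """Covariance and correlation over pooled samples (M, N); constant
    columns get NaN correlations and are reported."""
    m = x.mean(axis=0)
    cov = (x.T @ x) / x.shape[0] - np.outer(m, m)
    sd = np.sqrt(np.clip(np.diag(cov), 0, None))
    const = np.where(sd < 1e-12)[0]
    with np.errstate(divide="ignore", invalid="ignore"):
        corr = cov / np.outer(sd, sd)
    corr[const, :] = np.nan
    corr[:, const] = np.nan
    return cov, corr, const


def total_moments(raster: SpikeRaster):
    """Pooled means and total covariance/correlation over all (t, repeat).

    Returns ``(means, CorrelationSet)``.  Constant (all-0 or all-1) neurons
    have undefined correlations: flagged in ``constant_neurons``, covariance
    still returned.
    """
    x = raster.pooled().astype(np.float64)
    if x.shape[0] < 2:
        raise ValueError("need at least 2 samples")
    means = x.mean(axis=0)
    cov, corr, const = _corr_from_pooled(x)
    if const.size:
        logger.warning("constant neurons (correlation undefined): %s", const.tolist())
    return means, CorrelationSet(cov_total=cov, corr_total=corr,
                                 constant_neurons=const)


def significance_cutoff(raster: SpikeRaster, n_shuffles: int = 20,
                        seed: int = 0, rule: str = "mean2std"):
    """Correlation significance threshold from a time-shuffle null.

    Each neuron's spike train is independently permuted in time (within
    each repeat), destroying all pairwise locking; the null distribution of
    correlation coefficients over pairs and shuffles defines the cutoff:
    ``mean2std`` (default) uses null mean + 2 * null std, ``p95`` the 95th
    percentile.  Returns ``(cutoff, null_mean, null_std, significant)``
    where ``significant`` flags pairs whose measured coefficient exceeds
    the cutoff.
    """
    if n_shuffles < 1:
        raise ValueError("n_shuffles must be >= 1")
    rng = np.random.default_rng(seed)
    R, T, N = raster.spikes.shape
    iu = np.triu_indices(N, k=1)
    null_vals = []
    for _ in range(n_shuffles):
        shuf = np.empty_like(raster.spikes)
        for i in range(N):
            for r in range(R):
                shuf[r, :, i] = raster.spikes[r, rng.permutation(T), i]
        _, corr, _ = _corr_from_pooled(shuf.reshape(-1, N).astype(np.float64))
        null_vals.append(corr[iu])
    null = np.concatenate(null_vals)
    null = null[np.isfinite(null)]
    null_mean, null_std = float(null.mean()), float(null.std())
    if rule == "mean2std":
        cutoff = null_mean + 2.0 * null_std
    elif rule == "p95":
        cutoff = float(np.percentile(null, 95))
    else:
        raise ValueError(f"unknown rule {rule!r}")
    _, corr, _ = _corr_from_pooled(raster.pooled().astype(np.float64))
    significant = corr > cutoff
    np.fill_diagonal(significant, False)
    return cutoff, null_mean, null_std, significant


def signal_noise_split(raster: SpikeRaster, n_perms: int = 20,
                       seed: int = 0) -> CorrelationSet:
    """Decompose total correlation into signal and noise parts.

    The signal component is the total correlation of a surrogate raster in
    which repeat indices are randomly and independently permuted for each
    neuron and time bin (averaged over ``n_perms`` permutations) — this
    keeps stimulus locking but destroys within-trial covariation.  Noise is
    the elementwise difference total - signal.
    """
    if raster.n_repeats < 2:
        raise ValueError("signal/noise decomposition requires >= 2 repeats")
    rng = np.random.default_rng(seed)
    R, T, N = raster.spikes.shape
    _, cs = total_moments(raster)
    corr_sig = np.zeros((N, N))
    cov_sig = np.zeros((N, N))
    for _ in range(n_perms):
        shuf = np.empty_like(raster.spikes)
        for i in range(N):
            perms = np.argsort(rng.random((T, R)), axis=1)  # (T, R)
            shuf[:, :, i] = raster.spikes[perms.T, np.arange(T)[None, :], i]
        cov, corr, _ = _corr_from_pooled(shuf.reshape(-1, N).astype(np.float64))
        corr_sig += corr
        cov_sig += cov
    corr_sig /= n_perms
    cov_sig /= n_perms
    cs.corr_signal = corr_sig
    cs.cov_signal = cov_sig
    cs.corr_noise = cs.corr_total - corr_sig
    cs.cov_noise = cs.cov_total - cov_sig
    return cs


def drift_check(raster: SpikeRaster):
    """Per-neuron relative rate drift across repeats.

    The mean rate in each repeat is regressed against the repeat index;
    relative change = fitted slope * n_repeats / mean rate.  Silent neurons
    get NaN and are flagged.  Returns ``(relative_change, silent_mask)``.
    """
    if raster.n_repeats < 3:
        raise ValueError("drift check requires >= 3 repeats")
    per_rep = raster.spikes.mean(axis=1).astype(np.float64)  # (R, N)
    x = np.arange(raster.n_repeats, dtype=float)
    xc = x - x.mean()
    slopes = (xc @ (per_rep - per_rep.mean(axis=0))) / (xc @ xc)
    mean_rate = per_rep.mean(axis=0)
    silent = mean_rate <= 0
    with np.errstate(divide="ignore", invalid="ignore"):
        rel = slopes * raster.n_repeats / mean_rate
    rel[silent] = np.nan
    if silent.any():
        logger.warning("silent neurons, drift undefined: %s",
                       np.where(silent)[0].tolist())
    return rel, silent


def split_odd_even(raster: SpikeRaster):
    """Odd-numbered repeats (1-based: 1st, 3rd, ...) -> train, even -> test."""
    if raster.n_repeats < 2:
        raise ValueError("need >= 2 repeats to split")
    train = SpikeRaster(raster.spikes[0::2], dt=raster.dt, positions=raster.positions)
    test = SpikeRaster(raster.spikes[1::2], dt=raster.dt, positions=raster.positions)
    return train, test
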