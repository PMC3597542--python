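"""Linear-nonlinear single-cell front end.

Each neuron is summarized by a temporal linear filter k (estimated by
reverse correlation / spike-triggered averaging), the generator signal
x(t) = k . s_t obtained by filtering the stimulus, and a pointwise
nonlinearity f defined on adaptively sized bins of x and recovered by
Bayes inversion.  These are the building blocks of the conditionally
independent stimulus-dependent model (S1) and supply the generator-signal
binning reused by the coupled model (S2).

Conventions: filters are unit-norm with the overall scale absorbed into
f (LN models are invariant to this rescaling); the filter window covers
the spike bin itself plus D-1 bins into the past, most-recent-first.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np

from .popdata import PSTH, SpikeRaster, StimulusTrace

logger = logging.getLogger(__name__)

DEFAULT_K_BINS = 10


@dataclass
class LinearFilter:
    """Temporal filter taps, most-recent-first (lag 0 .. D-1)."""

    taps: np.ndarray
    normalized: bool = True

    def __post_init__(self):
        self.taps = np.asarray(self.taps, dtype=float).ravel()


@dataclass
class BinnedNonlinearity:
    """Pointwise rate function f on K bins of the generator signal.

    ``rates`` are in spikes/s; ``counts`` is the training occupancy per
    bin; ``filled`` flags bins whose rate came from the empty-bin
    pseudocount rule rather than data.
    """

    edges: np.ndarray  # (K+1,)
    rates: np.ndarray  # (K,)
    counts: np.ndarray  # (K,)
    filled: np.ndarray = None

    def __post_init__(self):
        self.edges = np.asarray(self.edges, dtype=float)
        self.rates = np.asarray(self.rates, dtype=float)
        self.counts = np.asarray(self.counts)
        if np.any(np.diff(self.edges) <= 0):
            raise ValueError("bin edges must be strictly increasing")
        if np.any(self.rates < 0):
            raise ValueError("rates must be non-negative")
        if self.filled is None:
            self.filled = np.zeros(len(self.rates), dtype=bool)

    @property
    def K(self) -> int:
        return len(self.rates)

    def bin_of(self, x: np.ndarray) -> np.ndarray:
        """Bin index of each x, clamping out-of-range values to end bins."""
        return np.clip(np.digitize(x, self.edges[1:-1]), 0, self.K - 1)


@dataclass
class LNModel:
    """Per-population LN front end: one filter + nonlinearity per neuron,
    with the generator signals cached on the fitting stimulus grid."""

    filters: list  # of LinearFilter
    nonlinearities: list  # of BinnedNonlinearity
    dt: float
    x: np.ndarray = None  # (N, T) generator-signal cache

    @property
    def n_neurons(self) -> int:
        return len(self.filters)

    @property
    def bin_edges(self) -> list:
        return [nl.edges for nl in self.nonlinearities]


# ---------------------------------------------------------------------------
# reverse correlation
# ---------------------------------------------------------------------------

def spike_triggered_average(raster: SpikeRaster, stimulus: StimulusTrace,
                            D: int | None = None, normalize: bool = True):
    """Per-neuron spike-triggered averages.

    The STA is the mean of the D-tap stimulus windows ending at each spike
    bin (pooled over repeats), minus the mean window; unit-norm by default.
    A neuron with zero spikes raises an error naming it.
    """
    D = D or stimulus.D
    stim = StimulusTrace(stimulus.luminance, stimulus.update_rate, D=D)
    W = stim.windows(raster.dt, raster.n_bins)  # (T, D)
    mean_w = W.mean(axis=0)
    counts = raster.spikes.sum(axis=(0, 1))  # per neuron
    filters = []
    for i in range(raster.n_neurons):
        if counts[i] == 0:
            raise ValueError(f"neuron {i} has zero spikes; STA undefined")
        w = raster.spikes[:, :, i].sum(axis=0).astype(float)  # spikes per bin
        sta = (w @ W) / counts[i] - mean_w
        if normalize:
            nrm = np.linalg.norm(sta)
            if nrm > 0:
                sta = sta / nrm
        filters.append(LinearFilter(sta, normalized=normalize))
    return filters


def generator_signal(filt: LinearFilter, stimulus: StimulusTrace,
                     dt: float, n_bins: int):
    """x(t) = k . s_t on the dt grid; returns (x, burnin_mask) where the
    first D-1 bins (incomplete windows) are flagged as burn-in."""
    D = len(filt.taps)
    if len(stimulus.luminance) < D:
        raise ValueError("stimulus shorter than filter window")
    stim = StimulusTrace(stimulus.luminance, stimulus.update_rate, D=D)
    W = stim.windows(dt, n_bins)
    x = W @ filt.taps
    burnin = np.zeros(n_bins, dtype=bool)
    burnin[: D - 1] = True
    return x, burnin


# ---------------------------------------------------------------------------
# adaptive binning
# ---------------------------------------------------------------------------

def adaptive_bin_edges(x_values: np.ndarray, spike_indicator: np.ndarray | None,
                       K: int = DEFAULT_K_BINS, refine: bool = True) -> np.ndarray:
    """Bin edges over generator-signal values.

    Stage 1 places equal-occupancy (quantile) edges.  Stage 2 — where the
    firing rates are high, i.e. above the spike-weighted median of x —
    bins are refined to be denser: any high-x bin holding more than twice
    the stage-1 average spike count is split at its internal median, and K
    is kept constant by merging the pair of adjacent low-x bins with the
    smallest combined spike count.
    """
    x = np.asarray(x_values, dtype=float).ravel()
    if K < 1:
        raise ValueError("K must be >= 1")
    n_distinct = len(np.unique(x))
    if n_distinct < K:
        logger.warning("only %d distinct values; reducing K from %d", n_distinct, K)
        K = max(1, n_distinct)
    qs = np.linspace(0, 1, K + 1)
    edges = np.quantile(x, qs)
    # guard against duplicate quantiles on tied data
    for j in range(1, K + 1):
        if edges[j] <= edges[j - 1]:
            edges[j] = np.nextafter(edges[j - 1], np.inf)
    span = edges[-1] - edges[0]
    edges[0] -= 1e-9 * max(span, 1.0)
    edges[-1] += 1e-9 * max(span, 1.0)
    if not refine or spike_indicator is None or K < 3:
        return edges
    y = np.asarray(spike_indicator, dtype=float).ravel()
    if y.sum() <= 0:
        return edges
    x_med = _weighted_median(x, y)
    target = y.sum() / K
    for _ in range(K):  # bounded number of refinements
        counts = np.histogram(x, bins=edges, weights=y)[0]
        high = np.where(edges[:-1] >= x_med)[0]
        low = np.where(edges[1:] <= x_med)[0]
        cand = [b for b in high if counts[b] > 2 * target]
        if not cand or len(low) < 2:
            break
        b = cand[int(np.argmax(counts[cand]))]
        inside = x[(x >= edges[b]) & (x < edges[b + 1])]
        if inside.size < 2:
            break
        split = np.median(inside)
        if split <= edges[b] or split >= edges[b + 1]:
            break
        # merge the adjacent low-x pair with the least spikes
        pair_counts = counts[low[:-1]] + counts[low[1:]]
        m = low[int(np.argmin(pair_counts))]
        edges = np.delete(edges, m + 1)
        b_new = b if b < m + 1 else b - 1
        edges = np.insert(edges, b_new + 1, split)
    return edges


def _weighted_median(x, w):
    order = np.argsort(x)
    cw = np.cumsum(w[order])
    return x[order][np.searchsorted(cw, 0.5 * cw[-1])]


# ---------------------------------------------------------------------------
# nonlinearity by Bayes inversion
# ---------------------------------------------------------------------------

def fit_nonlinearity(x: np.ndarray, spikes_i: np.ndarray, edges: np.ndarray,
                     dt: float) -> BinnedNonlinearity:
    """Recover f on the given bins: f(bin) = rbar * P(bin|spike) / P(bin),
    identically the mean spike rate among samples falling in the bin.

    ``x`` is (T,) and ``spikes_i`` either (T,) spike probabilities averaged
    over repeats or an (R, T) binary slab.  Empty bins receive a Laplace
    pseudocount of 0.5 spikes over the average bin occupancy and are
    flagged.
    """
    x = np.asarray(x, dtype=float).ravel()
    sp = np.asarray(spikes_i, dtype=float)
    if sp.ndim == 2:
        sp = sp.mean(axis=0)
    K = len(edges) - 1
    idx = np.clip(np.digitize(x, edges[1:-1]), 0, K - 1)
    counts = np.bincount(idx, minlength=K)
    spike_mass = np.bincount(idx, weights=sp, minlength=K)
    rates = np.zeros(K)
    filled = counts == 0
    occ = counts[counts > 0]
    avg_occ = occ.mean() if occ.size else 1.0
    with np.errstate(invalid="ignore"):
        rates[~filled] = spike_mass[~filled] / counts[~filled] / dt
    rates[filled] = 0.5 / avg_occ / dt
    if filled.any():
        logger.warning("empty generator bins filled by pseudocount: %s",
                       np.where(filled)[0].tolist())
    return BinnedNonlinearity(edges=edges, rates=rates, counts=counts, filled=filled)


def fit_ln(raster: SpikeRaster, stimulus: StimulusTrace, D: int | None = None,
           K: int = DEFAULT_K_BINS, refine: bool = True) -> LNModel:
    """Full LN fit: STA -> generator signal -> adaptive bins -> Bayes f."""
    filters = spike_triggered_average(raster, stimulus, D)
    p_t = raster.spikes.mean(axis=0).T  # (N, T) spike prob per bin
    xs, nls = [], []
    for i, f in enumerate(filters):
        x, _ = generator_signal(f, stimulus, raster.dt, raster.n_bins)
        edges = adaptive_bin_edges(x, p_t[i], K, refine=refine)
        nls.append(fit_nonlinearity(x, p_t[i], edges, raster.dt))
        xs.append(x)
    return LNModel(filters=filters, nonlinearities=nls, dt=raster.dt,
                   x=np.asarray(xs))


def predict_rate(model: LNModel, stimulus: StimulusTrace, n_bins: int) -> PSTH:
    """Predicted PSTH by bin lookup of x(t) for each neuron; out-of-range
    generator values clamp to the end bins (counted and logged)."""
    rates = np.empty((model.n_neurons, n_bins))
    n_clamped = 0
    for i in range(model.n_neurons):
        x, _ = generator_signal(model.filters[i], stimulus, model.dt, n_bins)
        nl = model.nonlinearities[i]
        n_clamped += int(np.sum((x < nl.edges[0]) | (x > nl.edges[-1])))
        rates[i] = nl.rates[nl.bin_of(x)]
    if n_clamped:
        logger.info("clamped %d out-of-range generator values", n_clamped)
    return PSTH(np.clip(rates, 0, 1.0 / model.dt), model.dt)


# ---------------------------------------------------------------------------
# JSON I/O
# ---------------------------------------------------------------------------

def save_ln(model: LNModel, path) -> None:
    d = {"dt": model.dt, "neurons": [
        {"filter": model.filters[i].taps.tolist(),
         "bin_edges": model.nonlinearities[i].edges.tolist(),
         "bin_rates_hz": model.nonlinearities[i].rates.tolist(),
         "bin_counts": model.nonlinearities[i].counts.tolist()}
        for i in range(model.n_neurons)]}
    with open(path, "w") as fh:
        json.dump(d, fh)


def load_ln(path) -> LNModel:
    with open(path) as fh:
        d = json.load(fh)
    filters, nls = [], []
    for nd in d["neurons"]:
        filters.append(LinearFilter(np.asarray(nd["filter"])))
        nls.append(BinnedNonlinearity(
            edges=np.asarray(nd["bin_edges"]),
            rates=np.asarray(nd["bin_rates_hz"]),
            counts=np.asarray(nd.get("bin_counts", np.zeros(len(nd["bin_rates_hz"]))))))
    return LNModel(filters=filters, nonlinearities=nls, dt=d["dt"])
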