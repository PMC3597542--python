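"""Model-quality metrics: PSTH correlation, likelihood ratios,
per-codeword likelihoods with regularized empirical baselines, vocabulary
scatter / goodness of fit, top-K pattern overlap, and noise-correlation
prediction.

Log-likelihoods are reported as NEGATIVE log2 likelihood per codeword
(bits/codeword, lower = better); the plug-in entropy of the test
codeword distribution is the unbeatable lower bound.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.special import expit, logit

from . import maxent, popdata
from .maxent import ENUM_CAP, MaxEntModel
from .popdata import PSTH, SpikeRaster

logger = logging.getLogger(__name__)

_LN2 = np.log(2.0)
REG_GRID = np.geomspace(1e-4, 1e-1, 10)  # per-bin probability scale


# ---------------------------------------------------------------------------
# rate-level metrics
# ---------------------------------------------------------------------------

def model_psth(model: MaxEntModel) -> PSTH:
    """Predicted PSTH of a stimulus- or time-dependent model: the exact
    per-context means divided by dt."""
    m1, _ = maxent.moments_all(model)
    return PSTH(m1 / model.dt, model.dt)


def psth_correlation(psth_true: PSTH, psth_pred: PSTH) -> np.ndarray:
    """Per-neuron Pearson r between measured and predicted PSTH over time
    bins; constant traces yield NaN (flagged in the log)."""
    a = np.asarray(psth_true.rates, dtype=float)
    b = np.asarray(psth_pred.rates, dtype=float)
    if a.shape != b.shape:
        raise ValueError("PSTH shapes differ")
    out = np.empty(a.shape[0])
    for i in range(a.shape[0]):
        sa, sb = a[i].std(), b[i].std()
        if sa == 0 or sb == 0:
            out[i] = np.nan
            logger.warning("neuron %d: constant PSTH, correlation undefined", i)
        else:
            out[i] = float(np.corrcoef(a[i], b[i])[0, 1])
    return out


# ---------------------------------------------------------------------------
# likelihoods
# ---------------------------------------------------------------------------

def _log2_prob_raster(model: MaxEntModel, raster: SpikeRaster) -> np.ndarray:
    """(R, T) matrix of log2 P(sigma_{r,t} | t) under the model."""
    X = raster.spikes.astype(np.float64)
    H = model.field_matrix()
    if H.shape[1] == 1:
        H = np.broadcast_to(H, (H.shape[0], raster.n_bins))
    neg_e = np.einsum("rtn,nt->rt", X, H) + \
        0.5 * np.einsum("rtn,nm,rtm->rt", X, model.J, X, optimize=True)
    if model.n_neurons <= ENUM_CAP:
        if model.fields.variant == "static":
            lz = np.full(raster.n_bins, maxent.logZ_exact(model, None))
        else:
            lz = maxent.logZ_all(model)
    else:  # pragma: no cover - large-N path
        from .infotheory import logZ_thermo
        if model.fields.variant == "static":
            lz = np.full(raster.n_bins, logZ_thermo(model, None))
        else:
            lz = np.array([logZ_thermo(model, t) for t in range(raster.n_bins)])
    return (neg_e - lz[None, :]) / _LN2


def loglik_ratio_trace(model_a: MaxEntModel, model_b: MaxEntModel,
                       raster_test: SpikeRaster) -> np.ndarray:
    """L(t): mean over test repeats of log2 P_A(sigma|t) - log2 P_B(sigma|t)."""
    la = _log2_prob_raster(model_a, raster_test)
    lb = _log2_prob_raster(model_b, raster_test)
    return (la - lb).mean(axis=0)


@dataclass
class NLLReport:
    """Per-codeword negative log2 likelihoods (bits/codeword)."""

    model_bits: float
    empirical_train_bits: float
    empirical_test_bits: float
    epsilon: float | None = None      # T1 rate regularizer actually used
    pseudocount_scale: float = None   # mixture weight of the train baseline


def _t1_regularized_nll(model, raster_test, eps_grid=REG_GRID):
    """T1 NLL with the rate regularizer chosen to favor the model most:
    p -> (p + eps) / (1 + 2 eps), eps maximizing test likelihood."""
    p = expit(model.fields.lam)
    best = (np.inf, None)
    for eps in eps_grid:
        p_eps = (p + eps) / (1.0 + 2.0 * eps)
        reg = maxent.MaxEntModel(
            "T1", maxent.FieldSpec("time_indexed", lam=logit(p_eps)),
            np.zeros_like(model.J), dt=model.dt)
        nll = -float(_log2_prob_raster(reg, raster_test).mean())
        if nll < best[0]:
            best = (nll, eps)
    return best


def _empirical_train_nll(raster_train, raster_test, grid=REG_GRID):
    """Pooled empirical-train vocabulary, mixture-regularized with the
    uniform distribution, mixture weight chosen to maximize test
    likelihood (maximally favoring the baseline)."""
    n = raster_train.n_neurons
    codes_tr = maxent.encode_words(raster_train.pooled())
    codes_te = maxent.encode_words(raster_test.pooled())
    m_tr = codes_tr.size
    uniq, cnt = np.unique(codes_tr, return_counts=True)
    freq = dict(zip(uniq.tolist(), (cnt / m_tr).tolist()))
    p_emp = np.array([freq.get(int(c), 0.0) for c in codes_te])
    u = 2.0 ** (-n)
    best = (np.inf, None)
    for v in grid:
        nll = -float(np.mean(np.log2((1 - v) * p_emp + v * u)))
        if nll < best[0]:
            best = (nll, v)
    return best


def empirical_test_nll(raster_test: SpikeRaster) -> float:
    """Plug-in entropy of the pooled test codeword distribution — the
    lower bound for any pooled (vocabulary) model's per-codeword NLL.
    Stimulus-conditional models are instead bounded by
    :func:`empirical_conditional_nll`, which is never larger."""
    codes = maxent.encode_words(raster_test.pooled())
    _, cnt = np.unique(codes, return_counts=True)
    p = cnt / cnt.sum()
    return -float(np.sum(p * np.log2(p)))


def empirical_conditional_nll(raster_test: SpikeRaster) -> float:
    """Mean over time bins of the per-context plug-in codeword entropy —
    the exact lower bound for conditional models' per-codeword NLL."""
    codes = maxent.encode_words(raster_test.spikes)  # (R, T)
    out = 0.0
    for t in range(raster_test.n_bins):
        _, cnt = np.unique(codes[:, t], return_counts=True)
        p = cnt / cnt.sum()
        out -= float(np.sum(p * np.log2(p)))
    return out / raster_test.n_bins


def per_codeword_nll(model: MaxEntModel, raster_test: SpikeRaster,
                     raster_train: SpikeRaster | None = None) -> NLLReport:
    """Mean -log2 P(sigma|t) over all (test repeat, time bin) samples,
    with the paper-style regularized empirical baselines."""
    eps = None
    if model.model_class == "T1":
        nll, eps = _t1_regularized_nll(model, raster_test)
    else:
        ll = _log2_prob_raster(model, raster_test)
        if not np.all(np.isfinite(ll)):
            raise ValueError("zero-probability codeword under the model; "
                             "a regularized variant is required")
        nll = -float(ll.mean())
    tr_nll, pc = (np.nan, None)
    if raster_train is not None:
        tr_nll, pc = _empirical_train_nll(raster_train, raster_test)
    return NLLReport(model_bits=nll, empirical_train_bits=tr_nll,
                     empirical_test_bits=empirical_test_nll(raster_test),
                     epsilon=eps, pseudocount_scale=pc)


# ---------------------------------------------------------------------------
# vocabulary-level metrics
# ---------------------------------------------------------------------------

def _model_sample_codes(model: MaxEntModel, mc_samples: int, seed):
    """Pooled integer codewords from ``mc_samples`` draws per context."""
    samp = maxent.sample_raster(model, n_repeats=mc_samples, seed=seed)
    return maxent.encode_words(samp).ravel()


def vocabulary_scatter_gof(model: MaxEntModel, raster_test: SpikeRaster,
                           mc_samples: int = 5000, seed: int = 0):
    """Scatter of model vs empirical codeword probabilities, and GoF.

    Model probabilities q_w come from Monte Carlo draws pooled over all
    contexts; the scatter keeps codewords present in both the MC run and
    the test data.  The all-silent codeword is reported separately.  GoF
    is the standard deviation over plotted non-silent codewords of
    z_w = (log2 p_hat_w - log2 q_w) / delta_w with delta_w the
    delta-method multinomial std of log2 p_hat_w at M test samples.
    """
    codes_data = maxent.encode_words(raster_test.pooled())
    M = codes_data.size
    uniq_d, cnt_d = np.unique(codes_data, return_counts=True)
    p_hat = cnt_d / M
    codes_mc = _model_sample_codes(model, mc_samples, seed)
    uniq_m, cnt_m = np.unique(codes_mc, return_counts=True)
    q = dict(zip(uniq_m.tolist(), (cnt_m / codes_mc.size).tolist()))
    rows = []
    silent = None
    for w, p_w in zip(uniq_d.tolist(), p_hat):
        if w not in q:
            continue
        delta = np.sqrt((1.0 - p_w) / (M * p_w)) / _LN2
        z = (np.log2(p_w) - np.log2(q[w])) / delta if delta > 0 else np.nan
        rec = (w, p_w, q[w], z)
        if w == 0:
            silent = rec
        else:
            rows.append(rec)
    z_vals = np.array([r[3] for r in rows if np.isfinite(r[3])])
    gof = float(z_vals.std()) if z_vals.size else np.nan
    return {"pairs": rows, "silent": silent, "gof": gof,
            "n_plotted": len(rows), "mc_total": int(codes_mc.size),
            "test_samples": int(M)}


def _topk(codes: np.ndarray, K: int):
    uniq, cnt = np.unique(codes, return_counts=True)
    order = np.lexsort((uniq, -cnt))  # frequency desc, integer code asc
    return uniq[order[:K]]


def topk_overlap(model: MaxEntModel, raster_test: SpikeRaster, K: int = 500,
                 mc_samples: int = 5000, seed: int = 0) -> int:
    """Size of the intersection between the K most frequent test codewords
    and the K most frequent model-sampled codewords."""
    if K < 1:
        raise ValueError("K must be >= 1")
    codes_data = maxent.encode_words(raster_test.pooled())
    codes_mc = _model_sample_codes(model, mc_samples, seed)
    k_eff = min(K, np.unique(codes_data).size, np.unique(codes_mc).size)
    if k_eff < K:
        logger.info("top-K reduced from %d to %d (distinct patterns)", K, k_eff)
    top_d = set(_topk(codes_data, k_eff).tolist())
    top_m = set(_topk(codes_mc, k_eff).tolist())
    return len(top_d & top_m)


# ---------------------------------------------------------------------------
# noise correlations
# ---------------------------------------------------------------------------

def noise_corr_prediction(model: MaxEntModel, raster_test: SpikeRaster,
                          repeats_sim: int | None = None, seed: int = 0,
                          n_perms: int = 10, restrict_significant: bool = True):
    """Measured vs model-predicted noise correlations.

    A raster with the test repeat/time structure is simulated from the
    model; noise correlations on both sides come from the trial-shuffle
    signal/noise decomposition.  The regression (least-squares slope,
    Pearson r) is reported over significantly correlated pairs when
    enough exist.
    """
    repeats_sim = repeats_sim or raster_test.n_repeats
    sim = SpikeRaster(maxent.sample_raster(model, repeats_sim, seed=seed),
                      dt=raster_test.dt)
    cs_data = popdata.signal_noise_split(raster_test, n_perms=n_perms,
                                         seed=seed + 1)
    cs_sim = popdata.signal_noise_split(sim, n_perms=n_perms, seed=seed + 2)
    iu = np.triu_indices(raster_test.n_neurons, 1)
    x = cs_data.corr_noise[iu]
    y = cs_sim.corr_noise[iu]
    mask = np.isfinite(x) & np.isfinite(y)
    if restrict_significant:
        _, _, _, sig = popdata.significance_cutoff(raster_test, n_shuffles=5,
                                                   seed=seed + 3)
        sig_mask = mask & sig[iu]
        if sig_mask.sum() >= 3:
            mask = sig_mask
    x, y = x[mask], y[mask]
    if x.size > 1 and x.std() > 0:
        xc = x - x.mean()
        slope = float((xc @ (y - y.mean())) / (xc @ xc))
        r = float(np.corrcoef(x, y)[0, 1])
    else:
        slope, r = np.nan, np.nan
    return {"measured": x, "predicted": y, "slope": slope, "pearson_r": r,
            "n_pairs": int(x.size)}
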