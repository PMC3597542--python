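"""Entropies, mutual information, surprise, and the stimulus source rate.

Entropy of a model distribution is computed exactly by enumeration for
N <= 20 neurons, or by thermodynamic (heat-capacity) integration for
larger populations: the energy is rescaled by a temperature T,
P_T proportional to exp(-E/T); the heat capacity C(T) = Var_T[E] / T^2 is
estimated by Monte Carlo on a log-spaced temperature grid, and

    S(T=1) = N ln 2 - integral_1^Tmax C(T)/T dT - Var_inf[E] / (2 Tmax^2)

in nats (the tail term is the leading high-temperature expansion, with
Var_inf the energy variance under the uniform distribution).  Integration
runs from the hot side, where S(inf) = N ln 2 is known exactly, avoiding
ground-state degeneracy issues.

The mutual information between stimulus and codewords is the difference
between the vocabulary entropy and the mean conditional (noise) entropy;
the surprise trace and instantaneous information resolve this in time.
All entropies are reported in bits, rates in bits/s (divided by dt).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import norm

from . import maxent
from .maxent import ENUM_CAP, MaxEntModel

logger = logging.getLogger(__name__)

_LN2 = np.log(2.0)


@dataclass
class ThermoScan:
    """Heat-capacity scan over the temperature grid."""

    T: np.ndarray
    C: np.ndarray            # heat capacity Var_T[E]/T^2 per grid point
    C_err: np.ndarray        # MC standard error per grid point
    tail: float              # analytic tail correction (nats)

    def __post_init__(self):
        if np.any(np.diff(self.T) <= 0) or self.T[0] != 1.0:
            raise ValueError("temperature grid must increase from T=1")


@dataclass
class EntropyEstimate:
    value_bits: float
    method: str              # "exact" | "thermo"
    mc_error_bits: float = 0.0

    def __post_init__(self):
        if self.value_bits < -1e-9:
            raise ValueError("entropy cannot be negative")


@dataclass
class InfoReport:
    """Information accounting of a vocabulary/codebook model pair."""

    vocab_entropy_bits: float
    noise_entropy_bits: float          # mean over contexts of S[P(sigma|t)]
    mutual_information_bits: float     # per codeword
    dt: float
    surprise_rate: np.ndarray = None   # bits/s per context
    instantaneous_info_rate: np.ndarray = None  # bits/s per context
    cond_entropy_bits: np.ndarray = None

    @property
    def vocab_entropy_rate(self):
        return self.vocab_entropy_bits / self.dt

    @property
    def noise_entropy_rate(self):
        return self.noise_entropy_bits / self.dt

    @property
    def info_rate(self):
        return self.mutual_information_bits / self.dt


# ---------------------------------------------------------------------------
# entropies
# ---------------------------------------------------------------------------

def entropy_exact(model: MaxEntModel, t: int | None = None) -> EntropyEstimate:
    """Exact -sum P log2 P by enumeration (N <= 20)."""
    if model.n_neurons > ENUM_CAP:
        raise ValueError("population too large for enumeration; "
                         "use entropy_thermo")
    lp = maxent.log_prob_exact(model, t)
    s = -float(np.sum(np.exp(lp) * lp)) / _LN2
    return EntropyEstimate(max(s, 0.0), "exact")


def _uniform_energy_variance(model: MaxEntModel, t, rng, n=20000) -> float:
    """Var[E] under the uniform (infinite-temperature) distribution,
    estimated from i.i.d. fair-coin codewords."""
    sig = rng.integers(0, 2, size=(n, model.n_neurons)).astype(np.float64)
    h = model.fields_at(t)
    e = -(sig @ h) - 0.5 * np.einsum("si,ij,sj->s", sig, model.J, sig)
    return float(e.var())


def entropy_thermo(model: MaxEntModel, t: int | None = None,
                   Tmax: float = 100.0, grid: int = 60,
                   samples: int = 5000, seed: int = 0,
                   spacing: int | None = None):
    """Entropy by Monte-Carlo heat-capacity integration.

    Chains anneal from the hot end of a log-spaced grid (each temperature
    reuses the previous chain's final state); C(T)/T is integrated by the
    trapezoidal rule and converted to bits.  Returns
    ``(EntropyEstimate, ThermoScan)``.
    """
    rng = np.random.default_rng(seed)
    n = model.n_neurons
    if spacing is None:
        spacing = max(2 * n, 20)
    temps = np.geomspace(1.0, Tmax, grid)
    C = np.empty(grid)
    C_err = np.empty(grid)
    state = rng.integers(0, 2, size=n).astype(np.uint8)
    for k in range(grid - 1, -1, -1):  # hot -> cold annealing
        T = temps[k]
        samp, energies = maxent.gibbs_sample(
            model, t, n_samples=samples, spacing=spacing, seed=rng,
            temp=T, burnin=20 * spacing, init_state=state)
        state = samp[-1]
        var_e = energies.var()
        C[k] = var_e / T ** 2
        # crude autocorrelation-blind standard error of a variance
        m4 = np.mean((energies - energies.mean()) ** 4)
        C_err[k] = np.sqrt(max(m4 - var_e ** 2, 0.0) / samples) / T ** 2
    var_inf = _uniform_energy_variance(model, t, rng)
    tail = var_inf / (2.0 * Tmax ** 2)
    integral = np.trapezoid(C / temps, temps)
    s_nats = n * _LN2 - integral - tail
    # propagate per-point MC errors through the trapezoid weights
    w = np.gradient(temps)
    mc_err = float(np.sqrt(np.sum((w * C_err / temps) ** 2)))
    est = EntropyEstimate(max(s_nats, 0.0) / _LN2, "thermo",
                          mc_error_bits=mc_err / _LN2)
    noisy = np.sum(np.diff(C) > 3 * (C_err[1:] + C_err[:-1]))
    if noisy > grid // 4:
        logger.warning("heat capacity non-monotone beyond MC error at %d "
                       "grid points", int(noisy))
    return est, ThermoScan(temps, C, C_err, tail)


def entropy(model: MaxEntModel, t: int | None = None, **thermo_kw):
    """Exact entropy when enumerable, thermodynamic estimate otherwise."""
    if model.n_neurons <= ENUM_CAP:
        return entropy_exact(model, t)
    est, _ = entropy_thermo(model, t, **thermo_kw)
    return est


# ---------------------------------------------------------------------------
# information quantities
# ---------------------------------------------------------------------------

def _check_same_n(a, b: MaxEntModel):
    if isinstance(a, MaxEntModel) and a.n_neurons != b.n_neurons:
        raise ValueError("vocabulary and codebook models differ in size")


def _vocab_log2_probs(vocab, n: int) -> np.ndarray:
    """log2 P_vocab over all 2^N codewords.

    ``vocab`` is either a model or an explicit probability vector (e.g. an
    empirical vocabulary); empirical zeros yield -inf — infinite surprise
    for codewords the vocabulary never saw — and are flagged.
    """
    if isinstance(vocab, MaxEntModel):
        return maxent.log_prob_exact(vocab, None) / _LN2
    p = np.asarray(vocab, dtype=float)
    if p.size != 2 ** n or abs(p.sum() - 1.0) > 1e-8:
        raise ValueError("explicit vocabulary must be a normalized "
                         "probability vector over all 2^N codewords")
    with np.errstate(divide="ignore"):
        lp = np.log2(p)
    if np.any(np.isneginf(lp)):
        logger.warning("empirical vocabulary assigns zero probability to "
                       "%d codewords: surprise may be infinite",
                       int(np.sum(np.isneginf(lp))))
    return lp


def _vocab_entropy_bits(vocab, n: int) -> float:
    if isinstance(vocab, MaxEntModel):
        return entropy(vocab, None).value_bits
    p = np.asarray(vocab, dtype=float)
    p = p[p > 0]
    return -float(np.sum(p * np.log2(p)))


def surprise_trace(vocab_model, codebook_model: MaxEntModel,
                   contexts=None) -> np.ndarray:
    """Average surprise rate per context (bits/s).

    S_hat_x(t) = -< log2 P_vocab(sigma) >_{P(sigma|t)} / dt, with the
    expectation exact by enumeration (sampling fallback above the cap).
    ``vocab_model`` may also be an explicit probability vector over all
    2^N codewords (an empirical vocabulary).
    """
    _check_same_n(vocab_model, codebook_model)
    n = codebook_model.n_neurons
    dt = codebook_model.dt
    T = codebook_model.n_contexts
    contexts = list(range(T)) if contexts is None else list(contexts)
    if n <= ENUM_CAP:
        lp_vocab = _vocab_log2_probs(vocab_model, n)
        out = np.empty(len(contexts))
        for j, t in enumerate(contexts):
            p = np.exp(maxent.log_prob_exact(codebook_model, t))
            mass = p > 0
            with np.errstate(invalid="ignore"):
                out[j] = -(p[mass] @ lp_vocab[mass]) / dt
        return out
    out = np.empty(len(contexts))
    rng = np.random.default_rng(0)
    for j, t in enumerate(contexts):
        samp, _ = maxent.gibbs_sample(codebook_model, t, n_samples=2000,
                                      spacing=100, seed=rng)
        lz = _logZ_sampled(vocab_model)
        e = np.array([maxent.energy(vocab_model, s) for s in samp])
        out[j] = float(np.mean(e + lz)) / _LN2 / dt
    return out


def _logZ_sampled(model, **kw):  # pragma: no cover - large-N fallback
    return logZ_thermo(model, None, **kw)


def logZ_thermo(model: MaxEntModel, t: int | None = None, grid: int = 60,
                samples: int = 5000, seed: int = 0) -> float:
    """log Z at T=1 by thermodynamic integration over inverse temperature:
    d logZ / d beta = -<E>_beta, anchored at logZ(beta=0) = N ln 2."""
    rng = np.random.default_rng(seed)
    n = model.n_neurons
    betas = np.linspace(0.0, 1.0, grid)
    mean_e = np.empty(grid)
    state = rng.integers(0, 2, size=n).astype(np.uint8)
    spacing = max(2 * n, 20)
    for k, b in enumerate(betas):
        if b == 0:
            sig = rng.integers(0, 2, size=(samples, n)).astype(np.float64)
            h = model.fields_at(t)
            mean_e[k] = float(np.mean(-(sig @ h) - 0.5 * np.einsum(
                "si,ij,sj->s", sig, model.J, sig)))
            continue
        samp, energies = maxent.gibbs_sample(
            model, t, n_samples=samples, spacing=spacing, seed=rng,
            temp=1.0 / b, burnin=20 * spacing, init_state=state)
        state = samp[-1]
        mean_e[k] = float(energies.mean())
    return n * _LN2 - float(np.trapezoid(mean_e, betas))


def mutual_information(vocab_model, codebook_model: MaxEntModel,
                       contexts=None, **thermo_kw) -> InfoReport:
    """Information accounting: I = S[vocabulary] - mean_t S[P(sigma|t)].

    Also fills the per-context surprise trace and instantaneous
    information i(t) = S_hat_x(t) - S[P(sigma|t)]/dt (non-negative when the
    vocabulary is the codebook's marginal, by Gibbs' inequality).
    ``vocab_model`` may be an explicit probability vector over codewords.
    """
    _check_same_n(vocab_model, codebook_model)
    dt = codebook_model.dt
    T = codebook_model.n_contexts
    if contexts is None:
        contexts = list(range(T))
    if isinstance(vocab_model, MaxEntModel):
        s_vocab = entropy(vocab_model, None, **thermo_kw).value_bits
    else:
        s_vocab = _vocab_entropy_bits(vocab_model, codebook_model.n_neurons)
    s_cond = np.array([entropy(codebook_model, t, **thermo_kw).value_bits
                       for t in contexts])
    surp = surprise_trace(vocab_model, codebook_model, contexts)
    inst = surp - s_cond / dt
    noise = float(s_cond.mean())
    return InfoReport(
        vocab_entropy_bits=s_vocab, noise_entropy_bits=noise,
        mutual_information_bits=s_vocab - noise, dt=dt,
        surprise_rate=surp, instantaneous_info_rate=inst,
        cond_entropy_bits=s_cond)


# ---------------------------------------------------------------------------
# stimulus source entropy
# ---------------------------------------------------------------------------

def source_entropy_rate(levels: int, mean: float, std: float,
                        update_rate: float, dist: str = "gaussian") -> float:
    """Entropy rate of the quantized luminance source, bits/s.

    The display quantizes a Gaussian to integer gray values 0..levels-1
    (rounding, ends absorbing the tails); the rate is the entropy of that
    discrete distribution times the update rate.  ``dist="uniform"`` gives
    the flat-source reference log2(levels) * rate.
    """
    if levels < 2:
        raise ValueError("levels must be >= 2")
    if dist == "uniform":
        return float(np.log2(levels) * update_rate)
    if std <= 0:
        raise ValueError("std must be positive")
    edges = np.arange(levels - 1) + 0.5  # cell boundaries between gray values
    cdf = norm.cdf(edges, loc=mean, scale=std)
    p = np.diff(np.concatenate([[0.0], cdf, [1.0]]))
    p = p[p > 0]
    h = -float(np.sum(p * np.log2(p)))
    return h * update_rate
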