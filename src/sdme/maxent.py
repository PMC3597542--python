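"""Maximum entropy model algebra for binary population codewords.

Implements the model grid used throughout the package:

========  ==============================  =========================
class     single-neuron terms             pairwise terms
========  ==============================  =========================
static1   static fields alpha_i           --
static2   static fields alpha_i           static couplings beta_ij
T1        per-time-bin fields lambda_i(t) --
T2        per-time-bin fields lambda_i(t) static couplings J_ij
S1        generator-binned fields h_i(x)  --
S2        generator-binned fields h_i(x)  static couplings J_ij
========  ==============================  =========================

Energy convention: ``E(sigma; t) = -sum_i h_i(t) sigma_i
- sum_{i<j} J_ij sigma_i sigma_j`` and ``P(sigma|t) = exp(-E)/Z(t)``,
so high-probability codewords sit at low energy (energy-landscape
convention: minima are metastable states).

For N <= ENUM_CAP neurons, partition functions, moments and entropies
are computed exactly by enumeration of all 2^N states; beyond that a
Metropolis sampler (numba-accelerated) is the workhorse.

Codeword integer encoding: neuron 0 is the least significant bit.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy.special import expit, logsumexp

ENUM_CAP = 20  # enumerate at most 2^20 states exactly

MODEL_CLASSES = ("static1", "static2", "T1", "T2", "S1", "S2")

_LN2 = np.log(2.0)


# ---------------------------------------------------------------------------
# state enumeration
# ---------------------------------------------------------------------------

@lru_cache(maxsize=4)
def state_table(n_neurons: int) -> np.ndarray:
    """All 2^N binary codewords as a (2^N, N) float array.

    Row ``s`` is the codeword whose integer encoding is ``s``
    (neuron 0 = least significant bit).
    """
    if n_neurons > ENUM_CAP:
        raise ValueError(
            f"enumeration over 2^{n_neurons} states exceeds cap {ENUM_CAP}; "
            "use sampling-based estimators"
        )
    ints = np.arange(2 ** n_neurons, dtype=np.uint32)
    bits = (ints[:, None] >> np.arange(n_neurons)[None, :]) & 1
    return bits.astype(np.float64)


def encode_words(words: np.ndarray) -> np.ndarray:
    """Integer encoding of binary codewords (..., N), neuron 0 = LSB."""
    words = np.asarray(words)
    n = words.shape[-1]
    if n > 63:
        raise ValueError("integer encoding supports at most 63 neurons")
    weights = (1 << np.arange(n, dtype=np.int64))
    return (words.astype(np.int64) @ weights)


def decode_words(codes: np.ndarray, n_neurons: int) -> np.ndarray:
    """Inverse of :func:`encode_words`."""
    codes = np.asarray(codes, dtype=np.int64)
    return ((codes[..., None] >> np.arange(n_neurons)) & 1).astype(np.uint8)


# ---------------------------------------------------------------------------
# model container
# ---------------------------------------------------------------------------

@dataclass
class FieldSpec:
    """Single-neuron terms of a maximum entropy model.

    Exactly one variant is active:

    - ``static``: ``alpha`` (N,) — one field per neuron.
    - ``time_indexed``: ``lam`` (N, T) — one field per neuron per time bin.
    - ``generator_binned``: ``h`` list of per-neuron arrays (K_i,) together
      with ``bin_edges`` (K_i + 1,) on the neuron's generator signal, plus a
      resolved ``bin_index`` (N, T) map once a stimulus context is attached.
    """

    variant: str
    alpha: np.ndarray | None = None
    lam: np.ndarray | None = None
    h: list | None = None
    bin_edges: list | None = None
    bin_index: np.ndarray | None = None

    def __post_init__(self):
        if self.variant not in ("static", "time_indexed", "generator_binned"):
            raise ValueError(f"unknown field variant {self.variant!r}")


@dataclass
class MaxEntModel:
    """A maximum entropy model of the codeword distribution P(sigma | t).

    ``J`` is the symmetric zero-diagonal coupling matrix (identically zero
    for order-1 classes); for the static vocabulary model the couplings are
    conventionally called beta but live in the same slot.
    """

    model_class: str
    fields: FieldSpec
    J: np.ndarray
    dt: float = 0.02
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.model_class not in MODEL_CLASSES:
            raise ValueError(f"unknown model class {self.model_class!r}")
        self.J = np.asarray(self.J, dtype=np.float64)
        n = self.J.shape[0]
        if self.J.shape != (n, n):
            raise ValueError("J must be square")
        if not np.allclose(self.J, self.J.T):
            raise ValueError("J must be symmetric")
        if np.any(np.diag(self.J) != 0):
            raise ValueError("J must have zero diagonal")

    # -- basic introspection -------------------------------------------------
    @property
    def n_neurons(self) -> int:
        return self.J.shape[0]

    @property
    def n_contexts(self) -> int:
        f = self.fields
        if f.variant == "static":
            return 1
        if f.variant == "time_indexed":
            return f.lam.shape[1]
        if f.bin_index is None:
            raise ValueError("generator-binned model has no attached context")
        return f.bin_index.shape[1]

    @property
    def is_pairwise(self) -> bool:
        return self.model_class in ("static2", "T2", "S2")

    # -- field resolution ----------------------------------------------------
    def fields_at(self, t: int | None = None) -> np.ndarray:
        """Resolved per-neuron fields h_i for context ``t``."""
        f = self.fields
        if f.variant == "static":
            return np.asarray(f.alpha, dtype=np.float64)
        if t is None:
            raise ValueError(f"{self.model_class} model requires a time context")
        if f.variant == "time_indexed":
            return np.asarray(f.lam[:, t], dtype=np.float64)
        if f.bin_index is None:
            raise ValueError("generator-binned model has no attached context; "
                             "call set_context(x) first")
        k = f.bin_index[:, t]
        return np.array([f.h[i][k[i]] for i in range(self.n_neurons)])

    def field_matrix(self) -> np.ndarray:
        """(N, T) matrix of resolved fields across all contexts."""
        f = self.fields
        if f.variant == "static":
            return np.asarray(f.alpha, dtype=np.float64)[:, None]
        if f.variant == "time_indexed":
            return np.asarray(f.lam, dtype=np.float64)
        if f.bin_index is None:
            raise ValueError("generator-binned model has no attached context")
        n, T = f.bin_index.shape
        out = np.empty((n, T))
        for i in range(n):
            out[i] = np.asarray(f.h[i])[f.bin_index[i]]
        return out

    def set_context(self, x: np.ndarray) -> None:
        """Attach a stimulus context to an S-class model.

        ``x`` is the (N, T) generator-signal matrix; it is digitized with
        each neuron's bin edges (out-of-range values clamp to end bins).
        """
        if self.fields.variant != "generator_binned":
            raise ValueError("set_context only applies to S-class models")
        x = np.atleast_2d(np.asarray(x, dtype=np.float64))
        idx = np.empty(x.shape, dtype=np.int64)
        for i in range(x.shape[0]):
            edges = np.asarray(self.fields.bin_edges[i])
            idx[i] = np.clip(np.digitize(x[i], edges[1:-1]), 0, len(edges) - 2)
        self.fields.bin_index = idx


# ---------------------------------------------------------------------------
# energies, partition functions, moments (exact)
# ---------------------------------------------------------------------------

def energy(model: MaxEntModel, sigma: np.ndarray, t: int | None = None) -> float:
    """Energy E(sigma; t) = -h(t).sigma - sum_{i<j} J_ij sigma_i sigma_j."""
    sigma = np.asarray(sigma, dtype=np.float64)
    if sigma.shape[-1] != model.n_neurons:
        raise ValueError("codeword length does not match model size")
    h = model.fields_at(t)
    pair = 0.5 * np.einsum("...i,ij,...j->...", sigma, model.J, sigma)
    return -(sigma @ h) - pair


def _pair_energy_per_state(states: np.ndarray, J: np.ndarray) -> np.ndarray:
    # -sum_{i<j} J_ij s_i s_j for every enumerated state (J has zero diagonal)
    return -0.5 * np.einsum("si,sj,ij->s", states, states, J, optimize=True)


def logZ_exact(model: MaxEntModel, t: int | None = None) -> float:
    """Exact log partition function by enumeration (N <= ENUM_CAP)."""
    states = state_table(model.n_neurons)
    e = _pair_energy_per_state(states, model.J) - states @ model.fields_at(t)
    return float(logsumexp(-e))


def log_prob_exact(model: MaxEntModel, t: int | None = None) -> np.ndarray:
    """log P(sigma|t) over all 2^N enumerated states (natural log)."""
    states = state_table(model.n_neurons)
    e = _pair_energy_per_state(states, model.J) - states @ model.fields_at(t)
    return -e - logsumexp(-e)


def moments_exact(model: MaxEntModel, t: int | None = None):
    """Exact first and second moments (<sigma_i>, <sigma_i sigma_j>) at t."""
    states = state_table(model.n_neurons)
    p = np.exp(log_prob_exact(model, t))
    m1 = states.T @ p
    m2 = states.T @ (states * p[:, None])
    return m1, m2


def _batched_log_probs(model: MaxEntModel, block: int = 1 << 22):
    """Yield (t_slice, logP (2^N, nt)) blocks across all contexts."""
    states = state_table(model.n_neurons)
    q = _pair_energy_per_state(states, model.J)
    H = model.field_matrix()
    T = H.shape[1]
    cols = max(1, block // states.shape[0])
    for lo in range(0, T, cols):
        hi = min(T, lo + cols)
        neg_e = states @ H[:, lo:hi] - q[:, None]
        lp = neg_e - logsumexp(neg_e, axis=0, keepdims=True)
        yield slice(lo, hi), lp


def logZ_all(model: MaxEntModel) -> np.ndarray:
    """Exact log Z(t) for every context of the model."""
    states = state_table(model.n_neurons)
    q = _pair_energy_per_state(states, model.J)
    H = model.field_matrix()
    out = np.empty(H.shape[1])
    cols = max(1, (1 << 22) // states.shape[0])
    for lo in range(0, H.shape[1], cols):
        hi = min(H.shape[1], lo + cols)
        out[lo:hi] = logsumexp(states @ H[:, lo:hi] - q[:, None], axis=0)
    return out


def moments_all(model: MaxEntModel):
    """Per-context first moments and the context-averaged second moments.

    Returns ``(m1, m2_pooled)`` with ``m1`` of shape (N, T) and
    ``m2_pooled`` the (N, N) matrix of <sigma_i sigma_j> averaged uniformly
    over contexts — the pooled coincidence rates that pairwise models
    constrain.
    """
    states = state_table(model.n_neurons)
    n = model.n_neurons
    T = model.n_contexts
    m1 = np.empty((n, T))
    w = np.zeros(states.shape[0])
    for sl, lp in _batched_log_probs(model):
        p = np.exp(lp)
        m1[:, sl] = states.T @ p
        w += p.sum(axis=1)
    w /= T
    m2 = states.T @ (states * w[:, None])
    return m1, m2


# ---------------------------------------------------------------------------
# closed-form T1
# ---------------------------------------------------------------------------

def t1_from_psth(psth, dt: float, eps_p: float | None = None,
                 n_samples: int | None = None) -> MaxEntModel:
    """Closed-form conditionally independent time-dependent model.

    With per-bin spike probability ``p_i(t) = r_i(t) * dt``, the fields are
    ``lambda_i(t) = log(p / (1 - p))``.  Probabilities hitting 0 or 1 are
    clipped to ``[eps_p, 1 - eps_p]``; the default clip is
    ``1 / (2 * n_samples)`` when a sample count is given, else 1e-6.
    """
    rates = np.asarray(getattr(psth, "rates", psth), dtype=np.float64)
    p = rates * dt
    if np.any(p < -1e-12) or np.any(p > 1 + 1e-9):
        raise ValueError("rates outside [0, 1/dt]")
    if eps_p is None:
        eps_p = 0.5 / n_samples if n_samples else 1e-6
    n_clipped = int(np.sum((p < eps_p) | (p > 1 - eps_p)))
    p = np.clip(p, eps_p, 1.0 - eps_p)
    lam = np.log(p / (1.0 - p))
    n = lam.shape[0]
    return MaxEntModel(
        "T1", FieldSpec("time_indexed", lam=lam), np.zeros((n, n)), dt=dt,
        meta={"clipped_bins": n_clipped, "eps_p": eps_p},
    )


# ---------------------------------------------------------------------------
# sampling
# ---------------------------------------------------------------------------

try:  # pragma: no cover - exercised implicitly everywhere
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

    def njit(*a, **k):
        def wrap(f):
            return f
        return wrap if not (len(a) == 1 and callable(a[0])) else a[0]


@njit(cache=True)
def _metropolis_chain(h, J, temp, n_samples, spacing, state, rand_sites, rand_u):
    """Single-site Metropolis chain; records one pattern per `spacing` trials.

    ``rand_sites``/``rand_u`` are pre-drawn arrays of length
    n_samples * spacing.  Returns (samples uint8, energy per sample).
    """
    n = h.shape[0]
    out = np.empty((n_samples, n), dtype=np.uint8)
    energies = np.empty(n_samples)
    # current energy
    e = 0.0
    for i in range(n):
        if state[i]:
            e -= h[i]
            for j in range(n):
                if j != i and state[j]:
                    e -= 0.5 * J[i, j]
    k = 0
    for s in range(n_samples):
        for _ in range(spacing):
            i = rand_sites[k]
            # field felt by site i
            loc = h[i]
            for j in range(n):
                if state[j]:
                    loc += J[i, j]
            if state[i]:
                d_e = loc  # flipping 1 -> 0 raises E by +loc... sign below
                # E contribution of sigma_i=1 is -loc; removing it: dE = +loc
            else:
                d_e = -loc
            if d_e <= 0.0 or rand_u[k] < np.exp(-d_e / temp):
                state[i] = 1 - state[i]
                e += d_e
            k += 1
        out[s] = state
        energies[s] = e
    return out, energies


def gibbs_sample(model: MaxEntModel, t: int | None = None,
                 n_samples: int = 5000, spacing: int = 100,
                 seed: int | np.random.Generator = 0,
                 temp: float = 1.0, burnin: int | None = None,
                 init_state: np.ndarray | None = None):
    """Draw codewords from P(sigma|t) by single-site Metropolis sampling.

    One pattern is recorded after every ``spacing`` spin-flip trials
    (default 100); ``n_samples`` patterns are returned as a
    (n_samples, N) uint8 array.  ``temp`` rescales the energy
    (P_T proportional to exp(-E/T)) for thermodynamic scans.
    """
    if spacing < 1:
        raise ValueError("spacing must be >= 1")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    h = model.fields_at(t)
    n = model.n_neurons
    if init_state is None:
        state = rng.integers(0, 2, size=n).astype(np.uint8)
    else:
        state = np.array(init_state, dtype=np.uint8)
    if burnin is None:
        burnin = 10 * spacing
    total = n_samples * spacing + burnin
    sites = rng.integers(0, n, size=total).astype(np.int64)
    unif = rng.random(total)
    if burnin:
        # burn-in chain mutates `state` in place (spacing 1, samples discarded)
        _metropolis_chain(h, model.J, temp, burnin, 1, state,
                          sites[:burnin], unif[:burnin])
    samples, energies = _metropolis_chain(
        h, model.J, temp, n_samples, spacing, state,
        sites[burnin:], unif[burnin:])
    return samples, energies


def sample_exact(model: MaxEntModel, t: int | None, n_samples: int,
                 rng: np.random.Generator) -> np.ndarray:
    """Draw exact i.i.d. codewords at context t by enumeration (N <= cap)."""
    p = np.exp(log_prob_exact(model, t))
    idx = rng.choice(p.size, size=n_samples, p=p)
    return decode_words(idx, model.n_neurons)


def sample_raster(model: MaxEntModel, n_repeats: int,
                  seed: int | np.random.Generator = 0,
                  n_gibbs_spacing: int = 100):
    """Simulate a (repeat, time, neuron) raster: one independent codeword per
    (t, repeat) from P(sigma|t).  Exact enumeration sampling for N <= cap,
    Metropolis otherwise."""
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    n, T = model.n_neurons, model.n_contexts
    out = np.empty((n_repeats, T, n), dtype=np.uint8)
    if n <= ENUM_CAP:
        states = state_table(n).astype(np.uint8)
        for sl, lp in _batched_log_probs(model):
            p = np.exp(lp)
            for c, t in enumerate(range(sl.start, sl.stop)):
                idx = rng.choice(p.shape[0], size=n_repeats, p=p[:, c] / p[:, c].sum())
                out[:, t, :] = states[idx]
    else:
        for t in range(T):
            s, _ = gibbs_sample(model, t, n_samples=n_repeats,
                                spacing=n_gibbs_spacing, seed=rng)
            out[:, t, :] = s
    return out


# ---------------------------------------------------------------------------
# JSON (de)serialization
# ---------------------------------------------------------------------------

def model_to_dict(model: MaxEntModel) -> dict:
    f = model.fields
    d = {"model_class": model.model_class, "dt": model.dt,
         "J": model.J.tolist(), "field_variant": f.variant}
    if f.variant == "static":
        d["fields"] = np.asarray(f.alpha).tolist()
    elif f.variant == "time_indexed":
        d["fields"] = np.asarray(f.lam).tolist()
    else:
        d["fields"] = [np.asarray(hi).tolist() for hi in f.h]
        d["bin_edges"] = [np.asarray(e).tolist() for e in f.bin_edges]
        if f.bin_index is not None:
            # fitted stimulus context travels with the model so that
            # downstream evaluation is reproducible from the file alone
            d["bin_index"] = np.asarray(f.bin_index).tolist()
    return d


def save_model(model: MaxEntModel, path) -> None:
    with open(path, "w") as fh:
        json.dump(model_to_dict(model), fh)


def model_from_dict(d: dict) -> MaxEntModel:
    variant = d["field_variant"]
    if variant == "static":
        fs = FieldSpec("static", alpha=np.asarray(d["fields"], dtype=float))
    elif variant == "time_indexed":
        fs = FieldSpec("time_indexed", lam=np.asarray(d["fields"], dtype=float))
    else:
        fs = FieldSpec("generator_binned",
                       h=[np.asarray(x, dtype=float) for x in d["fields"]],
                       bin_edges=[np.asarray(x, dtype=float) for x in d["bin_edges"]],
                       bin_index=(np.asarray(d["bin_index"], dtype=np.int64)
                                  if "bin_index" in d else None))
    return MaxEntModel(d["model_class"], fs, np.asarray(d["J"], dtype=float),
                       dt=float(d.get("dt", 0.02)))


def load_model(path) -> MaxEntModel:
    with open(path) as fh:
        return model_from_dict(json.load(fh))
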