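"""Maximum-entropy inference by moment-matching gradient ascent.

Constraints are extracted from a training raster (per-time-bin rates for
T-class models, conditional rates per generator-signal bin for S-class
models, pooled pairwise coincidence rates for order-2 models) and the
model parameters are ascended on the log-likelihood, whose gradient is the
difference between data and model expectations.  The problem is convex,
so the solution is unique.

Model moments come from exact enumeration for N <= 20 neurons and from
Metropolis sampling with importance reweighting of retained samples for
larger populations.  Convergence is declared when the mean relative error
on rates drops below 1% and on coincidence rates below 5% (configurable).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.special import logit

from . import maxent
from .maxent import ENUM_CAP, FieldSpec, MaxEntModel
from .popdata import SpikeRaster

logger = logging.getLogger(__name__)

PARAM_CAP = 15.0  # |field|, |coupling| bound flagging degenerate constraints


# ---------------------------------------------------------------------------
# constraints
# ---------------------------------------------------------------------------

@dataclass
class ConstraintSet:
    """Empirical targets for one model class.

    - T1/T2: ``p`` (N, T) per-bin spike probabilities.
    - S1/S2: ``cond_means`` list of per-neuron arrays over generator bins,
      ``occupancy`` matching time-bin counts, ``bin_index`` (N, T) and
      ``bin_edges`` resolving contexts.
    - static1/static2: ``means`` (N,).
    - order-2 classes additionally carry ``m2`` — the pooled coincidence
      rates <sigma_i sigma_j> with the means on the diagonal.
    """

    model_class: str
    n_neurons: int
    dt: float
    n_samples: int
    means: np.ndarray | None = None
    p: np.ndarray | None = None
    cond_means: list | None = None
    occupancy: list | None = None
    bin_index: np.ndarray | None = None
    bin_edges: list | None = None
    m2: np.ndarray | None = None

    def __post_init__(self):
        if self.m2 is not None:
            m2 = np.asarray(self.m2)
            iu = np.triu_indices(self.n_neurons, 1)
            mins = np.minimum.outer(np.diag(m2), np.diag(m2))
            if np.any(m2[iu] > mins[iu] + 1e-9):
                raise ValueError("coincidence rates exceed min of the marginals")

    @property
    def n_contexts(self) -> int:
        if self.p is not None:
            return self.p.shape[1]
        if self.bin_index is not None:
            return self.bin_index.shape[1]
        return 1


@dataclass
class FitConfig:
    """Tunables of the gradient ascent (defaults follow the package docs)."""

    lr_fields: float = 1.0          # diagonal-Newton step scale on fields
    lr_J: float = 0.4               # diagonal-Newton step scale on couplings
    max_iter: int = 5000
    rate_tol: float = 0.01          # mean relative error on rates
    coinc_tol: float = 0.05        # mean relative error on coincidences
    mc_samples: int = 50_000        # MC samples per gradient step (large N)
    mc_spacing: int = 10
    ess_threshold: float = 0.5      # refresh importance samples below this
    param_cap: float = PARAM_CAP
    max_step: float = 0.5           # trust-region clip on any parameter step
    seed: int = 0

    def __post_init__(self):
        if self.rate_tol <= 0 or self.coinc_tol <= 0:
            raise ValueError("tolerances must be positive")


@dataclass
class FitTrace:
    """Per-iteration convergence diagnostics."""

    rate_err: list = field(default_factory=list)
    coinc_err: list = field(default_factory=list)
    max_rate_err: list = field(default_factory=list)
    step_norm: list = field(default_factory=list)
    converged: bool = False
    degenerate: bool = False
    n_iter: int = 0


def extract_constraints(raster: SpikeRaster, ln_models=None,
                        model_class: str = "S2") -> ConstraintSet:
    """Empirical constraint targets over the (training) raster."""
    if model_class not in maxent.MODEL_CLASSES:
        raise ValueError(f"unknown model class {model_class!r}")
    X = raster.pooled().astype(np.float64)
    M = X.shape[0]
    N = raster.n_neurons
    means = X.mean(axis=0)
    cs = ConstraintSet(model_class=model_class, n_neurons=N, dt=raster.dt,
                       n_samples=M, means=means)
    if model_class in ("static2", "T2", "S2"):
        m2 = (X.T @ X) / M
        np.fill_diagonal(m2, means)
        cs.m2 = m2
    if model_class in ("T1", "T2"):
        cs.p = raster.spikes.mean(axis=0).T  # (N, T)
    if model_class in ("S1", "S2"):
        if ln_models is None or ln_models.x is None:
            raise ValueError("S-class constraints need fitted LN models with "
                             "cached generator signals")
        p_t = raster.spikes.mean(axis=0).T
        edges = [np.asarray(e, dtype=float) for e in ln_models.bin_edges]
        bin_index = np.empty((N, raster.n_bins), dtype=np.int64)
        cond_means, occupancy, new_edges = [], [], []
        for i in range(N):
            e = edges[i]
            k = np.clip(np.digitize(ln_models.x[i], e[1:-1]), 0, len(e) - 2)
            occ = np.bincount(k, minlength=len(e) - 1)
            # merge zero-occupancy bins into their lower neighbor
            while np.any(occ == 0) and len(e) > 2:
                j = int(np.where(occ == 0)[0][0])
                e = np.delete(e, max(j, 1))
                logger.info("neuron %d: merged empty generator bin %d", i, j)
                k = np.clip(np.digitize(ln_models.x[i], e[1:-1]), 0, len(e) - 2)
                occ = np.bincount(k, minlength=len(e) - 1)
            cm = np.bincount(k, weights=p_t[i], minlength=len(e) - 1) / occ
            bin_index[i] = k
            cond_means.append(cm)
            occupancy.append(occ)
            new_edges.append(e)
        cs.cond_means = cond_means
        cs.occupancy = occupancy
        cs.bin_index = bin_index
        cs.bin_edges = new_edges
    return cs


# ---------------------------------------------------------------------------
# target/model moment plumbing
# ---------------------------------------------------------------------------

def _constraint_floors(cs: ConstraintSet):
    """Half-count floors, one per field constraint, mirroring the target
    structure: a statistic estimated from M samples is known to ~1/M, so
    relative errors and probability clips bottom out at 0.5/M."""
    if cs.model_class in ("static1", "static2"):
        return np.full((cs.n_neurons, 1), 0.5 / cs.n_samples)
    if cs.model_class in ("T1", "T2"):
        per_bin = cs.n_samples / cs.n_contexts  # repeats per time bin
        return np.full_like(cs.p, 0.5 / per_bin)
    reps = cs.n_samples / cs.n_contexts
    return [0.5 / np.maximum(occ * reps, 2.0) for occ in cs.occupancy]


def _initial_model(cs: ConstraintSet) -> MaxEntModel:
    """Fields from the independent closed form, couplings zero."""
    N = cs.n_neurons
    J = np.zeros((N, N))
    floors = _constraint_floors(cs)
    if cs.model_class in ("static1", "static2"):
        e = floors[:, 0]
        fs = FieldSpec("static", alpha=logit(np.clip(cs.means, e, 1 - e)))
    elif cs.model_class in ("T1", "T2"):
        fs = FieldSpec("time_indexed",
                       lam=logit(np.clip(cs.p, floors, 1 - floors)))
    else:
        h = [logit(np.clip(cm, e, 1 - e))
             for cm, e in zip(cs.cond_means, floors)]
        fs = FieldSpec("generator_binned", h=h, bin_edges=cs.bin_edges,
                       bin_index=cs.bin_index)
    return MaxEntModel(cs.model_class, fs, J, dt=cs.dt)


def _field_targets(cs: ConstraintSet):
    if cs.model_class in ("static1", "static2"):
        return cs.means[:, None]
    if cs.model_class in ("T1", "T2"):
        return cs.p
    return cs.cond_means  # list of arrays


def _model_field_stats(cs: ConstraintSet, m1: np.ndarray):
    """Model-side statistics matching the field constraints."""
    if cs.model_class in ("static1", "static2"):
        return m1
    if cs.model_class in ("T1", "T2"):
        return m1
    out = []
    for i in range(cs.n_neurons):
        k = cs.bin_index[i]
        occ = cs.occupancy[i].astype(float)
        out.append(np.bincount(k, weights=m1[i], minlength=len(occ)) / occ)
    return out


def _apply_field_step(model: MaxEntModel, cs: ConstraintSet, delta, cap):
    f = model.fields
    if f.variant == "static":
        f.alpha = np.clip(f.alpha + delta[:, 0], -cap, cap)
    elif f.variant == "time_indexed":
        f.lam = np.clip(f.lam + delta, -cap, cap)
    else:
        for i in range(model.n_neurons):
            f.h[i] = np.clip(f.h[i] + delta[i], -cap, cap)


def _rel_err(target, model_val, floor):
    t = np.asarray(target, dtype=float)
    m = np.asarray(model_val, dtype=float)
    return np.abs(m - t) / np.maximum(t, floor)


# ---------------------------------------------------------------------------
# the fitter
# ---------------------------------------------------------------------------

def fit(model_class_or_cs, constraints: ConstraintSet | None = None,
        config: FitConfig | None = None, force_mc: bool = False,
        init_model: MaxEntModel | None = None):
    """Fit a maximum entropy model to empirical constraints.

    Accepts either ``fit(constraints)`` or ``fit(model_class, constraints)``;
    returns ``(MaxEntModel, FitTrace)``.  Non-convergence returns the best
    model found with ``trace.converged == False``.  ``init_model``
    overrides the default closed-form initialization (the problem is
    convex, so the solution does not depend on it).
    """
    if isinstance(model_class_or_cs, ConstraintSet):
        cs = model_class_or_cs
    else:
        cs = constraints
        if cs.model_class != model_class_or_cs:
            raise ValueError("model class mismatch with constraints")
    cfg = config or FitConfig()
    model = init_model if init_model is not None else _initial_model(cs)
    trace = FitTrace()
    pairwise = model.is_pairwise
    exact = (cs.n_neurons <= ENUM_CAP) and not force_mc
    sampler = None if exact else _MCMoments(model, cfg)

    targets_f = _field_targets(cs)
    floors_f = _constraint_floors(cs)
    iu = np.triu_indices(cs.n_neurons, 1)
    floor_pair = 0.5 / max(cs.n_samples, 2)
    lr_f, lr_J = cfg.lr_fields, cfg.lr_J
    prev_score = np.inf
    var_floor = 1e-4

    for it in range(cfg.max_iter):
        if exact:
            m1, m2 = maxent.moments_all(model)
        else:
            m1, m2 = sampler.moments(model)
        stats_f = _model_field_stats(cs, m1)

        # relative errors
        if isinstance(targets_f, list):
            errs = np.concatenate([_rel_err(targets_f[i], stats_f[i], floors_f[i])
                                   for i in range(cs.n_neurons)])
        else:
            errs = _rel_err(targets_f, stats_f, floors_f).ravel()
        rate_err = float(errs.mean())
        max_rate_err = float(errs.max())
        if pairwise:
            coinc_errs = _rel_err(cs.m2[iu], m2[iu], floor_pair)
            coinc_err = float(coinc_errs.mean())
        else:
            coinc_err = 0.0
        trace.rate_err.append(rate_err)
        trace.coinc_err.append(coinc_err)
        trace.max_rate_err.append(max_rate_err)

        if rate_err < cfg.rate_tol and coinc_err < cfg.coinc_tol:
            trace.converged = True
            trace.n_iter = it
            break

        # adaptive step scale: halve on clear oscillation of the combined
        # score (20% worsening; a tighter trigger lets exact-arithmetic
        # micro-fluctuations collapse the rate to zero), regrow gently
        score = rate_err / cfg.rate_tol + coinc_err / cfg.coinc_tol
        if score > prev_score * 1.2:
            lr_f *= 0.5
            lr_J *= 0.5
        else:
            lr_f = min(lr_f * 1.05, cfg.lr_fields)
            lr_J = min(lr_J * 1.05, cfg.lr_J)
        prev_score = score

        # diagonal-Newton field step: d<sigma>/dh = var; steps are clipped
        # to a trust region — unclipped Newton oscillates when fields and
        # couplings are strongly cross-coupled (e.g. near-degenerate pairs)
        ms = cfg.max_step
        if isinstance(targets_f, list):
            delta = [np.clip(lr_f * (targets_f[i] - stats_f[i])
                             / np.maximum(stats_f[i] * (1 - stats_f[i]),
                                          var_floor), -ms, ms)
                     for i in range(cs.n_neurons)]
            step_sq = sum(float(np.sum(d ** 2)) for d in delta)
        else:
            stats_arr = np.asarray(stats_f)
            delta = np.clip(lr_f * (targets_f - stats_arr) / np.maximum(
                stats_arr * (1 - stats_arr), var_floor), -ms, ms)
            step_sq = float(np.sum(delta ** 2))
        _apply_field_step(model, cs, delta, cfg.param_cap)

        if pairwise:
            dJ = np.clip(lr_J * (cs.m2 - m2)
                         / np.maximum(m2 * (1 - m2), var_floor), -ms, ms)
            dJ = 0.5 * (dJ + dJ.T)
            np.fill_diagonal(dJ, 0.0)
            model.J = np.clip(model.J + dJ, -cfg.param_cap, cfg.param_cap)
            step_sq += float(np.sum(dJ ** 2))
        trace.step_norm.append(np.sqrt(step_sq))
        if not exact:
            sampler.after_update(model)
    else:
        trace.n_iter = cfg.max_iter
        logger.warning("fit(%s) did not converge: rate err %.4g, coinc err %.4g",
                       cs.model_class, trace.rate_err[-1], trace.coinc_err[-1])

    at_cap = np.any(np.abs(model.J) >= cfg.param_cap - 1e-9)
    if model.fields.variant == "static":
        at_cap |= np.any(np.abs(model.fields.alpha) >= cfg.param_cap - 1e-9)
    trace.degenerate = bool(at_cap)
    if trace.degenerate:
        logger.warning("parameters hit the cap +-%g: degenerate constraints",
                       cfg.param_cap)
    return model, trace


class _MCMoments:
    """Monte-Carlo moment estimator with importance reweighting.

    Keeps a pool of Metropolis samples per context drawn under reference
    parameters; between parameter updates the samples are reweighted by
    the energy difference, and any context whose effective sample size
    falls below the threshold is redrawn.
    """

    def __init__(self, model: MaxEntModel, cfg: FitConfig):
        self.cfg = cfg
        self.rng = np.random.default_rng(cfg.seed)
        T = model.n_contexts
        self.per_ctx = max(50, cfg.mc_samples // T)
        self.samples = [None] * T
        self.ref_logw = [None] * T  # -E under reference params
        self._draw_all(model)

    def _draw(self, model, t):
        s, _ = maxent.gibbs_sample(model, t, n_samples=self.per_ctx,
                                   spacing=self.cfg.mc_spacing, seed=self.rng)
        self.samples[t] = s.astype(np.float64)
        self.ref_logw[t] = self._neg_energy(model, t)

    def _draw_all(self, model):
        for t in range(len(self.samples)):
            self._draw(model, t)

    def _neg_energy(self, model, t):
        s = self.samples[t]
        h = model.fields_at(t)
        return s @ h + 0.5 * np.einsum("si,ij,sj->s", s, model.J, s)

    def after_update(self, model):
        for t in range(len(self.samples)):
            logw = self._neg_energy(model, t) - self.ref_logw[t]
            logw -= logw.max()
            w = np.exp(logw)
            ess = w.sum() ** 2 / np.sum(w ** 2)
            if ess < self.cfg.ess_threshold * self.per_ctx:
                self._draw(model, t)

    def moments(self, model):
        T = len(self.samples)
        n = model.n_neurons
        m1 = np.empty((n, T))
        m2 = np.zeros((n, n))
        for t in range(T):
            s = self.samples[t]
            logw = self._neg_energy(model, t) - self.ref_logw[t]
            logw -= logw.max()
            w = np.exp(logw)
            w /= w.sum()
            m1[:, t] = s.T @ w
            m2 += (s.T * w) @ s
        m2 /= T
        np.fill_diagonal(m2, m1.mean(axis=1))
        return m1, m2


def fit_static(raster: SpikeRaster, config: FitConfig | None = None):
    """Static pairwise maximum entropy model of the pooled vocabulary."""
    cs = extract_constraints(raster, model_class="static2")
    return fit(cs, config=config)


def compare_couplings(J_s2: np.ndarray, beta_static: np.ndarray) -> dict:
    """Scatter comparison of stimulus-dependent vs static couplings.

    Returns upper-triangle pairs, the Pearson r, the least-squares
    regression slope of J on beta, and the sign-agreement fraction.
    """
    J = np.asarray(J_s2, dtype=float)
    B = np.asarray(beta_static, dtype=float)
    if J.shape != B.shape:
        raise ValueError("coupling matrices must have the same shape")
    iu = np.triu_indices(J.shape[0], 1)
    x, y = B[iu], J[iu]
    r = float(np.corrcoef(x, y)[0, 1]) if x.size > 1 else np.nan
    xc = x - x.mean()
    slope = float((xc @ (y - y.mean())) / (xc @ xc)) if np.any(xc) else np.nan
    sign_agree = float(np.mean(np.sign(x) == np.sign(y)))
    return {"pairs": np.column_stack([x, y]), "pearson_r": r,
            "slope": slope, "sign_agreement": sign_agree}
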