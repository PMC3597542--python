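"""Energy-landscape clustering of codewords into metastable states.

At every time bin the fitted model defines an energy over all 2^N
codewords; local minima of that landscape (no single-bit flip lowers the
energy) act as attractors, and every observed codeword is assigned to one
by greedy steepest descent.  The census of attractor visits per time bin
is a drastically simplified — and, on held-out repeats, reproducible —
summary of the population response.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import maxent
from .maxent import MaxEntModel
from .popdata import SpikeRaster

DEFAULT_MIN_VISITS = 30


@dataclass
class MetastableMap:
    """Attractor census per time bin.

    ``assignments[t]`` maps observed codeword (integer encoding) to its
    attractor codeword; ``census[t]`` maps attractor -> visit count over
    repeats; ``energies[t]`` maps attractor -> energy; only attractors
    with more than ``min_visits`` visits survive in ``census``.
    """

    assignments: list          # per t: dict {codeword int -> attractor int}
    census: list               # per t: dict {attractor int -> visits}
    energies: list             # per t: dict {attractor int -> energy}
    min_visits: int
    n_repeats: int


def descend(model: MaxEntModel, sigma: np.ndarray, t: int | None = None):
    """Greedy steepest descent to the nearest local energy minimum.

    At each step the single-bit flip with the largest energy decrease is
    applied (ties broken by lowest neuron index); the walk stops when no
    flip decreases the energy.  Energy strictly decreases along the path,
    so termination is guaranteed.
    """
    sig = np.array(sigma, dtype=np.float64).ravel()
    if sig.size != model.n_neurons:
        raise ValueError("codeword length does not match model size")
    h = model.fields_at(t)
    J = model.J
    while True:
        # dE of flipping each bit: +loc if on (1->0), -loc if off (0->1)
        loc = h + J @ sig
        d_e = np.where(sig > 0.5, loc, -loc)
        i = int(np.argmin(d_e))  # argmin returns the lowest index on ties
        if d_e[i] >= 0:
            return sig.astype(np.uint8)
        sig[i] = 1.0 - sig[i]


def _descend_codes(model, codes, t):
    """Descend each distinct integer codeword; returns dict code -> attractor
    (integer encoding) and dict attractor -> energy."""
    n = model.n_neurons
    assign, energies = {}, {}
    for c in codes:
        star = descend(model, maxent.decode_words(np.int64(c), n), t)
        a = int(maxent.encode_words(star))
        assign[int(c)] = a
        if a not in energies:
            energies[a] = float(maxent.energy(model, star, t))
    return assign, energies


def census(model: MaxEntModel, raster: SpikeRaster,
           min_visits: int = DEFAULT_MIN_VISITS) -> MetastableMap:
    """Per-time-bin attractor visit census of a raster.

    Every observed codeword is descended to its attractor; attractors with
    more than ``min_visits`` visits (over repeats) are kept in the census.
    Visit counts across all attractors sum to the number of repeats before
    thresholding.
    """
    codes_rt = maxent.encode_words(raster.spikes)  # (R, T)
    assignments, censuses, energies = [], [], []
    for t in range(raster.n_bins):
        col = codes_rt[:, t]
        uniq, counts = np.unique(col, return_counts=True)
        assign, e_map = _descend_codes(model, uniq, t)
        visits = {}
        for c, n_c in zip(uniq, counts):
            a = assign[int(c)]
            visits[a] = visits.get(a, 0) + int(n_c)
        kept = {a: v for a, v in visits.items() if v > min_visits}
        assignments.append(assign)
        censuses.append(kept)
        energies.append({a: e_map[a] for a in visits})
    return MetastableMap(assignments=assignments, census=censuses,
                         energies=energies, min_visits=min_visits,
                         n_repeats=raster.n_repeats)


def traintest_overlap(map_train: MetastableMap, map_test: MetastableMap) -> dict:
    """Generalization of the metastable census across disjoint repeat sets.

    Pools attractors over time bins (as (t, attractor) keys), reports the
    fraction of train-set attractors also visited in the test set (and
    vice versa), paired visit frequencies for the scatter, and their
    Pearson correlation.
    """
    if len(map_train.census) != len(map_test.census):
        raise ValueError("maps cover different numbers of time bins")
    shared, only_train, only_test = 0, 0, 0
    f_train, f_test = [], []
    for t in range(len(map_train.census)):
        a_tr = map_train.census[t]
        a_te = map_test.census[t]
        keys = set(a_tr) | set(a_te)
        for a in keys:
            in_tr, in_te = a in a_tr, a in a_te
            shared += in_tr and in_te
            only_train += in_tr and not in_te
            only_test += in_te and not in_tr
            f_train.append(a_tr.get(a, 0) / map_train.n_repeats)
            f_test.append(a_te.get(a, 0) / map_test.n_repeats)
    f_train = np.asarray(f_train)
    f_test = np.asarray(f_test)
    n_tr = shared + only_train
    n_te = shared + only_test
    r = (float(np.corrcoef(f_train, f_test)[0, 1])
         if len(f_train) > 1 and f_train.std() > 0 and f_test.std() > 0
         else np.nan)
    return {
        "overlap_train": shared / n_tr if n_tr else np.nan,
        "overlap_test": shared / n_te if n_te else np.nan,
        "overlap": 2 * shared / (n_tr + n_te) if (n_tr + n_te) else np.nan,
        "freq_train": f_train, "freq_test": f_test, "pearson_r": r,
        "n_shared": shared,
    }


def is_local_minimum(model: MaxEntModel, sigma, t: int | None = None) -> bool:
    """True when no single-bit flip lowers the energy of ``sigma``."""
    sig = np.asarray(sigma, dtype=np.float64).ravel()
    loc = model.fields_at(t) + model.J @ sig
    d_e = np.where(sig > 0.5, loc, -loc)
    return bool(np.all(d_e >= 0))
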