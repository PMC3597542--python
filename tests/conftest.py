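"""Shared fixtures: small ground-truth synthetic experiments.

Everything is generated programmatically at fixed seeds; session scope
keeps the expensive fits shared across test modules.
"""

import numpy as np
import pytest

from sdme import fit as fitmod
from sdme import ln as lnmod
from sdme import popdata, synthdata


@pytest.fixture(scope="session")
def exp6():
    """N=6 coupled synthetic experiment with train/test split and LN fit."""
    truth, stim, raster = synthdata.synth_experiment(
        N=6, n_repeats=300, duration_s=8.0, seed=7)
    train, test = popdata.split_odd_even(raster)
    ln_models = lnmod.fit_ln(train, stim, D=40, K=8)
    return {"truth": truth, "stim": stim, "raster": raster,
            "train": train, "test": test, "ln": ln_models}


@pytest.fixture(scope="session")
def exp6_s2(exp6):
    """S2 and S1 fits on the N=6 experiment's training half."""
    cs2 = fitmod.extract_constraints(exp6["train"], exp6["ln"], "S2")
    s2, tr2 = fitmod.fit(cs2)
    cs1 = fitmod.extract_constraints(exp6["train"], exp6["ln"], "S1")
    s1, tr1 = fitmod.fit(cs1)
    assert tr2.converged and tr1.converged
    return {"S2": s2, "S1": s1, "cs2": cs2, "cs1": cs1}


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
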