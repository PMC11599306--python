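"""Shared fixtures: small deterministic datasets and ready-made fits."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import hostassay as ha
from hostassay.mcmc import MCMCSettings, ModelSpec, PosteriorDraws, PriorSpec


@pytest.fixture(scope="session")
def small_design():
    return ha.make_design(2, 3, 2, 10, broods_per_pop=(5, 5))


@pytest.fixture(scope="session")
def fixtures():
    return ha.make_fixtures(seed=11)


@pytest.fixture(scope="session")
def strong_fit(fixtures):
    """Binary survival fit on the strong-host-effect fixture table."""
    settings = MCMCSettings(iterations=4000, burnin=1500, thin=5, seed=7)
    return ha.fit_binary_glmm(fixtures["strong_host"], ModelSpec.survival(),
                              PriorSpec(), settings)


@pytest.fixture(scope="session")
def mass_fit(fixtures):
    settings = MCMCSettings(iterations=3000, burnin=1000, thin=4, seed=8)
    return ha.fit_gaussian_lmm(fixtures["small"], ModelSpec.mass(),
                               PriorSpec(), settings)


def make_draws(intercept, variances, effects, family="gaussian",
               response="mass", var_residual=1.0, seed=0):
    """Construct a known-answer PosteriorDraws object.

    ``intercept``: (S,) array.  ``variances``: {term: (S,) array}.
    ``effects``: {term: (levels, (S, q) array)}.
    """
    intercept = np.asarray(intercept, dtype=float)
    S = len(intercept)
    cols = {"intercept": intercept}
    for t, v in variances.items():
        cols[f"var_{t}"] = np.broadcast_to(np.asarray(v, float), (S,)).copy()
    cols["var_residual"] = np.broadcast_to(
        np.asarray(var_residual, float), (S,)).copy()
    levels = {}
    for t, (lvls, mat) in effects.items():
        mat = np.asarray(mat, dtype=float)
        levels[t] = tuple(lvls)
        for j, lv in enumerate(lvls):
            cols[f"u_{t}[{lv}]"] = mat[:, j]
    spec = ModelSpec(response=response, family=family,
                     random_terms=tuple(effects))
    settings = MCMCSettings(iterations=S, burnin=0, thin=1, seed=seed)
    return PosteriorDraws(params=pd.DataFrame(cols), spec=spec,
                          priors=PriorSpec(), settings=settings,
                          levels=levels)


def cell_effects(pops, hosts, rng, scale=1.0, S=400):
    """Random effect blocks for a full population x host grid."""
    ph = [f"{p}:{h}" for p in pops for h in hosts]
    return {
        "host": (hosts, scale * rng.standard_normal((S, len(hosts)))),
        "population": (pops, scale * rng.standard_normal((S, len(pops)))),
        "population:host": (ph, scale * rng.standard_normal((S, len(ph)))),
    }
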