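"""Shared fixtures: small synthetic landscapes, species and sample matrices.

Everything is generated programmatically with fixed seeds; session scope
keeps the heavier objects (fitted replicate designs) shared across tests.
"""

import pandas as pd
import pytest

import nichekit as nk


@pytest.fixture(scope="session")
def species():
    return nk.default_species()


@pytest.fixture(scope="session")
def landscape(species):
    names = list(species.response_params)
    return nk.generate_landscape(
        len(names), (60, 60), autocorr_range=2, seed=11, layer_names=names
    )


@pytest.fixture(scope="session")
def sample_matrix(species, landscape):
    surf = nk.suitability_surface(species, landscape)
    occ = nk.sample_occurrences(surf, landscape, 500, seed=21)
    pabs = nk.sample_pseudo_absence(landscape, occ, n=1000, seed=22)
    return nk.build_sample_matrix(landscape, occ, pabs)


@pytest.fixture(scope="session")
def small_fit(sample_matrix):
    """Three-family x three-replicate design plus its ensemble."""
    models, evals = nk.run_replicates(["RF", "GLM", "GBM"], sample_matrix, reps=3, seed=31)
    em = nk.build_ensemble(models, evals, sample_matrix, k=3, seed=31)
    return models, evals, em


@pytest.fixture(scope="session")
def range_pair():
    """Offset-0 native/invaded pair with extracted environments."""
    occ_n, occ_i, s_n, s_i = nk.make_range_pair(niche_offset=0.0, seed=41)
    bg_n = pd.DataFrame(s_n.to_matrix()[0], columns=s_n.names)
    bg_i = pd.DataFrame(s_i.to_matrix()[0], columns=s_i.names)
    env_n = nk.extract(s_n, occ_n)
    env_i = nk.extract(s_i, occ_i)
    return dict(
        occ_native=occ_n, occ_invasive=occ_i, stack_native=s_n, stack_invasive=s_i,
        bg_native=bg_n, bg_invasive=bg_i, env_native=env_n, env_invasive=env_i,
    )


def pooled_background(stack):
    return pd.DataFrame(stack.to_matrix()[0], columns=stack.names)
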