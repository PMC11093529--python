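import numpy as np
import pytest

from abmix.mixture import CategoricalMixture, FitConfig, em_fit
from abmix.synthetic import (
    SyntheticScenario,
    make_ground_truth_mixture,
    make_shifted_species,
    make_toy_reference_alignment,
    sample_repertoire,
)
from abmix.numbering import build_chain_profile
from abmix.positions import canonical_positions


@pytest.fixture(scope="session")
def default_scenario():
    return SyntheticScenario(seed=0)


@pytest.fixture(scope="session")
def truth_model(default_scenario):
    return make_ground_truth_mixture(default_scenario)


@pytest.fixture(scope="session")
def shifted_model(truth_model, default_scenario):
    return make_shifted_species(truth_model, default_scenario.divergence, seed=1)


@pytest.fixture(scope="session")
def fitted_human(truth_model, default_scenario):
    rep, _ = sample_repertoire(truth_model, default_scenario.n_train, seed=10)
    model, _ = em_fit(rep, default_scenario.K_true, FitConfig(seed=0))
    return model


@pytest.fixture(scope="session")
def fitted_shifted(shifted_model, default_scenario):
    rep, _ = sample_repertoire(shifted_model, default_scenario.n_train, seed=11)
    model, _ = em_fit(rep, default_scenario.K_true, FitConfig(seed=0))
    return model


@pytest.fixture(scope="session")
def toy_heavy_alignment():
    return make_toy_reference_alignment("H", n_rows=200, indel_rate=0.02, seed=42)


@pytest.fixture(scope="session")
def toy_heavy_profile(toy_heavy_alignment):
    aln = toy_heavy_alignment
    return build_chain_profile(aln.gapped_rows, aln.positions, "H")


def make_random_model(rng, K, L, chain_type="H"):
    """Small random mixture on the first L canonical positions."""
    pi = rng.dirichlet(np.ones(K))
    theta = rng.dirichlet(np.ones(21), size=(K, L))
    return CategoricalMixture(
        positions=canonical_positions()[:L],
        mixture_weights=pi,
        emission_probs=theta,
        chain_type=chain_type,
    )
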