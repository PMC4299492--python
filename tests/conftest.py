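import numpy as np
import pytest

from ebaflux.io import MetabolicModelFile, Reaction
from ebaflux._gpr import parse_gpr
from ebaflux.synth import (generate_toy_metabolic_model, generate_trn,
                           generate_training_scenarios, simulate_compendium)
from ebaflux.transcriptional import fit


@pytest.fixture(scope="session")
def small_truth():
    """30-gene / 6-TF ground-truth network."""
    network, truth = generate_trn(30, 6, 4, seed=3)
    return network, truth


@pytest.fixture(scope="session")
def training_setup(small_truth):
    _, truth = small_truth
    system, scenarios = generate_training_scenarios(truth, 80, seed=3)
    return system, scenarios


@pytest.fixture(scope="session")
def noisefree_compendium(small_truth, training_setup):
    _, truth = small_truth
    system, scenarios = training_setup
    return simulate_compendium(truth, 5, scenarios, noise_sd=0.0, seed=3,
                               system=system)


@pytest.fixture(scope="session")
def fitted_model(small_truth, noisefree_compendium):
    """Self-consistent model: fitted on noise-free data, so y_wt satisfies
    the linear equations exactly."""
    network, _ = small_truth
    return fit(network, noisefree_compendium)


@pytest.fixture(scope="session")
def toy_met(small_truth):
    _, truth = small_truth
    non_tf = [g for g in truth.genes if g not in set(truth.tf_ids)]
    return generate_toy_metabolic_model(4, 1, seed=3, enzyme_genes=non_tf)


@pytest.fixture()
def chain_model():
    """EX_A (ub 10) -> R1: A->B -> BIO: B->; growth is forced to 10."""
    return MetabolicModelFile(
        metabolites=["A", "B"],
        reactions=[
            Reaction("EX_A", {"A": 1.0}, 0.0, 10.0, is_exchange=True),
            Reaction("R1", {"A": -1.0, "B": 1.0}, 0.0, 1000.0,
                     gpr=parse_gpr("gE")),
            Reaction("BIO", {"B": -1.0}, 0.0, 1000.0),
        ],
        biomass_reaction_id="BIO",
    )


@pytest.fixture()
def diamond_model():
    """A -> B via R2 or R3 (each ub 10), uptake ub 10."""
    return MetabolicModelFile(
        metabolites=["A", "B"],
        reactions=[
            Reaction("EX_A", {"A": 1.0}, 0.0, 10.0, is_exchange=True),
            Reaction("R2", {"A": -1.0, "B": 1.0}, 0.0, 10.0),
            Reaction("R3", {"A": -1.0, "B": 1.0}, 0.0, 10.0),
            Reaction("BIO", {"B": -1.0}, 0.0, 1000.0),
        ],
        biomass_reaction_id="BIO",
    )
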