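"""Shared fixtures: small simulated experiments reused across test modules."""

import numpy as np
import pandas as pd
import pytest

from subloc import (
    ProfileTable,
    SimulationConfig,
    estimate_content_by_sample,
    normalize_profiles,
    rescale_to_endogenous,
    simulate_psm_table,
    simulate_rna_experiment,
)


@pytest.fixture(scope="session")
def noiseless_dataset():
    """Noiseless, uniform-content experiment: the exact-recovery regime."""
    cfg = SimulationConfig(
        n_transcripts=300,
        nb_dispersion=0.0,
        replicates=1,
        content=tuple([1 / 8] * 8),
        seed=11,
    )
    return simulate_rna_experiment(cfg)


@pytest.fixture(scope="session")
def noisy_dataset():
    """Default-noise experiment at reduced size for module tests."""
    cfg = SimulationConfig(n_transcripts=800, seed=7)
    return simulate_rna_experiment(cfg)


def normalized_control_profiles(dataset):
    """Spike-in normalized, row-normalized profiles (all conditions)."""
    content = estimate_content_by_sample(dataset.rna_profiles, dataset.spikeins)
    endo = rescale_to_endogenous(dataset.rna_profiles, dataset.spikeins)
    norm = normalize_profiles(endo, content)
    return norm


@pytest.fixture(scope="session")
def normalized_noiseless(noiseless_dataset):
    return normalized_control_profiles(noiseless_dataset)


@pytest.fixture(scope="session")
def normalized_noisy(noisy_dataset):
    return normalized_control_profiles(noisy_dataset)


@pytest.fixture(scope="session")
def psm_simulation():
    cfg = SimulationConfig(n_proteins=400, psm_noise_sd=0.0, seed=5)
    psm, protein_truth, psm_truth = simulate_psm_table(cfg)
    return psm, protein_truth, psm_truth


@pytest.fixture()
def toy_profile_table():
    """Tiny hand-written raw profile table (2 features, 4 fractions)."""
    df = pd.DataFrame(
        {
            "feature_id": ["a", "b"],
            "biotype": ["protein_coding", "protein_coding"],
            "condition": ["control", "control"],
            "replicate": [1, 1],
            "fraction_1": [2.0, 1.0],
            "fraction_2": [2.0, 1.0],
            "fraction_3": [4.0, 1.0],
            "fraction_4": [2.0, 1.0],
        }
    )
    return ProfileTable(df, state="raw")
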