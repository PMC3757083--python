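"""Shared fixtures: one study-scale synthetic run and one desk-scale run."""

from __future__ import annotations

import pytest

import crossonco as co


@pytest.fixture(scope="session")
def default_config() -> co.SimulationConfig:
    return co.SimulationConfig(rng_seed=1)


@pytest.fixture(scope="session")
def default_study(default_config):
    """Full study-scale synthetic dataset (147 fish + 23 human samples)."""
    return co.simulate_study(default_config)


@pytest.fixture(scope="session")
def default_fish_matrix(default_study):
    human_genes, fish_genes, _, fish_profiles, _, _ = default_study
    return co.gene_level_matrix(fish_profiles, fish_genes, co.Species.FISH)


def small_config(seed: int = 0, **overrides) -> co.SimulationConfig:
    """A scaled-down study for cheap unit tests."""
    params = dict(
        n_ancestral_genes=600,
        n_human_chroms=5,
        n_fish_chroms=6,
        n_rp_diploid=16,
        n_tp53_diploid=12,
        n_tp53_triploid=12,
        n_human_samples=8,
        n_fish_gain_chroms=2,
        n_fish_loss_chroms=1,
        n_human_gain_chroms=1,
        n_human_loss_chroms=2,
        n_fish_focal_gains=2,
        n_fish_focal_losses=1,
        n_human_focal_gains=2,
        n_human_focal_losses=1,
        n_mirna_families=12,
        n_concordant_gain_families=2,
        n_concordant_loss_families=2,
        rng_seed=seed,
    )
    params.update(overrides)
    return co.SimulationConfig(**params)


@pytest.fixture(scope="session")
def small_study():
    return co.simulate_study(small_config(seed=4))
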