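import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from amdcomp.simulate import (
    PlantedIndicator,
    SimulationConfig,
    simulate_paired_counts,
    to_read_table,
)


@pytest.fixture(scope="session")
def small_config():
    """Four small communities, uniform composition, no planted effects."""
    return SimulationConfig(
        n_communities=4, n_genera=4, n_cogs=10, depth_dna=10_000, depth_cdna=10_000, seed=11
    )


@pytest.fixture(scope="session")
def planted_config():
    """One strong higher-indicator planted in the cDNA layer of DBS."""
    return SimulationConfig(
        n_communities=4,
        n_genera=4,
        n_cogs=10,
        depth_dna=10_000,
        depth_cdna=10_000,
        seed=23,
        planted_indicators=(
            PlantedIndicator("Acidithiobacillus|COG0002", "DBS", 8.0, "higher"),
        ),
    )


@pytest.fixture(scope="session")
def planted_dataset(planted_config):
    return simulate_paired_counts(planted_config)


@pytest.fixture(scope="session")
def read_table(planted_dataset):
    dna, cdna, _ = planted_dataset
    return to_read_table(dna, cdna)


@pytest.fixture()
def tiny_reads():
    """Hand-written five-read annotated table."""
    return pd.DataFrame(
        {
            "read_id": [f"r{i}" for i in range(5)],
            "sample": ["A", "A", "A", "B", "B"],
            "layer": ["DNA", "DNA", "cDNA", "DNA", "cDNA"],
            "genus": ["Leptospirillum", "Acidiphilium", "Leptospirillum", "Leptospirillum", None],
            "species": [None] * 5,
            "cog_id": ["COG0001", "COG0002", "COG0001", None, "COG0002"],
            "cog_category": ["C", "E", "C", None, "E"],
            "kegg_pathway": [None] * 5,
        }
    )
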