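import dataclasses

import numpy as np
import pandas as pd
import pytest

import micronet as mn
from micronet.data_model import OtuTable


@pytest.fixture
def tiny_counts():
    """3 OTUs x 4 samples (2 subjects x 2 conditions)."""
    counts = pd.DataFrame(
        {
            "S01_PL": [12, 0, 3],
            "S01_BR": [20, 0, 7],
            "S02_PL": [5, 0, 9],
            "S02_BR": [8, 0, 11],
        },
        index=pd.Index(["OTU_1", "OTU_2", "OTU_3"], name="otu_id"),
    )
    tax = pd.Series(
        [
            "Bacteria;Firmicutes;C;O;F;Streptococcus;Streptococcus mitis",
            "Bacteria;Bacteroidetes;C;O;F;Prevotella;Prevotella oris",
            "Bacteria;Proteobacteria;C;O;F;Neisseria;Neisseria subflava",
        ],
        index=counts.index,
        name="taxonomy",
    )
    return counts, tax


@pytest.fixture
def tiny_table(tiny_counts):
    counts, tax = tiny_counts
    return OtuTable(counts=counts, taxonomy=tax)


def small_params(**overrides):
    """A scaled-down generator preset for fast unit tests: 4 planted modules,
    ~150 OTUs, shallower sequencing, no planted condition effects or trait
    couplings unless supplied."""
    base = dict(
        module_sizes=(40, 30, 30, 24),
        n_background_otus=20,
        sequencing_depth=30_000,
        condition_effects=(),
        trait_couplings=(),
    )
    base.update(overrides)
    return dataclasses.replace(mn.SyntheticParams(), **base)


@pytest.fixture(scope="session")
def study_scale_dataset():
    """One study-scale synthetic dataset shared across tests."""
    return mn.generate(seed=11)


@pytest.fixture(scope="session")
def small_dataset():
    return mn.generate(small_params(), seed=7)


def rng(seed=0):
    return np.random.default_rng(seed)
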