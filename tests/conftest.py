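import warnings

import numpy as np
import pandas as pd
import pytest

from thermogut import (SampleMetadata, SyntheticConfig, FeatureTable,
                       generate_expression, generate_microbiome)

warnings.filterwarnings("ignore", module="statsmodels")


@pytest.fixture(scope="session")
def default_study():
    """One default synthetic study shared by read-only tests."""
    cfg = SyntheticConfig(seed=11)
    table, meta, truth = generate_microbiome(cfg)
    expr = generate_expression(cfg, truth)
    return cfg, table, meta, truth, expr


def null_config(seed, **overrides):
    """A small study with every systematic effect switched off: samples iid."""
    kwargs = dict(
        seed=seed,
        n_families_per_group=2,
        fish_per_family=3,
        n_taxa=40,
        n_core_taxa=5,
        depth_mean=5000,
        dm_concentration_cold=150.0,
        dm_concentration_warm=150.0,
        shift_resistant=0.0,
        shift_sensitive=0.0,
        diversity_drop_cold=0.0,
        tolerance_sd=0.0,
        family_sd=0.0,
        part_sd=0.0,
        microbiome_latent_scale=0.0,
        latent_loading=0.0,
        n_transcripts=60,
    )
    kwargs.update(overrides)
    return SyntheticConfig(**kwargs)


@pytest.fixture
def tiny_table():
    """4 samples x 3 features with easy hand arithmetic."""
    data = pd.DataFrame(
        [[6, 2, 0], [2, 2, 0], [0, 0, 5], [1, 1, 1]],
        index=["s1", "s2", "s3", "s4"],
        columns=["t1", "t2", "t3"],
    )
    return FeatureTable(data)


def make_metadata(sample_ids, tolerance, temperature, family=None, part=None, fish=None):
    n = len(sample_ids)
    return SampleMetadata(pd.DataFrame({
        "tolerance": tolerance,
        "temperature": temperature,
        "family": family if family is not None else ["F1"] * n,
        "part": part if part is not None else ["anterior"] * n,
        "fish": fish if fish is not None else [f"fish{i}" for i in range(n)],
    }, index=sample_ids))
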