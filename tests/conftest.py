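"""Shared fixtures: small synthetic datasets generated at collection time."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from lhmap import simulate
from lhmap.regionstats import PairDesign


@pytest.fixture(scope="session")
def paired_counts():
    """11-pair x 20-region count matrix with 4 known signal regions."""
    params = simulate.CountSimParams(
        n_pairs=11,
        n_regions=20,
        signal_regions=(0, 1, 2, 3),
        signal_directions={3: -1},
        log_fold_change=1.0,
        seed=42,
    )
    counts, design_df, truth = simulate.gen_region_counts(params)
    return counts, PairDesign.from_frame(design_df), design_df, truth


@pytest.fixture(scope="session")
def behavior_cohort():
    """144-animal shuttle-box cohort with true phenotypes."""
    params = simulate.BehaviorSimParams(n_animals=144, p_helpless=0.22, seed=11)
    trials, truth = simulate.gen_behavior_cohort(params)
    return trials, truth


@pytest.fixture(scope="session")
def toy_atlas_params():
    return simulate.CloudSimParams(
        volume_shape=(20, 20, 8),
        voxel_size=(50.0, 50.0, 50.0),
        region_layout=simulate.default_brain_layout((20, 20, 8)),
        cells_per_region=150.0,
        seed=5,
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
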