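"""Shared fixtures: the desk-scale study conditions.

The desk scale (300 datasets per model, 200 quartet subsamples per
dataset, 100 haplotypes, 10-kb locus, theta = rho = 15) is the package's
scaled-down version of the full design (10^4 datasets per model, 10^3
subsamples); the simulations are expensive, so the labeled datasets and
their feature tables are built once per session and shared.
"""

import numpy as np
import pandas as pd
import pytest

from recombpast import (ExperimentConfig, THREE_MODEL_LABELS,
                        dataset_summary_table, features_for_models,
                        simulate_model_datasets)

DESK_SEED = 0


@pytest.fixture(scope="session")
def desk_cfg():
    return ExperimentConfig(datasets_per_model=300, n_subsamples=200,
                            seed=DESK_SEED)


@pytest.fixture(scope="session")
def three_model_data(desk_cfg):
    """300 labeled datasets under each of constant / linear-inc / linear-dec."""
    return simulate_model_datasets(desk_cfg, THREE_MODEL_LABELS)


@pytest.fixture(scope="session")
def lowhigh_data(desk_cfg):
    """300 datasets each under the 15%/85%-of-linear-maximum constants."""
    return simulate_model_datasets(desk_cfg, ["constant-low", "constant-high"])


@pytest.fixture(scope="session")
def three_model_features(desk_cfg, three_model_data):
    return features_for_models(desk_cfg, three_model_data)


@pytest.fixture(scope="session")
def four_model_features(desk_cfg, lowhigh_data, three_model_features):
    lohi = features_for_models(desk_cfg, lowhigh_data)
    lin = three_model_features[
        three_model_features["label"].isin(["linear-inc", "linear-dec"])]
    return pd.concat([lohi, lin], ignore_index=True)


@pytest.fixture(scope="session")
def three_model_summaries(three_model_data):
    return dataset_summary_table(three_model_data)
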