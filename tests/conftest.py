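import numpy as np
import pandas as pd
import pytest

import licograde as lg

#: coarse hyperparameter grids (same e^-5..e^5 / 10^-5..10^5 ranges, fewer
#: steps) for tests where grid resolution is not the property under test
SMALL_C_GRID = np.exp(np.linspace(-5, 5, 6))
SMALL_GAMMA_GRID = 10.0 ** np.linspace(-5, 5, 6)


@pytest.fixture(scope="session")
def dataset():
    """Default synthetic study, seed 1."""
    return lg.simulate_batches(lg.GeneratorConfig(seed=1))


@pytest.fixture(scope="session")
def feature_table(dataset):
    return lg.build_feature_table(dataset)


@pytest.fixture(scope="session")
def compliant_features(dataset, feature_table):
    compliant = lg.apply_compliance_filter(dataset.batches, dataset.contents)
    return feature_table[
        feature_table["batch_id"].isin(compliant["batch_id"])
    ].reset_index(drop=True)


@pytest.fixture(scope="session")
def pipeline_result(compliant_features):
    """Full default pipeline (documented 21-point grids), seed 1."""
    return lg.run_full_pipeline(compliant_features, seed=1)


def small_study_config(seed: int = 0, **overrides) -> "lg.GeneratorConfig":
    """An 80-batch study with proportionally scaled grade counts, for tests
    where dataset size is not the property under test."""
    cfg = lg.GeneratorConfig(
        n_batches=80,
        grade_counts={"premium": 15, "first": 26, "second": 13},
        seed=seed,
        **overrides,
    )
    return cfg


def compliant_feature_table(config) -> pd.DataFrame:
    ds = lg.simulate_batches(config)
    ft = lg.build_feature_table(ds)
    ok = lg.apply_compliance_filter(ds.batches, ds.contents)
    return ft[ft["batch_id"].isin(ok["batch_id"])].reset_index(drop=True)
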