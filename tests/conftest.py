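import numpy as np
import pandas as pd
import pytest

from coralsource import (GBMParams, BoostedSurvival, TrueResponse,
                         ReplicationLayout, default_reef_profiles,
                         gen_cross_design, gen_survival)


@pytest.fixture(scope="session")
def reef_profiles() -> pd.DataFrame:
    return default_reef_profiles()


@pytest.fixture(scope="session")
def full_design(reef_profiles):
    return gen_cross_design(reef_profiles["reef_id"].tolist())


@pytest.fixture(scope="session")
def larval_table(full_design, reef_profiles) -> pd.DataFrame:
    """Well-level larval survival under the default unimodal truth."""
    truth = TrueResponse(driver_metric="TSA_DHW_stdev",
                         coefficients=(0.332, 1.08, -0.45),
                         residual_sd=0.02)
    return gen_survival(full_design, reef_profiles, truth, seed=42,
                        stages=("larva",))


@pytest.fixture(scope="session")
def small_fit(larval_table, reef_profiles):
    """A quick, small boosted fit shared by diagnostics tests."""
    model = BoostedSurvival.from_survival_table(larval_table, reef_profiles,
                                                stage="larva")
    res = model.fit(GBMParams(n_trees=60, shrinkage=0.1, interaction_depth=2,
                              min_obs_in_node=10, bag_fraction=0.8, seed=7))
    return model, res


@pytest.fixture()
def smooth_regression():
    """Continuous-feature smooth target for CV and oracle comparisons."""
    rng = np.random.default_rng(123)
    n = 150
    X = pd.DataFrame(rng.uniform(0, 1, size=(n, 4)),
                     columns=[f"f{i}" for i in range(4)])
    y = 80 - 120 * (X["f0"] - 0.55) ** 2 + rng.normal(0, 3, n)
    return X, y.to_numpy()
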