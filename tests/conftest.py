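import numpy as np
import pytest

from imseeker.automl import AutoMLBudget, SearchSpace, run_automl
from imseeker.bundle import build_bundle
from imseeker.detect import DetectionParams
from imseeker.synthetic import labelled_dataset


@pytest.fixture(scope="session")
def ph_dataset():
    """Default study condition: n=500, 3 informative features, signal R2=0.9."""
    df, lm = labelled_dataset(500, seed=20260925)
    return df, lm


@pytest.fixture(scope="session")
def quick_run(ph_dataset):
    """A tiny but real AutoML run (1x1 portfolio) for bundle-level tests."""
    df, _ = ph_dataset
    space = SearchSpace(fs_portfolio=("NONE",), model_portfolio=("RIDGE",))
    return run_automl(df.iloc[:200], space=space,
                      budget=AutoMLBudget(1, 5), seed=5)


@pytest.fixture(scope="session")
def quick_bundle(quick_run):
    return build_bundle(quick_run, DetectionParams(
        scan_reverse_complement=False))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
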