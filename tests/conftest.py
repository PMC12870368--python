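import warnings

import numpy as np
import pandas as pd
import pytest

from microsem.simulate import generate_study
from microsem.tables import FeatureTable, RunConfig


@pytest.fixture(autouse=True)
def _quiet_expected_warnings():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        warnings.simplefilter("ignore", RuntimeWarning)
        yield


@pytest.fixture
def counts_3x2() -> FeatureTable:
    frame = pd.DataFrame(
        [[10, 0], [5, 5], [0, 10]],
        index=["s1", "s2", "s3"],
        columns=["taxA", "taxB"],
    )
    return FeatureTable(frame, scale="counts", feature_kind="taxon")


@pytest.fixture(scope="session")
def default_study():
    """The default synthetic study at its reference seed."""
    return generate_study(RunConfig.defaults(), seed=42)


@pytest.fixture
def rng():
    return np.random.default_rng(20260929)
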