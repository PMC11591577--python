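import numpy as np
import pytest

import ftirchem as fc
from ftirchem.preprocess import PreprocessConfig, fit_scaler


@pytest.fixture(scope="session")
def default_cohort():
    return fc.generate_cohort(fc.default_cohort_config(seed=0))


@pytest.fixture(scope="session")
def two_class_scaled(default_cohort):
    """Preprocessed + autoscaled ALS_T0 vs HC block of the default cohort."""
    sub = default_cohort.subset_groups(["ALS_T0", "HC"])
    pp = fc.preprocess(sub, PreprocessConfig())
    X = fit_scaler(pp).transform(pp.absorbance)
    return X, pp.groups, pp.grid


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
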