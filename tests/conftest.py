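import numpy as np
import pandas as pd
import pytest

import mbmi


@pytest.fixture(scope="session")
def small_cohort():
    """Session-wide medium cohort: big enough for signal, fast to fit."""
    cfg = mbmi.GeneratorConfig(n_samples=800, n_species=80, seed=42)
    return mbmi.generate_cohort(cfg)


@pytest.fixture(scope="session")
def small_features(small_cohort):
    ph = small_cohort.phenotypes
    corrected = mbmi.batch_median_center(small_cohort.lipids)
    features = pd.concat(
        [corrected.cohort().data.loc[ph.index], ph[["age", "sex"]]], axis=1)
    return features, ph


@pytest.fixture(scope="session")
def scored_cohort():
    """A larger scored cohort shared by the downstream-statistics tests."""
    cfg = mbmi.GeneratorConfig(n_samples=3000, n_species=80, seed=7)
    cohort = mbmi.generate_cohort(cfg)
    ph = cohort.phenotypes
    features = pd.concat(
        [cohort.lipids.cohort().data.loc[ph.index], ph[["age", "sex"]]], axis=1)
    spec = mbmi.ModelSpec(penalty="ridge", lam=0.094, folds=5, seed=0)
    cvp = mbmi.crossval_predict(features, ph["bmi"], spec)
    line = mbmi.fit_reference_line(cvp.pbmi, ph["bmi"])
    scores = mbmi.compute_mbmi(ph["bmi"], cvp.pbmi, line)
    scores.index = ph.index
    scores["quintile"], _ = mbmi.assign_quintiles(scores["mbmi_delta"])
    return cohort, scores


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
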