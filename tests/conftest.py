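import numpy as np
import pandas as pd
import pytest

from pathsurv.containers import (
    AlterationMatrix,
    FeatureMatrix,
    GeneSetCollection,
    SurvivalData,
)
from pathsurv.simulate import SurvivalSimConfig, generate_survival


@pytest.fixture
def toy_spm() -> AlterationMatrix:
    """3 genes x 4 samples binary matrix with hand-checkable counts."""
    df = pd.DataFrame(
        [[1, 0, 0, 1], [0, 0, 1, 1], [1, 1, 0, 0]],
        index=["g1", "g2", "g3"],
        columns=["s1", "s2", "s3", "s4"],
    )
    return AlterationMatrix(df, "binary")


@pytest.fixture
def toy_sets() -> GeneSetCollection:
    return GeneSetCollection(
        {"P1": frozenset({"g1", "g2"}), "P2": frozenset({"g3"})},
        {"P1": "two genes", "P2": "one gene"},
    )


@pytest.fixture
def toy_survival() -> SurvivalData:
    df = pd.DataFrame(
        {"time": [5.0, 3.0, 8.0, 1.0], "event": [1, 0, 1, 1]},
        index=["s1", "s2", "s3", "s4"],
    )
    return SurvivalData(df)


def make_gaussian_features(n: int, p: int, seed: int) -> FeatureMatrix:
    rng = np.random.default_rng(seed)
    df = pd.DataFrame(
        rng.standard_normal((n, p)),
        columns=[f"x{i}" for i in range(p)],
        index=[f"S{i:04d}" for i in range(n)],
    )
    return FeatureMatrix(df, "gene", "spm")


@pytest.fixture
def noise_cohort():
    """400 samples x 50 independent predictors with outcome-free survival."""
    fm = make_gaussian_features(400, 50, seed=101)
    y = generate_survival(
        fm, SurvivalSimConfig(betas={}, censoring_rate_target=0.3, seed=102)
    )
    return fm, y


@pytest.fixture
def signal_cohort():
    """300 samples x 20 predictors, survival driven by x0 (log-HR 2)."""
    fm = make_gaussian_features(300, 20, seed=103)
    y = generate_survival(
        fm,
        SurvivalSimConfig(betas={"x0": 2.0}, censoring_rate_target=0.3, seed=104),
    )
    return fm, y
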