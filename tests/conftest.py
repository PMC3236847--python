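import numpy as np
import pandas as pd
import pytest

from organspec import CountMatrix, score_matrix
from organspec import simulate as sim


@pytest.fixture(scope="session")
def small_matrix() -> CountMatrix:
    """A tiny hand-written matrix: gene gA is strongly liver-enriched,
    gB is flat, gC is brain-leaning."""
    df = pd.DataFrame(
        {
            "liver": [40, 10, 2],
            "brain": [2, 10, 30],
            "kidney": [1, 10, 5],
            "lung": [1, 10, 3],
        },
        index=["gA", "gB", "gC"],
    )
    return CountMatrix(df)


@pytest.fixture(scope="session")
def demo_truth() -> sim.SimulationTruth:
    """52-organ demonstration compendium with 20 planted markers."""
    return sim.simulate_counts(sim.demonstration_fixture(seed=20260930))


@pytest.fixture(scope="session")
def demo_scores(demo_truth) -> pd.DataFrame:
    return score_matrix(demo_truth.count_matrix)


@pytest.fixture(scope="session")
def calib_truth() -> sim.SimulationTruth:
    """Calibration compendium: strong single-organ markers plus
    two-organ markers whose minor organ falls between the RZ 3 and 4
    cutoffs."""
    return sim.simulate_counts(sim.calibration_fixture(seed=20260930))


@pytest.fixture(scope="session")
def calib_scores(calib_truth) -> pd.DataFrame:
    return score_matrix(calib_truth.count_matrix)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
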