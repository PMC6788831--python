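import numpy as np
import pandas as pd
import pytest

from cyclecurate.fixtures import (
    barbell,
    fixture_atlas_config,
    fixture_timecourse_config,
    two_triangles,
)
from cyclecurate.preprocess import ExpressionMatrix
from cyclecurate.synthetic import (
    TimecourseConfig,
    simulate_atlas,
    simulate_study,
    simulate_timecourse,
)


@pytest.fixture(scope="session")
def default_study():
    """Matched synthetic time course + atlas at study-default settings."""
    return simulate_study(seed=1)


@pytest.fixture(scope="session")
def fixture_timecourse():
    return simulate_timecourse(fixture_timecourse_config(seed=1))


@pytest.fixture(scope="session")
def fixture_atlas():
    return simulate_atlas(fixture_atlas_config(seed=1))


@pytest.fixture()
def noise_free_timecourse():
    """Single batch + zero noise: module genes are exact affine transforms."""
    return simulate_timecourse(
        TimecourseConfig(seed=2, noise_sd=0.0, batch_offsets={"b1": 0.0})
    )


@pytest.fixture()
def triangles_graph():
    return two_triangles()


@pytest.fixture()
def barbell_graph():
    return barbell()


@pytest.fixture()
def toy_matrix():
    """A small handmade matrix with batch metadata."""
    values = pd.DataFrame(
        np.array(
            [
                [1.0, 2.0, 3.0, 4.0],
                [2.0, 4.0, 6.0, 8.0],
                [4.0, 3.0, 2.0, 1.0],
            ]
        ),
        index=["up_a", "up_b", "down"],
        columns=["s1", "s2", "s3", "s4"],
    )
    meta = pd.DataFrame(
        {"batch": ["b1", "b1", "b2", "b2"]},
        index=pd.Index(values.columns, name="sample_id"),
    )
    return ExpressionMatrix(values, meta)
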