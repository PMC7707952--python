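import math

import numpy as np
import pytest

from cytodx import CohortConfig, RBFConfig
from cytodx.morphometry import NucleusBoundary
from cytodx.pipeline import run_pipeline
from cytodx.synthetic import cohort_frames, simulate_cohort, split_train_test


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


@pytest.fixture
def unit_square():
    return NucleusBoundary(np.array([[0, 0], [1, 0], [1, 1], [0, 1]], float))


@pytest.fixture
def rect_4x2():
    return NucleusBoundary(np.array([[0, 0], [4, 0], [4, 2], [0, 2]], float))


def regular_polygon(n: int, radius: float, center=(0.0, 0.0)) -> NucleusBoundary:
    t = np.linspace(0, 2 * math.pi, n, endpoint=False)
    return NucleusBoundary(
        np.column_stack([center[0] + radius * np.cos(t),
                         center[1] + radius * np.sin(t)])
    )


def random_convex_polygon(rng, n_points=12, scale=10.0) -> NucleusBoundary:
    from scipy.spatial import ConvexHull

    pts = rng.normal(0, scale, (n_points + 6, 2))
    hull = ConvexHull(pts)
    return NucleusBoundary(pts[hull.vertices])


def koch_snowflake(depth: int = 4, side: float = 243.0) -> NucleusBoundary:
    """Closed Koch snowflake polygon; boundary dimension log4/log3."""

    def edge(p0, p1, d):
        if d == 0:
            return [p0]
        p0, p1 = np.asarray(p0, float), np.asarray(p1, float)
        delta = (p1 - p0) / 3.0
        a, b = p0 + delta, p0 + 2 * delta
        ang = -math.pi / 3.0
        rot = np.array([[math.cos(ang), -math.sin(ang)],
                        [math.sin(ang), math.cos(ang)]])
        peak = a + rot @ delta
        out = []
        for q0, q1 in ((p0, a), (a, peak), (peak, b), (b, p1)):
            out += edge(q0, q1, d - 1)
        return out

    v0, v1, v2 = (0.0, 0.0), (side, 0.0), (side / 2, side * math.sqrt(3) / 2)
    pts = edge(v0, v1, depth) + edge(v1, v2, depth) + edge(v2, v0, depth)
    return NucleusBoundary(np.array(pts))


SMALL_COHORT = CohortConfig(n_cases=60, nuclei_per_case_mean=25.0, seed=5)
SMALL_RBF = RBFConfig(k_grid=(5, 10), seed=5)


@pytest.fixture(scope="session")
def small_cohort_frames():
    cohort = simulate_cohort(SMALL_COHORT)
    train, test = split_train_test(cohort, seed=SMALL_COHORT.seed)
    split = {c.case_id: "train" for c in train}
    split.update({c.case_id: "test" for c in test})
    return cohort_frames(cohort, split=split)


@pytest.fixture(scope="session")
def small_pipeline_result():
    return run_pipeline(SMALL_COHORT, SMALL_RBF)
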