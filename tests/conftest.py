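import numpy as np
import pytest

import spatscale as ss


@pytest.fixture(scope="session")
def grid7():
    """7 x 7 grid with 10-unit spacing."""
    return ss.make_rect_grid(60, 60, 10, unit_label="km")


@pytest.fixture(scope="session")
def grid10():
    """10 x 10 grid with 10-unit spacing."""
    return ss.make_rect_grid(90, 90, 10, unit_label="km")


@pytest.fixture(scope="session")
def grid20():
    """20 x 20 grid with 10-unit spacing."""
    return ss.make_rect_grid(190, 190, 10, unit_label="km")


@pytest.fixture(scope="session")
def random_points():
    """Factory for seeded uniform point sets."""

    def make(n, seed, extent=100.0):
        rng = np.random.default_rng(seed)
        return ss.PointSet(rng.uniform(0, extent, (n, 2)), unit_label="km")

    return make


@pytest.fixture(scope="session")
def rigid_motion():
    """Factory applying a rotation + translation to a point set."""

    def move(points, theta, shift):
        R = np.array(
            [[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]]
        )
        return ss.PointSet(
            points.coords @ R.T + np.asarray(shift), unit_label=points.unit_label
        )

    return move
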