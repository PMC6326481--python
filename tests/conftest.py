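import numpy as np
import pytest

from manglar import synth
from manglar.geometry import PatchLayer, PatchPolygon


@pytest.fixture
def unit_square():
    return PatchPolygon(exterior=[(0, 0), (10, 0), (10, 10), (0, 10)], id="sq")


@pytest.fixture
def square_with_hole():
    return PatchPolygon(
        exterior=[(0, 0), (10, 0), (10, 10), (0, 10)],
        holes=[[(4, 4), (6, 4), (6, 6), (4, 6)]],
        id="sq_hole",
    )


@pytest.fixture
def plus_pentomino():
    """Five 1 m cells in a plus shape: area 5, perimeter 12, 12 nodes;
    hull perimeter 4 + 4*sqrt(2), hull area 7."""
    return PatchPolygon(
        exterior=[(1, 0), (2, 0), (2, 1), (3, 1), (3, 2), (2, 2),
                  (2, 3), (1, 3), (1, 2), (0, 2), (0, 1), (1, 1)],
        id="plus",
    )


@pytest.fixture(scope="session")
def landscape():
    """Default synthetic landscape, shared across the suite."""
    return synth.generate_landscape(synth.LandscapeScript(seed=11))


@pytest.fixture(scope="session")
def confusable():
    """Confusable scene at a fixed seed with a dense truth-point sample."""
    return synth.generate_confusable_scene(
        synth.LandscapeScript(seed=11, n_truth_points=2000))


def random_rectilinear_polygon(rng: np.random.Generator) -> list[tuple[float, float]]:
    """Random staircase-style rectilinear simple polygon (open ring).

    Built from a monotone upper staircase closed by a lower rim, so it is
    always simple. Used as an oracle generator for area/perimeter/nodes.
    """
    n_steps = int(rng.integers(2, 8))
    xs = np.cumsum(rng.integers(1, 5, n_steps))
    hs = rng.integers(1, 6, n_steps)
    pts: list[tuple[float, float]] = [(0.0, 0.0), (0.0, float(hs[0]))]
    x_prev = 0.0
    for i in range(n_steps):
        x = float(xs[i])
        pts.append((x_prev, float(hs[i])))
        pts.append((x, float(hs[i])))
        x_prev = x
    pts.append((x_prev, 0.0))
    # drop duplicates introduced at the first step
    ring = []
    for p in pts:
        if not ring or p != ring[-1]:
            ring.append(p)
    return ring


def rectilinear_oracle(ring: list[tuple[float, float]]):
    """Independent vertex-walk computation of area, perimeter, node count."""
    n = len(ring)
    a2 = 0.0
    per = 0.0
    for i in range(n):
        x1, y1 = ring[i]
        x2, y2 = ring[(i + 1) % n]
        a2 += x1 * y2 - x2 * y1
        per += abs(x2 - x1) + abs(y2 - y1)  # rectilinear edges
    return abs(a2) / 2.0, per, n
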