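import numpy as np
import pytest

import zftrunk as z


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def control_phantom():
    """One control trunk phantom shared across read-only tests."""
    return z.generate_trunk_phantom(z.preset_params("control", seed=7))


def point_in_polygon_oracle(r, c, vertices):
    """Even-odd ray-casting test for a pixel center, boundary-inclusive.

    Independent of shapely: casts a horizontal ray and counts edge
    crossings; points lying exactly on an edge count as inside.
    """
    n = len(vertices)
    inside = False
    for i in range(n):
        r1, c1 = vertices[i]
        r2, c2 = vertices[(i + 1) % n]
        # on-edge check
        dr, dc = r2 - r1, c2 - c1
        cross = dr * (c - c1) - dc * (r - r1)
        if abs(cross) < 1e-9:
            if min(r1, r2) - 1e-9 <= r <= max(r1, r2) + 1e-9 and (
                min(c1, c2) - 1e-9 <= c <= max(c1, c2) + 1e-9
            ):
                return True
        if (r1 > r) != (r2 > r):
            c_int = c1 + (r - r1) * dc / dr
            if c_int > c:
                inside = not inside
    return inside
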