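import numpy as np
import pytest

import ivdquant as iq


@pytest.fixture(scope="session")
def default_spec():
    return iq.default_phantom_spec(seed=11)


@pytest.fixture(scope="session")
def default_geometry(default_spec):
    return iq.make_disc_geometry(default_spec)


@pytest.fixture(scope="session")
def noiseless_stack(default_spec, default_geometry):
    stack, truth = iq.simulate_multiecho(default_spec, default_geometry)
    return stack, truth


def brute_force_even_odd(polygon_xy: np.ndarray, px: float, py: float) -> bool:
    """Independent even-odd (ray casting) point-in-polygon test; points
    exactly on an edge count as inside."""
    n = len(polygon_xy)
    inside = False
    for i in range(n):
        x1, y1 = polygon_xy[i]
        x2, y2 = polygon_xy[(i + 1) % n]
        # on-edge check
        cross = (x2 - x1) * (py - y1) - (y2 - y1) * (px - x1)
        if abs(cross) < 1e-12:
            if min(x1, x2) - 1e-12 <= px <= max(x1, x2) + 1e-12 and \
                    min(y1, y2) - 1e-12 <= py <= max(y1, y2) + 1e-12:
                return True
        if (y1 > py) != (y2 > py):
            x_int = x1 + (py - y1) * (x2 - x1) / (y2 - y1)
            if px < x_int:
                inside = not inside
    return inside
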