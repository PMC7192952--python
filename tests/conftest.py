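import math

import numpy as np
import pytest

from hbnet.core import Frame, SimulationBox, TIP4P2005_GEOMETRY
from hbnet.fixtures import generate_ice_ih, generate_liquid_like


def random_rigid_frame(
    n_mol: int, box_length: float, seed: int, min_sep: float = 0.0
) -> Frame:
    """Frame of rigid waters at random positions and orientations.

    With ``min_sep`` > 0, oxygen positions are drawn by rejection so no
    two come closer (minimum image) than that separation.
    """
    rng = np.random.default_rng(seed)
    box = SimulationBox(np.full(3, box_length))
    g = TIP4P2005_GEOMETRY
    th = math.radians(g.theta_HOH)
    h1 = g.r_OH * np.array([1.0, 0.0, 0.0])
    h2 = g.r_OH * np.array([math.cos(th), 0.0, -math.sin(th)])

    O = []
    while len(O) < n_mol:
        cand = rng.uniform(0.0, box_length, size=3)
        if min_sep > 0 and O:
            d = cand - np.array(O)
            d -= box_length * np.floor(d / box_length + 0.5)
            if (np.linalg.norm(d, axis=1) < min_sep).any():
                continue
        O.append(cand)
    O = np.array(O)

    q = rng.standard_normal((n_mol, 4))
    q /= np.linalg.norm(q, axis=1, keepdims=True)
    w, x, y, z = q.T
    R = np.stack(
        [
            np.stack([1 - 2 * (y * y + z * z), 2 * (x * y - z * w), 2 * (x * z + y * w)], -1),
            np.stack([2 * (x * y + z * w), 1 - 2 * (x * x + z * z), 2 * (y * z - x * w)], -1),
            np.stack([2 * (x * z - y * w), 2 * (y * z + x * w), 1 - 2 * (x * x + y * y)], -1),
        ],
        axis=1,
    )
    H1 = O + np.einsum("nij,j->ni", R, h1)
    H2 = O + np.einsum("nij,j->ni", R, h2)
    return Frame(0.0, box, np.arange(1, n_mol + 1), O, H1, H2)


@pytest.fixture(scope="session")
def ice_frame() -> Frame:
    return generate_ice_ih((2, 2, 2), seed=7)


@pytest.fixture(scope="session")
def liquid_frames():
    frames, meta = generate_liquid_like(
        n_mol=96, seed=11, target_short_fraction=0.35, n_frames=3
    )
    return frames, meta
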