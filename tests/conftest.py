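import numpy as np
import pytest

from starburst.morphology import Morphology, generate_synthetic_sac


@pytest.fixture(scope="session")
def sac_morph():
    return generate_synthetic_sac(seed=1)


@pytest.fixture(scope="session")
def bar_stim():
    from starburst.stimuli import make_bar_stimulus
    return make_bar_stimulus(0.5)


def cylinder_morphology(length=500.0, diam=1.0, n=251):
    """Straight unbranched cable (non-soma root = sealed end)."""
    xyz = np.column_stack([np.linspace(0.0, length, n),
                           np.zeros(n), np.zeros(n)])
    return Morphology(xyz, np.full(n, diam / 2.0),
                      np.arange(-1, n - 1), np.full(n, 3))


def random_tree_morphology(n_sections=50, seed=0, seg_per_section=4,
                           seg_len=5.0):
    """Random branched tree: each section attaches to a uniformly chosen
    existing node and grows in a random direction."""
    rng = np.random.default_rng(seed)
    xyz = [np.zeros(3)]
    radius = [2.0]
    parent = [-1]
    ntype = [1]
    attach_points = [0]
    for _ in range(n_sections):
        a = int(rng.choice(attach_points))
        theta = rng.uniform(0, 2 * np.pi)
        d = np.array([np.cos(theta), np.sin(theta), 0.0])
        r = float(rng.uniform(0.15, 0.6))
        last = a
        for k in range(seg_per_section):
            xyz.append(xyz[a] + d * seg_len * (k + 1))
            radius.append(r)
            parent.append(last)
            ntype.append(3)
            last = len(xyz) - 1
        attach_points.append(last)
    return Morphology(np.array(xyz), np.array(radius),
                      np.array(parent, dtype=int), np.array(ntype, dtype=int))


@pytest.fixture()
def random_tree():
    return random_tree_morphology()
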