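import numpy as np
import pytest

from aaamorph import LandmarkSet, SkeletonSpec, reconstruct_landmarks


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def random_phi(rng, lo=20.0, hi=175.0):
    """A feasible 10-angle target vector, away from degenerate extremes."""
    return rng.uniform(lo, hi, size=10)


def random_torsions(rng, spread=180.0):
    return {j: float(rng.uniform(-spread, spread)) for j in SkeletonSpec._JOINTS}


def random_tree(rng) -> LandmarkSet:
    """A random genuinely-3D landmark set built from feasible angles/torsions."""
    sk = SkeletonSpec(torsions=random_torsions(rng))
    return reconstruct_landmarks(random_phi(rng), sk)


def random_point_landmarks(rng, scale=80.0) -> LandmarkSet:
    """A landmark set of 13 i.i.d. random points (no anatomy, worst case)."""
    while True:
        pts = {f"P{i}": rng.uniform(-scale, scale, 3) for i in range(1, 14)}
        try:
            return LandmarkSet.from_mapping(pts)
        except ValueError:
            continue


@pytest.fixture
def tree(rng):
    return random_tree(rng)
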