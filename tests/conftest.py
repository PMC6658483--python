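import numpy as np
import pytest

from frenetfold.geometry import FrenetAngles, angles_from_coords, coords_from_angles
from frenetfold.io_fixtures import (
    SyntheticDecoySpec,
    make_globin_like_decoy,
    make_ideal_helix,
    make_synthetic_decoy,
)
from frenetfold.model import ModelSpec, SolitonSegment


def random_chain_angles(rng, n_defined=20, theta_lo=0.3, theta_hi=3.0):
    """Feasible random (θ, φ) arrays with the gauge slot zeroed."""
    theta = rng.uniform(theta_lo, theta_hi, n_defined)
    phi = rng.uniform(-np.pi, np.pi, n_defined)
    phi[0] = 0.0
    return FrenetAngles(theta=theta, phi=phi)


@pytest.fixture(scope="session")
def ideal_helix():
    return make_ideal_helix(30)


@pytest.fixture(scope="session")
def two_kink_decoy():
    """Clean (noiseless) 2-kink decoy with ground truth."""
    return make_synthetic_decoy(SyntheticDecoySpec(n_sites=60, kink_positions=(20, 40), seed=3))


@pytest.fixture(scope="session")
def globin_decoy():
    """154-residue ten-soliton globin-like decoy with 12 titratable sites."""
    return make_globin_like_decoy()


@pytest.fixture(scope="session")
def small_model():
    """Two-segment model on a 14-site chain, generic couplings."""
    segs = (
        SolitonSegment(1, 6, lambda_=1.3, m=1.2, a=0.3, b=0.4, c=1.1, d=0.6),
        SolitonSegment(7, 12, lambda_=2.1, m=1.6, a=-0.2, b=0.5, c=0.9, d=0.2),
    )
    return ModelSpec(segments=segs, n_sites=14, titratable_sites=(3, 8))
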