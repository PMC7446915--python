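"""Shared fixtures: small rings and synthesized networks built once per session."""

import numpy as np
import pytest

from empj.dynamics import DriftSpec
from empj.manifolds import RingSpec, make_embedding_basis
from empj.metrics import fit_decoder
from empj.synthesis import SynthesisConfig, synthesize_ring_rnn


@pytest.fixture(scope="session")
def planar_ring():
    """Planar ring of radius 10 in a 240-unit state space."""
    return RingSpec(basis=make_embedding_basis(240, 2, seed=1), radius=10.0)


@pytest.fixture(scope="session")
def highdim_ring():
    """8-dimensional ring (6 von Mises bumps, kappa=2) of radius 12."""
    return RingSpec(basis=make_embedding_basis(240, 8, seed=1), radius=12.0, kappa=2.0)


@pytest.fixture(scope="session")
def drift6():
    """Sinusoidal drift with six stable fixed points, amplitude 0.1 rad/s."""
    return DriftSpec(amplitude=0.1, frequency=6)


@pytest.fixture(scope="session")
def ring_network(planar_ring, drift6):
    """Synthesized O(2,6) network plus its report."""
    return synthesize_ring_rnn(planar_ring, drift6, SynthesisConfig(tau=0.1, seed=1))


@pytest.fixture(scope="session")
def attractor_network(planar_ring):
    """Synthesized drift-free continuous ring attractor."""
    return synthesize_ring_rnn(
        planar_ring, DriftSpec(0.0, 0), SynthesisConfig(tau=0.1, seed=1, verify=False)
    )


@pytest.fixture(scope="session")
def planar_decoder(planar_ring):
    return fit_decoder(planar_ring)
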