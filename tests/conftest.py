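"""Shared fixtures: small synthetic systems reused across test modules."""

import numpy as np
import pytest

from solvagg.synthetic import (PlantedMixtureSpec, make_planted_mixture,
                               make_solvated_solute)


@pytest.fixture(scope="session")
def solvated_traj():
    """Small solvated solute with planted 0.6 contact probability on the
    O_m/N_m acceptor sites; 400 frames for tight binomial bounds."""
    return make_solvated_solute(n_waters=15, box=11.0,
                                donor_contact_prob=0.6, n_frames=400,
                                seed=11)


@pytest.fixture(scope="session")
def planted_mixture_small():
    """20-frame mixed box with planted (nn, zz, mixed) = (2, 3, 1)."""
    return make_planted_mixture(PlantedMixtureSpec(n_frames=20, seed=7))


@pytest.fixture(scope="session")
def planted_mixture_200():
    """200-frame mixed box used for frequency-recovery statistics."""
    return make_planted_mixture(PlantedMixtureSpec(n_frames=200, seed=23))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
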