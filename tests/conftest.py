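"""Shared fixtures: small reaction networks and cell-cycle models."""

import sys
from pathlib import Path

import numpy as np
import pytest

from galnoise.cellsim import CellCycleModel, GeneLocus, Reaction, ReactionNetwork

# make scripts/acceptance.py importable from the test suite
sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "scripts"))


@pytest.fixture
def fixed_volume_ccm():
    """No growth, no division: the kernel reduces to a textbook SSA."""
    return CellCycleModel(doubling_time=np.inf, birth_volume=2.0)


@pytest.fixture
def deterministic_cycle_ccm():
    """Strictly periodic cell cycle (no cycle-length randomness)."""
    return CellCycleModel(doubling_time=100.0, birth_volume=30.0,
                          cycle_length_cv=0.0, s_phase_jitter=0.0)


@pytest.fixture
def birth_death_network():
    """Constitutive synthesis (rate k*V) with first-order decay.

    At fixed volume V the stationary law is Poisson(k*V/gamma)."""
    return ReactionNetwork(
        species=["P"],
        loci=[],
        reactions=[
            Reaction("synth", "const", 3.0, vexp=1.0, stoich={"P": 1}),
            Reaction("decay", "uni", 0.4, s1="P", stoich={"P": -1}),
        ],
        init_counts={"P": 15},
    )


@pytest.fixture
def telegraph_network():
    """Two-state promoter (2 copies) with transcription and mRNA decay.

    Stationary mean mRNA = copies * k_on/(k_on+k_off) * k_tx / delta_m."""
    return ReactionNetwork(
        species=["M"],
        loci=[GeneLocus("gene", copies=2)],
        reactions=[
            Reaction("on", "per_off", 0.2, locus="gene", dlocus=+1),
            Reaction("off", "per_on", 0.3, locus="gene", dlocus=-1),
            Reaction("tx", "per_on", 1.0, locus="gene", stoich={"M": 1}),
            Reaction("dm", "uni", 0.1, s1="M", stoich={"M": -1}),
        ],
    )


@pytest.fixture
def inert_network():
    """No reactions: only growth, replication and division act."""
    return ReactionNetwork(species=["Z"], loci=[GeneLocus("g", copies=1)],
                          reactions=[], init_counts={"Z": 1000})
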