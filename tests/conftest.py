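import numpy as np
import pytest

from ligandcloud.core import AtomRecord, Frame, Trajectory
from ligandcloud.synth import (
    ChainSpec,
    LigandSpec,
    SimulationParams,
    simulate_cg,
)


def bead_topology(n, role="peptide", radius=2.0, charge=0.0, start=1):
    return [
        AtomRecord("CA" if role == "peptide" else f"L{i+1}",
                   start + i if role == "peptide" else start,
                   "ALA" if role == "peptide" else "LIG",
                   role, radius=radius, charge=charge,
                   lj_epsilon=0.1, lj_sigma=2 * radius * 2 ** (-1 / 6), mass=110.0)
        for i in range(n)
    ]


def make_trajectory(coord_frames, topology, spacing=20.0):
    frames = [Frame(np.asarray(c, dtype=float), k * spacing)
              for k, c in enumerate(coord_frames)]
    return Trajectory(topology, frames, time_spacing=spacing)


@pytest.fixture(scope="session")
def sticky_site_run():
    """A seeded chain+ligand run with a designed site on residues 3-15.

    Site stickiness is 10x the background, the spec ratio for site
    recovery.  Session-scoped: several tests read it, one simulation
    pays for it.
    """
    stick = np.full(40, 0.3)
    stick[2:15] = 3.0
    chain = ChainSpec(40, stickiness=stick)
    ligand = LigandSpec(n_beads=3)
    params = SimulationParams(n_steps=100_000, save_interval=100, seed=2026)
    return chain, ligand, simulate_cg(chain, ligand, params)
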