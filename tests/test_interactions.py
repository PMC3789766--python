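"""Contact maps, pair energies, hydrogen bonds, peptide-ligand profiles."""

import numpy as np
import pytest

from ligandcloud.core import AtomRecord
from ligandcloud.errors import ConfigurationError
from ligandcloud.interactions import (
    COULOMB_CONSTANT,
    ContactCriterion,
    HBondCriterion,
    contact_map,
    hbond_occupancy,
    pair_energy_matrices,
    peptide_ligand_profile,
)

from conftest import bead_topology, make_trajectory


def atom(name, res, role="peptide", radius=1.7, charge=0.0, eps=0.1, sigma=3.0,
         res_name="ALA"):
    return AtomRecord(name, res, res_name, role, radius=radius, charge=charge,
                      lj_epsilon=eps, lj_sigma=sigma, mass=12.0)


# ---------------------------------------------------------------------------
# Contacts
# ---------------------------------------------------------------------------

def _chain_coords(n, spacing=10.0):
    return np.column_stack([np.arange(n) * spacing, np.zeros(n), np.zeros(n)])


def test_contact_rules():
    # residues 1 and 4 fixed 3.9 A apart; residues 1 and 3 at 3.0 A;
    # residues 1 and 5 at 4.1 A
    topo = [atom("CA", r) for r in (1, 2, 3, 4, 5)]
    coords = np.array([
        [0.0, 0.0, 0.0],
        [50.0, 0.0, 0.0],
        [0.0, 3.0, 0.0],
        [3.9, 0.0, 0.0],
        [-4.1, 0.0, 0.0],
    ])
    traj = make_trajectory([coords, coords], topo)
    cm = contact_map(traj)
    assert cm.loc[1, 4] == 1.0              # 3.9 A, j = i+3: counted
    assert cm.loc[1, 3] == 0.0              # j = i+2: excluded by separation
    assert cm.loc[1, 5] == 0.0              # 4.1 A: strictly outside cutoff
    assert np.allclose(cm.values, cm.values.T)


def test_contact_probability_monotone_in_cutoff():
    rng = np.random.default_rng(1)
    topo = [atom("CA", r) for r in range(1, 9)]
    frames = [rng.uniform(0, 12, size=(8, 3)) for _ in range(10)]
    traj = make_trajectory(frames, topo)
    p4 = contact_map(traj, ContactCriterion(4.0)).values
    p6 = contact_map(traj, ContactCriterion(6.0)).values
    assert np.all(p6 >= p4 - 1e-12)


# ---------------------------------------------------------------------------
# Pair energies
# ---------------------------------------------------------------------------

def test_lj_minimum_is_minus_epsilon():
    eps, sigma = 0.25, 3.0
    topo = [atom("CA", 1, eps=eps, sigma=sigma), atom("CA", 4, eps=eps, sigma=sigma)]
    r = 2 ** (1 / 6) * sigma
    traj = make_trajectory([np.array([[0.0, 0.0, 0.0], [r, 0.0, 0.0]])], topo)
    lj, _ = pair_energy_matrices(traj)
    assert lj.loc[1, 4] == pytest.approx(-eps, rel=1e-12)


def test_coulomb_constant_arithmetic():
    r = COULOMB_CONSTANT / 100.0            # 3.320636 A
    topo = [atom("CA", 1, charge=1.0), atom("CA", 4, charge=-1.0)]
    traj = make_trajectory([np.array([[0.0, 0.0, 0.0], [r, 0.0, 0.0]])], topo)
    _, coulomb = pair_energy_matrices(traj)
    assert coulomb.loc[1, 4] == pytest.approx(-100.0, rel=1e-12)


def test_matrices_match_double_loop_oracle():
    """4-atom, 2-frame toy system vs an independent all-pairs re-summation."""
    rng = np.random.default_rng(2)
    topo = [
        atom("A1", 1, charge=0.5, eps=0.2, sigma=3.2),
        atom("A2", 1, charge=-0.3, eps=0.1, sigma=2.8),
        atom("B1", 2, charge=0.4, eps=0.15, sigma=3.5),
        atom("C1", 3, charge=-0.6, eps=0.3, sigma=3.0),
    ]
    frames = [rng.uniform(0, 8, size=(4, 3)) for _ in range(2)]
    traj = make_trajectory(frames, topo)
    lj, cl = pair_energy_matrices(traj)

    n_res = 3
    lj_ref = np.zeros((n_res, n_res))
    cl_ref = np.zeros((n_res, n_res))
    for f in frames:
        for i in range(4):
            for j in range(i + 1, 4):
                ri, rj = topo[i].residue_index - 1, topo[j].residue_index - 1
                if ri == rj:
                    continue
                r = np.linalg.norm(f[i] - f[j])
                eps = np.sqrt(topo[i].lj_epsilon * topo[j].lj_epsilon)
                sig = 0.5 * (topo[i].lj_sigma + topo[j].lj_sigma)
                e = 4 * eps * ((sig / r) ** 12 - (sig / r) ** 6)
                q = COULOMB_CONSTANT * topo[i].charge * topo[j].charge / r
                for a, b in ((ri, rj), (rj, ri)):
                    lj_ref[a, b] += e / 2
                    cl_ref[a, b] += q / 2
    lj_ref = 2 * lj_ref / len(frames)
    cl_ref = 2 * cl_ref / len(frames)
    assert np.allclose(lj.values, lj_ref, atol=1e-10)
    assert np.allclose(cl.values, cl_ref, atol=1e-10)


def test_energies_invariant_under_rigid_motion():
    rng = np.random.default_rng(3)
    topo = [atom("CA", r, charge=rng.uniform(-1, 1)) for r in range(1, 6)]
    frames = [rng.uniform(0, 10, size=(5, 3)) for _ in range(3)]
    traj = make_trajectory(frames, topo)
    lj1, cl1 = pair_energy_matrices(traj)
    shift = np.array([7.0, -2.0, 4.0])
    traj2 = make_trajectory([f + shift for f in frames], topo)
    lj2, cl2 = pair_energy_matrices(traj2)
    assert np.allclose(lj1.values, lj2.values, atol=1e-9)
    assert np.allclose(cl1.values, cl2.values, atol=1e-9)


def test_opposite_charges_attract_on_synthetic_chain():
    """Salt-bridge sign check: +/- residue pairs have negative Coulomb."""
    rng = np.random.default_rng(4)
    charges = np.array([1.0, 0.0, 0.0, -1.0, 0.0, 1.0])
    topo = [atom("CA", r + 1, charge=q) for r, q in enumerate(charges)]
    frames = [rng.uniform(0, 10, size=(6, 3)) for _ in range(20)]
    traj = make_trajectory(frames, topo)
    _, cl = pair_energy_matrices(traj)
    assert cl.loc[1, 4] < 0 and cl.loc[4, 6] < 0
    assert cl.loc[1, 6] > 0


# ---------------------------------------------------------------------------
# Hydrogen bonds
# ---------------------------------------------------------------------------

def _hbond_traj(angle_deg, da_dist=2.9):
    """Donor at origin with H at the given H-D...A angle from the acceptor."""
    theta = np.radians(angle_deg)
    d = np.array([0.0, 0.0, 0.0])
    a = np.array([da_dist, 0.0, 0.0])
    h = np.array([np.cos(theta), np.sin(theta), 0.0])
    topo = [
        atom("N", 1, res_name="GLN"),
        atom("H1", 1, radius=1.2),
        atom("O", 4, res_name="GLU"),
    ]
    return make_trajectory([np.vstack([d, h, a])], topo)


def test_hbond_geometry_criteria():
    occ = hbond_occupancy(_hbond_traj(10.0), donors=[(0, 1)], acceptors=[2])
    assert occ.loc[1, 4] == 100.0
    occ = hbond_occupancy(_hbond_traj(40.0), donors=[(0, 1)], acceptors=[2])
    assert occ.loc[1, 4] == 0.0
    occ = hbond_occupancy(_hbond_traj(10.0, da_dist=3.6), donors=[(0, 1)], acceptors=[2])
    assert occ.loc[1, 4] == 0.0


def test_persistent_bond_gives_full_occupancy():
    frames = [_hbond_traj(10.0).frames[0].coordinates for _ in range(4)]
    topo = _hbond_traj(10.0).topology
    traj = make_trajectory(frames, topo)
    occ = hbond_occupancy(traj, donors=[(0, 1)], acceptors=[2])
    assert occ.loc[1, 4] == 100.0
    assert occ.loc[4, 1] == 100.0           # symmetrised


def test_donor_without_hydrogen_rejected():
    traj = _hbond_traj(10.0)
    with pytest.raises(ConfigurationError, match="hydrogen"):
        hbond_occupancy(traj, donors=[(0, None)], acceptors=[2])


# ---------------------------------------------------------------------------
# Peptide-ligand profile
# ---------------------------------------------------------------------------

def _profile_traj(lig_pos, lig_charge=0.0):
    topo = bead_topology(4) + [
        AtomRecord("L1", 5, "LIG", "ligand", radius=2.5, charge=lig_charge,
                   lj_epsilon=0.1, lj_sigma=4.0, mass=150.0)
    ]
    pep = _chain_coords(4)
    coords = np.vstack([pep, [list(lig_pos)]])
    return make_trajectory([coords], topo)


def test_distant_neutral_ligand_flat_profile():
    traj = _profile_traj((100.0, 100.0, 100.0))
    prof = peptide_ligand_profile(traj)
    assert np.all(np.abs(prof["lj"]) < 1e-6)
    assert np.all(prof["coulomb"] == 0.0)
    assert np.all(prof["hbond_pct"] == 0.0)


def test_parked_ligand_energy_lands_on_one_residue():
    traj = _profile_traj((0.0, 4.5, 0.0))    # near residue 1 only
    prof = peptide_ligand_profile(traj)
    assert prof.loc[1, "lj"] != 0.0
    assert abs(prof.loc[1, "lj"]) > 10 * abs(prof.loc[3, "lj"])


def test_profile_partitions_total_energy():
    rng = np.random.default_rng(5)
    topo = bead_topology(5, charge=0.2) + [
        AtomRecord("L1", 6, "LIG", "ligand", radius=2.5, charge=-0.4,
                   lj_epsilon=0.15, lj_sigma=4.0, mass=150.0),
        AtomRecord("L2", 6, "LIG", "ligand", radius=2.5, charge=0.1,
                   lj_epsilon=0.15, lj_sigma=4.0, mass=150.0),
    ]
    frames = [rng.uniform(0, 15, size=(7, 3)) for _ in range(3)]
    traj = make_trajectory(frames, topo)
    prof = peptide_ligand_profile(traj)

    # oracle: total peptide-ligand energy summed directly
    lj_tot, cl_tot = 0.0, 0.0
    for f in frames:
        for i in range(5):
            for j in (5, 6):
                r = np.linalg.norm(f[i] - f[j])
                eps = np.sqrt(topo[i].lj_epsilon * topo[j].lj_epsilon)
                sig = 0.5 * (topo[i].lj_sigma + topo[j].lj_sigma)
                lj_tot += 4 * eps * ((sig / r) ** 12 - (sig / r) ** 6)
                cl_tot += COULOMB_CONSTANT * topo[i].charge * topo[j].charge / r
    assert prof["lj"].sum() == pytest.approx(lj_tot / 3, abs=1e-9)
    assert prof["coulomb"].sum() == pytest.approx(cl_tot / 3, abs=1e-9)


def test_profile_requires_ligand():
    traj = make_trajectory([_chain_coords(4)], bead_topology(4))
    with pytest.raises(ConfigurationError):
        peptide_ligand_profile(traj)
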