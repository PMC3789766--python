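"""Residue-residue and peptide-ligand interaction matrices.

Four complementary views of what holds an ensemble together and where a
ligand grips it: contact probabilities (any atom pair closer than 4.0 A
with sequence separation j > i+2), time-averaged Lennard-Jones and
electrostatic energies (Lorentz-Berthelot combination, Coulomb constant
332.0636 kcal A / (mol e^2), no distance cutoff -- the analysed systems
are small and image-free), and hydrogen-bond occupancy under a geometric
criterion (donor-acceptor distance <= 3.5 A and H-D...A angle <= 30 deg,
the common trajectory-analysis default; the numbers are configurable).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .core import Trajectory
from .errors import ConfigurationError

__all__ = [
    "ContactCriterion",
    "HBondCriterion",
    "InteractionMatrices",
    "contact_map",
    "pair_energy_matrices",
    "hbond_occupancy",
    "peptide_ligand_profile",
    "COULOMB_CONSTANT",
]

#: Coulomb constant in kcal*A/(mol*e^2).
COULOMB_CONSTANT = 332.0636


@dataclass(frozen=True)
class ContactCriterion:
    """Contact definition: distance strictly below the cutoff, j > i + s."""

    distance_cutoff: float = 4.0
    sequence_separation: int = 2    # exclusive: |j - i| must exceed this

    def __post_init__(self) -> None:
        if self.distance_cutoff <= 0:
            raise ValueError("distance_cutoff must be positive")
        if self.sequence_separation < 0:
            raise ValueError("sequence_separation must be non-negative")


@dataclass(frozen=True)
class HBondCriterion:
    """Geometric hydrogen-bond test on the donor-acceptor pair."""

    donor_acceptor_cutoff: float = 3.5
    angle_cutoff: float = 30.0      # degrees, H-D...A angle at the donor

    def __post_init__(self) -> None:
        if self.donor_acceptor_cutoff <= 0:
            raise ValueError("donor_acceptor_cutoff must be positive")
        if not 0 < self.angle_cutoff < 180:
            raise ValueError("angle_cutoff must be in (0, 180) degrees")


@dataclass
class InteractionMatrices:
    """The four residue x residue matrices, indexed by input numbering."""

    lj: pd.DataFrame
    coulomb: pd.DataFrame
    contact: pd.DataFrame
    hbond: pd.DataFrame | None = None


def _residue_table(traj: Trajectory, include_ligand: bool) -> tuple[np.ndarray, np.ndarray]:
    """(residue ids, per-atom position into that id list)."""
    ids = list(traj.residue_ids)
    if include_ligand and traj.has_ligand:
        lig_ids = sorted({traj.topology[i].residue_index for i in traj.ligand_indices})
        ids += [r for r in lig_ids if r not in ids]
    ids = np.array(ids)
    pos = {int(r): p for p, r in enumerate(ids)}
    atom_pos = np.array([
        pos.get(a.residue_index, -1) if (a.role == "peptide" or include_ligand) else -1
        for a in traj.topology
    ])
    return ids, atom_pos


def contact_map(traj: Trajectory, crit: ContactCriterion = ContactCriterion()) -> pd.DataFrame:
    """Residue-residue contact probability over all frames.

    Entry (i, j) is the fraction of frames in which any atom of residue i
    is strictly closer than the cutoff to any atom of residue j; pairs
    with |j - i| <= sequence_separation are left at zero.
    """
    ids = traj.residue_ids
    n_res = len(ids)
    pep = traj.peptide_indices
    res_pos = {int(r): p for p, r in enumerate(ids)}
    atom_res = np.array([res_pos[traj.topology[i].residue_index] for i in pep])

    counts = np.zeros((n_res, n_res))
    cut2 = crit.distance_cutoff ** 2
    for frame in traj.frames:
        xyz = frame.coordinates[pep]
        d2 = np.sum((xyz[:, None, :] - xyz[None, :, :]) ** 2, axis=-1)
        close = d2 < cut2
        # reduce atom pairs to residue pairs
        hit = np.zeros((n_res, n_res), dtype=bool)
        ii, jj = np.nonzero(close)
        hit[atom_res[ii], atom_res[jj]] = True
        counts += hit
    prob = counts / traj.n_frames
    sep = np.abs(ids[:, None] - ids[None, :])
    prob[sep <= crit.sequence_separation] = 0.0
    prob = np.maximum(prob, prob.T)
    return pd.DataFrame(prob, index=ids, columns=ids)


def _energy_terms(traj: Trajectory, include_ligand: bool = True):
    """Flat atom-pair lists (i, j, eps_ij, sigma_ij, qq) between residues."""
    eps = np.array([a.lj_epsilon for a in traj.topology])
    sig = np.array([a.lj_sigma for a in traj.topology])
    q = traj.charges()
    res = np.array([a.residue_index for a in traj.topology])
    role = np.array([a.role for a in traj.topology])
    n = traj.n_atoms
    iu, ju = np.triu_indices(n, k=1)
    # pairs within the same residue are excluded; reported energies are
    # inter-residue means
    keep = res[iu] != res[ju]
    if not include_ligand:
        keep &= (role[iu] == "peptide") & (role[ju] == "peptide")
    iu, ju = iu[keep], ju[keep]
    eps_ij = np.sqrt(eps[iu] * eps[ju])                 # geometric mean
    sig_ij = 0.5 * (sig[iu] + sig[ju])                  # arithmetic mean
    qq = COULOMB_CONSTANT * q[iu] * q[ju]
    return iu, ju, eps_ij, sig_ij, qq


def pair_energy_matrices(
    traj: Trajectory, include_ligand: bool = True
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Time-averaged LJ and Coulomb residue-pair energy matrices (kcal/mol).

    Sums 4 eps [(sigma/r)^12 - (sigma/r)^6] and k q_i q_j / r over all
    inter-residue atom pairs with no distance cutoff, averaged over frames.
    Missing parameters surface as a configuration error naming the atom.
    """
    for k, a in enumerate(traj.topology):
        if not np.isfinite(a.charge) or not np.isfinite(a.lj_epsilon):
            raise ConfigurationError(f"atom {k} ({a.atom_name}) lacks parameters")
    ids, atom_pos = _residue_table(traj, include_ligand)
    n_res = len(ids)
    iu, ju, eps_ij, sig_ij, qq = _energy_terms(traj, include_ligand)
    pi, pj = atom_pos[iu], atom_pos[ju]
    valid = (pi >= 0) & (pj >= 0)
    iu, ju, pi, pj = iu[valid], ju[valid], pi[valid], pj[valid]
    eps_ij, sig_ij, qq = eps_ij[valid], sig_ij[valid], qq[valid]

    lj_sum = np.zeros((n_res, n_res))
    cl_sum = np.zeros((n_res, n_res))
    flat = pi * n_res + pj
    for frame in traj.frames:
        d = frame.coordinates[ju] - frame.coordinates[iu]
        r = np.sqrt(np.einsum("ij,ij->i", d, d))
        sr6 = (sig_ij / r) ** 6
        lj = 4.0 * eps_ij * (sr6 ** 2 - sr6)
        cl = qq / r
        lj_sum += np.bincount(flat, weights=lj, minlength=n_res * n_res).reshape(n_res, n_res)
        cl_sum += np.bincount(flat, weights=cl, minlength=n_res * n_res).reshape(n_res, n_res)
    lj_m = (lj_sum + lj_sum.T) / traj.n_frames
    cl_m = (cl_sum + cl_sum.T) / traj.n_frames
    return (
        pd.DataFrame(lj_m, index=ids, columns=ids),
        pd.DataFrame(cl_m, index=ids, columns=ids),
    )


def hbond_occupancy(
    traj: Trajectory,
    donors: Sequence[tuple[int, int | None]],
    acceptors: Iterable[int],
    crit: HBondCriterion = HBondCriterion(),
) -> pd.DataFrame:
    """Residue-pair hydrogen-bond occupancy (% of frames).

    ``donors`` is a sequence of (donor atom index, attached hydrogen atom
    index) pairs; a donor without a hydrogen is a configuration error.
    A pair is bonded in a frame when the donor-acceptor distance is within
    the cutoff and the H-D...A angle (at the donor) is within the angular
    cutoff.  Same-residue donor/acceptor pairs are ignored.
    """
    donors = list(donors)
    acceptors = np.array(sorted(set(int(a) for a in acceptors)), dtype=int)
    for d_idx, h_idx in donors:
        if h_idx is None:
            name = traj.topology[d_idx].atom_name
            raise ConfigurationError(f"donor atom {d_idx} ({name}) has no hydrogen")
    if not donors or acceptors.size == 0:
        raise ConfigurationError("need at least one donor and one acceptor")

    ids, _ = _residue_table(traj, include_ligand=True)
    pos = {int(r): p for p, r in enumerate(ids)}
    n_res = len(ids)
    res_of = np.array([a.residue_index for a in traj.topology])

    d_idx = np.array([d for d, _ in donors], dtype=int)
    h_idx = np.array([h for _, h in donors], dtype=int)
    cos_cut = np.cos(np.radians(crit.angle_cutoff))
    cut2 = crit.donor_acceptor_cutoff ** 2

    counts = np.zeros((n_res, n_res))
    for frame in traj.frames:
        xyz = frame.coordinates
        da = xyz[acceptors][None, :, :] - xyz[d_idx][:, None, :]    # (D, A, 3)
        da2 = np.einsum("dak,dak->da", da, da)
        dh = xyz[h_idx] - xyz[d_idx]                                # (D, 3)
        dh /= np.linalg.norm(dh, axis=1, keepdims=True)
        cosang = np.einsum("dk,dak->da", dh, da) / np.sqrt(np.maximum(da2, 1e-12))
        bonded = (da2 <= cut2) & (cosang >= cos_cut)
        bonded &= res_of[d_idx][:, None] != res_of[acceptors][None, :]
        hit = np.zeros((n_res, n_res), dtype=bool)
        dd, aa = np.nonzero(bonded)
        for di, ai in zip(dd, aa):
            hit[pos[int(res_of[d_idx[di]])], pos[int(res_of[acceptors[ai]])]] = True
        counts += np.maximum(hit, hit.T)
    occ = 100.0 * counts / traj.n_frames
    return pd.DataFrame(occ, index=ids, columns=ids)


def peptide_ligand_profile(
    traj: Trajectory,
    donors: Sequence[tuple[int, int | None]] = (),
    acceptors: Iterable[int] = (),
    hbond_crit: HBondCriterion = HBondCriterion(),
) -> pd.DataFrame:
    """Per-residue LJ, Coulomb, and H-bond occupancy against the ligand.

    Restricts the energy sums to peptide-residue x ligand atom pairs, so
    the per-residue entries partition the total peptide-ligand non-bonded
    energy exactly.  H-bond occupancy is reported only when donor/acceptor
    sets are provided (and only pairs that straddle the peptide/ligand
    divide are counted); otherwise the column is zero.
    """
    if not traj.has_ligand:
        raise ConfigurationError("trajectory has no ligand atoms")
    ids = traj.residue_ids
    pos = {int(r): p for p, r in enumerate(ids)}
    n_res = len(ids)
    role = np.array([a.role for a in traj.topology])

    iu, ju, eps_ij, sig_ij, qq = _energy_terms(traj, include_ligand=True)
    cross = role[iu] != role[ju]
    iu, ju = iu[cross], ju[cross]
    eps_ij, sig_ij, qq = eps_ij[cross], sig_ij[cross], qq[cross]
    # the peptide-side residue of each cross pair
    res_of = np.array([a.residue_index for a in traj.topology])
    pep_res = np.where(role[iu] == "peptide", res_of[iu], res_of[ju])
    bin_idx = np.array([pos[int(r)] for r in pep_res])

    lj_sum = np.zeros(n_res)
    cl_sum = np.zeros(n_res)
    for frame in traj.frames:
        d = frame.coordinates[ju] - frame.coordinates[iu]
        r = np.sqrt(np.einsum("ij,ij->i", d, d))
        sr6 = (sig_ij / r) ** 6
        lj_sum += np.bincount(bin_idx, weights=4.0 * eps_ij * (sr6 ** 2 - sr6),
                              minlength=n_res)
        cl_sum += np.bincount(bin_idx, weights=qq / r, minlength=n_res)

    hb = np.zeros(n_res)
    donors = list(donors)
    acceptors = list(acceptors)
    if donors and acceptors:
        occ = hbond_occupancy(traj, donors, acceptors, hbond_crit)
        lig_ids = sorted({traj.topology[i].residue_index for i in traj.ligand_indices})
        for r in ids:
            hb[pos[int(r)]] = max(
                (float(occ.loc[r, lr]) for lr in lig_ids if lr in occ.columns),
                default=0.0,
            )
    return pd.DataFrame({
        "residue": ids,
        "lj": lj_sum / traj.n_frames,
        "coulomb": cl_sum / traj.n_frames,
        "hbond_pct": hb,
    }).set_index("residue")
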