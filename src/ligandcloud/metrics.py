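"""Chain dimensions and dihedral-based secondary-structure propensities.

Two complementary measures of how disordered an ensemble is:

* the radius-of-gyration distribution, compared against empirical
  scaling laws for denatured (random-coil) and natively folded chains --
  a 40-residue random coil is expected near 18.5 A, so an ensemble mean
  around 10 A signals substantial collapse;
* per-residue secondary-structure propensities from backbone (phi, psi)
  dihedrals classified into mesostate windows (helix, extended/sheet,
  polyproline II, coil).  This is a Ramachandran-window approximation,
  not a hydrogen-bond-pattern assignment: the windows are documented and
  configurable so users can recalibrate against their reference tool.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core import Trajectory

__all__ = [
    "ScalingLaw",
    "COIL_LAW",
    "NATIVE_LAW",
    "SSAssignment",
    "radius_of_gyration",
    "rg_distribution",
    "RgDistribution",
    "expected_rg",
    "dihedral",
    "assign_secondary_structure",
    "ss_content_and_propensity",
    "SS_WINDOWS",
]


@dataclass(frozen=True)
class ScalingLaw:
    """Empirical power law Rg = prefactor * N^exponent (A)."""

    prefactor: float
    exponent: float
    regime: str

    def __post_init__(self) -> None:
        if self.prefactor <= 0:
            raise ValueError("prefactor must be positive")
        if not 0 < self.exponent < 1:
            raise ValueError("exponent must be in (0, 1)")


#: Denatured-state (random-coil) scaling: 2.02 * N^0.6 A.  At N = 40 this
#: gives the expected coil dimension of 18.5 A.
COIL_LAW = ScalingLaw(2.02, 0.6, "coil")

#: Natively folded globular scaling (configurable; no printed anchor).
NATIVE_LAW = ScalingLaw(2.2, 0.38, "native")


def expected_rg(n_residues: int, law: ScalingLaw = COIL_LAW) -> float:
    """Expected radius of gyration (A, one decimal) for an N-residue chain."""
    if n_residues < 1:
        raise ValueError("n_residues must be >= 1")
    return round(law.prefactor * n_residues ** law.exponent, 1)


def radius_of_gyration(
    coords: np.ndarray,
    masses: np.ndarray | None = None,
    subset: np.ndarray | None = None,
    mass_weighted: bool = True,
) -> float:
    """Radius of gyration (A) of a coordinate set.

    sqrt( sum m_i |r_i - r_com|^2 / sum m_i ); with ``mass_weighted``
    False (or no masses) every particle counts equally.
    """
    coords = np.asarray(coords, dtype=float)
    if subset is not None:
        subset = np.asarray(subset, dtype=int)
        if subset.size == 0:
            raise ValueError("subset must be non-empty")
        coords = coords[subset]
        if masses is not None:
            masses = np.asarray(masses, dtype=float)[subset]
    if coords.shape[0] == 0:
        raise ValueError("no atoms selected")
    if not mass_weighted or masses is None:
        m = np.ones(coords.shape[0])
    else:
        m = np.asarray(masses, dtype=float)
    com = (m[:, None] * coords).sum(axis=0) / m.sum()
    sq = np.einsum("ij,ij->i", coords - com, coords - com)
    return float(np.sqrt((m * sq).sum() / m.sum()))


@dataclass
class RgDistribution:
    """Per-frame Rg series with summary statistics and a histogram."""

    series: np.ndarray
    mean: float
    sd: float
    bin_centers: np.ndarray
    density: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"bin_center": self.bin_centers, "density": self.density})


def rg_distribution(
    traj: Trajectory,
    subset: np.ndarray | None = None,
    mass_weighted: bool = True,
    bins: int = 30,
) -> RgDistribution:
    """Radius-of-gyration distribution over the trajectory.

    Defaults to the mass-weighted Rg over peptide atoms.  The standard
    deviation is the population value (ddof 0) over frames.
    """
    if traj.n_frames < 2:
        raise ValueError("need at least 2 frames")
    if subset is None:
        subset = traj.peptide_indices
    masses = traj.masses()
    series = np.array([
        radius_of_gyration(fr.coordinates, masses, subset, mass_weighted)
        for fr in traj.frames
    ])
    density, edges = np.histogram(series, bins=bins, density=True)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return RgDistribution(series, float(series.mean()), float(series.std()),
                          centers, density)


# ---------------------------------------------------------------------------
# Secondary structure from dihedral mesostates
# ---------------------------------------------------------------------------

#: (phi, psi) windows in degrees.  Precedence on overlap: H, then P, then E.
SS_WINDOWS: Mapping[str, tuple[tuple[float, float], tuple[float, float]]] = {
    "H": ((-100.0, -30.0), (-80.0, -5.0)),
    "P": ((-110.0, -50.0), (120.0, 180.0)),
    "E": ((-180.0, -90.0), (90.0, 180.0)),
}

#: DSSP-like minimum run length for a helix label.
MIN_HELIX_RUN = 3


def dihedral(p0: np.ndarray, p1: np.ndarray, p2: np.ndarray, p3: np.ndarray) -> float:
    """Signed dihedral angle (degrees) of four points about the p1-p2 axis."""
    b0 = p1 - p0
    b1 = p2 - p1
    b2 = p3 - p2
    n1 = np.cross(b0, b1)
    n2 = np.cross(b1, b2)
    m1 = np.cross(n1, b1 / np.linalg.norm(b1))
    x = np.dot(n1, n2)
    y = np.dot(m1, n2)
    return float(np.degrees(np.arctan2(y, x)))


@dataclass
class SSAssignment:
    """Per-frame, per-residue labels in {H, E, P, C}."""

    labels: np.ndarray          # (n_frames, n_residues) of 'H'/'E'/'P'/'C'
    residue_ids: np.ndarray

    @property
    def n_frames(self) -> int:
        return self.labels.shape[0]


def _backbone_dihedrals_atomistic(traj: Trajectory) -> tuple[np.ndarray, np.ndarray]:
    """(phi, psi) per frame/residue from N-CA-C backbones; NaN at termini."""
    ids = traj.residue_ids
    n_res = len(ids)
    by_res = {}
    for i, a in enumerate(traj.topology):
        if a.role == "peptide" and a.atom_name in ("N", "CA", "C"):
            by_res.setdefault(a.residue_index, {})[a.atom_name] = i
    idx = {name: np.array([by_res[r][name] for r in ids]) for name in ("N", "CA", "C")}
    phi = np.full((traj.n_frames, n_res), np.nan)
    psi = np.full((traj.n_frames, n_res), np.nan)
    for f, frame in enumerate(traj.frames):
        x = frame.coordinates
        for k in range(n_res):
            if k > 0:
                phi[f, k] = dihedral(x[idx["C"][k - 1]], x[idx["N"][k]],
                                     x[idx["CA"][k]], x[idx["C"][k]])
            if k < n_res - 1:
                psi[f, k] = dihedral(x[idx["N"][k]], x[idx["CA"][k]],
                                     x[idx["C"][k]], x[idx["N"][k + 1]])
    return phi, psi


def _backbone_dihedrals_beads(traj: Trajectory) -> tuple[np.ndarray, np.ndarray]:
    """Virtual dihedrals over bead quadruplets for one-bead-per-residue chains.

    phi_i uses beads (i-2, i-1, i, i+1), psi_i uses (i-1, i, i+1, i+2);
    both are NaN where the quadruplet does not exist.
    """
    ids = traj.residue_ids
    n_res = len(ids)
    bead = np.array([traj.residue_atom_indices(r)[0] for r in ids])
    phi = np.full((traj.n_frames, n_res), np.nan)
    psi = np.full((traj.n_frames, n_res), np.nan)
    for f, frame in enumerate(traj.frames):
        x = frame.coordinates
        for k in range(n_res):
            if k >= 2 and k + 1 < n_res:
                phi[f, k] = dihedral(x[bead[k - 2]], x[bead[k - 1]],
                                     x[bead[k]], x[bead[k + 1]])
            if k >= 1 and k + 2 < n_res:
                psi[f, k] = dihedral(x[bead[k - 1]], x[bead[k]],
                                     x[bead[k + 1]], x[bead[k + 2]])
    return phi, psi


def _in_window(val: np.ndarray, lo: float, hi: float) -> np.ndarray:
    return (val >= lo) & (val <= hi)


def assign_secondary_structure(
    traj: Trajectory,
    windows: Mapping[str, tuple[tuple[float, float], tuple[float, float]]] = SS_WINDOWS,
    min_helix_run: int = MIN_HELIX_RUN,
) -> SSAssignment:
    """Classify each residue of each frame into H / E / P / C mesostates.

    Atomistic backbones (N, CA, C atoms present) use true (phi, psi);
    one-bead chains fall back to virtual dihedrals over bead quadruplets.
    Residues lacking either dihedral are coil.  Helix labels additionally
    require a run of at least ``min_helix_run`` consecutive helical
    residues; shorter runs revert to coil.
    """
    names = {a.atom_name for a in traj.topology if a.role == "peptide"}
    if {"N", "CA", "C"} <= names:
        phi, psi = _backbone_dihedrals_atomistic(traj)
    else:
        phi, psi = _backbone_dihedrals_beads(traj)

    n_frames, n_res = phi.shape
    labels = np.full((n_frames, n_res), "C", dtype="<U1")
    ok = np.isfinite(phi) & np.isfinite(psi)
    for code in ("E", "P", "H"):    # later assignments take precedence
        (plo, phi_hi), (slo, shi) = windows[code]
        mask = ok & _in_window(phi, plo, phi_hi) & _in_window(psi, slo, shi)
        labels[mask] = code

    # enforce the minimum helix run length per frame
    if min_helix_run > 1:
        for f in range(n_frames):
            row = labels[f]
            k = 0
            while k < n_res:
                if row[k] == "H":
                    j = k
                    while j < n_res and row[j] == "H":
                        j += 1
                    if j - k < min_helix_run:
                        row[k:j] = "C"
                    k = j
                else:
                    k += 1
    return SSAssignment(labels, traj.residue_ids)


def ss_content_and_propensity(assign: SSAssignment) -> tuple[pd.DataFrame, pd.Series]:
    """Overall class content (mean +/- sd over frames) and helix propensity.

    Content: per-frame fraction of residues in each class, averaged over
    frames (class fractions sum to one in every frame).  Propensity: per
    residue, the fraction of frames labelled H.
    """
    labels = assign.labels
    n_frames, n_res = labels.shape
    rows = []
    for code in ("H", "E", "P", "C"):
        frac = (labels == code).mean(axis=1)
        rows.append((code, 100.0 * frac.mean(), 100.0 * frac.std()))
    content = pd.DataFrame(rows, columns=["class", "mean_pct", "sd_pct"])
    propensity = pd.Series(
        (labels == "H").mean(axis=0), index=assign.residue_ids, name="helix_propensity"
    )
    propensity.index.name = "residue"
    return content, propensity
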