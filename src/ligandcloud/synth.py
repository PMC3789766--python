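"""Synthetic trajectory generators with known ground truth.

Real ensembles of disordered peptides come from microsecond-scale molecular
dynamics; at desk scale this module stands in for them with two generators
whose ground truth is known by construction:

* :func:`simulate_cg` -- a one-bead-per-residue Langevin (BAOAB) simulation
  of a flexible chain plus a small ligand, where per-residue "stickiness"
  well depths define designed binding sites that the dSASA stage should
  recover.
* :func:`sample_conformer_mixture` -- draws frames from a weighted mixture
  of rigid templates plus isotropic Gaussian noise, giving clustering a
  known number of basins and known populations.

All randomness flows through a single integer seed per generator call; no
global RNG state is touched.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .core import AtomRecord, Frame, Trajectory
from .errors import IntegrationError

__all__ = [
    "ChainSpec",
    "LigandSpec",
    "SimulationParams",
    "ConformerMixtureSpec",
    "simulate_cg",
    "sample_conformer_mixture",
    "ground_truth_sites",
    "cg_topology",
    "peptide_backbone",
]

#: Boltzmann constant in kcal/mol/K.
KB = 0.0019872

#: Conversion from (kcal/mol/A)/amu to acceleration in A/ps^2.
ACCEL = 418.4

#: Depth of the purely repulsive (WCA) excluded-volume term, kcal/mol.
WCA_EPSILON = 1.0

#: Equilibrium pseudo-bond angle of the bead chain, radians (~120 deg);
#: loose enough that the chain stays flexible at moderate angle_k.
THETA0 = 2.0944


@dataclass
class ChainSpec:
    """A coarse-grained heteropolymer: one bead per residue.

    ``stickiness`` holds the attraction well depth (kcal/mol) between each
    residue bead and the ligand beads; a designed binding site is simply a
    run of residues with larger well depth than the background.
    """

    n_residues: int
    bond_length: float = 3.8
    bond_k: float = 50.0
    angle_k: float = 2.0
    excluded_volume_sigma: float = 4.0
    stickiness: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.n_residues < 3:
            raise ValueError("need at least 3 residues")
        for name in ("bond_k", "angle_k"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.bond_length <= 0 or self.excluded_volume_sigma <= 0:
            raise ValueError("lengths must be positive")
        if self.stickiness is None:
            self.stickiness = np.zeros(self.n_residues)
        self.stickiness = np.asarray(self.stickiness, dtype=float)
        if self.stickiness.shape != (self.n_residues,):
            raise ValueError("stickiness must have one value per residue")
        if np.any(self.stickiness < 0):
            raise ValueError("stickiness must be non-negative")


@dataclass
class LigandSpec:
    """A small rigid-ish ligand of 1-3 beads (bonded by stiff springs)."""

    n_beads: int = 1
    bead_radius: float = 2.5
    rigid: bool = True

    def __post_init__(self) -> None:
        if self.n_beads < 1:
            raise ValueError("ligand needs at least one bead")
        if self.bead_radius <= 0:
            raise ValueError("bead_radius must be positive")


@dataclass
class SimulationParams:
    """Langevin integration settings.

    The defaults (dt 0.01 ps, friction 1/ps, 300 K) are chosen for numerical
    stability of the bead-spring model, not for physical fidelity to any
    particular force field.  ``box_size`` is the edge of a cubic box with
    reflecting walls, so analyses never see periodic images.
    """

    temperature: float = 300.0
    friction: float = 1.0
    dt: float = 0.01
    n_steps: int = 100_000
    save_interval: int = 100
    seed: int = 0
    box_size: float = 60.0

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")
        if self.save_interval < 1:
            raise ValueError("save_interval must be >= 1")
        if self.friction < 0:
            raise ValueError("friction must be non-negative")
        if self.box_size <= 0:
            raise ValueError("box_size must be positive")


@dataclass
class ConformerMixtureSpec:
    """Frames drawn from rigid templates by weight, plus Gaussian noise."""

    templates: Sequence[np.ndarray]
    weights: Sequence[float]
    noise_sigma: float = 0.5
    seed: int = 0
    topology: Sequence[AtomRecord] | None = None

    def __post_init__(self) -> None:
        self.templates = [np.asarray(t, dtype=float) for t in self.templates]
        if not self.templates:
            raise ValueError("need at least one template")
        shape = self.templates[0].shape
        if any(t.shape != shape for t in self.templates):
            raise ValueError("all templates must share the same atom count")
        w = np.asarray(self.weights, dtype=float)
        if w.shape != (len(self.templates),):
            raise ValueError("one weight per template required")
        if np.any(w < 0) or not np.isclose(w.sum(), 1.0, atol=1e-9):
            raise ValueError("weights must be non-negative and sum to 1")
        self.weights = w
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be non-negative")


# ---------------------------------------------------------------------------
# Topology construction
# ---------------------------------------------------------------------------

_RESIDUE_MASS = 110.0   # average amino-acid residue mass, amu
_LIGAND_BEAD_MASS = 150.0


def cg_topology(chain: ChainSpec, ligand: LigandSpec | None = None,
                charges: np.ndarray | None = None) -> list[AtomRecord]:
    """Atom records for the bead-spring system.

    Bead van der Waals radii are half the excluded-volume sigma, so the
    SASA stage sees spheres that touch exactly where the repulsion kicks
    in.  ``charges`` optionally assigns per-residue charges (ligand beads
    stay neutral) for electrostatics tests.
    """
    records = []
    for i in range(chain.n_residues):
        q = float(charges[i]) if charges is not None else 0.0
        records.append(
            AtomRecord(
                atom_name="CA",
                residue_index=i + 1,
                residue_name="ALA",
                role="peptide",
                radius=chain.excluded_volume_sigma / 2,
                charge=q,
                lj_epsilon=0.1,
                lj_sigma=chain.excluded_volume_sigma,
                mass=_RESIDUE_MASS,
            )
        )
    if ligand is not None:
        for b in range(ligand.n_beads):
            records.append(
                AtomRecord(
                    atom_name=f"L{b + 1}",
                    residue_index=chain.n_residues + 1,
                    residue_name="LIG",
                    role="ligand",
                    radius=ligand.bead_radius,
                    charge=0.0,
                    lj_epsilon=0.1,
                    lj_sigma=2 * ligand.bead_radius,
                    mass=_LIGAND_BEAD_MASS,
                )
            )
    return records


# ---------------------------------------------------------------------------
# Forces
# ---------------------------------------------------------------------------

class _ForceField:
    """Precomputed pair/angle lists and vectorized force evaluation.

    Potential terms: harmonic bonds along the chain (and between ligand
    beads), harmonic angles on chain triples, WCA excluded volume between
    all non-bonded pairs, and for peptide-ligand pairs with positive
    stickiness a truncated-and-shifted Lennard-Jones well of depth eps_i
    cut at 2.5 sigma.
    """

    def __init__(self, chain: ChainSpec, ligand: LigandSpec | None):
        n = chain.n_residues
        m = ligand.n_beads if ligand is not None else 0
        self.n_total = n + m
        self.n_chain = n

        # Bonds: chain backbone, then stiff ligand bonds.
        bi, bj, b0, bk = [], [], [], []
        for i in range(n - 1):
            bi.append(i); bj.append(i + 1)
            b0.append(chain.bond_length); bk.append(chain.bond_k)
        if ligand is not None and ligand.n_beads > 1:
            lig_k = 200.0 if ligand.rigid else chain.bond_k
            for b in range(m - 1):
                bi.append(n + b); bj.append(n + b + 1)
                b0.append(2 * ligand.bead_radius); bk.append(lig_k)
        self.bond_i = np.array(bi, dtype=int)
        self.bond_j = np.array(bj, dtype=int)
        self.bond_b0 = np.array(b0)
        self.bond_k = np.array(bk)

        # Angles on consecutive chain triples.
        self.angle_idx = np.arange(n - 2)
        self.angle_k = chain.angle_k

        # Non-bonded pair list: chain pairs |i-j| >= 2, ligand-ligand
        # non-bonded, and every peptide-ligand pair.
        pi, pj, sig, att = [], [], [], []
        s_pp = chain.excluded_volume_sigma
        for i in range(n):
            for j in range(i + 2, n):
                pi.append(i); pj.append(j); sig.append(s_pp); att.append(0.0)
        if ligand is not None:
            s_pl = 0.5 * (s_pp + 2 * ligand.bead_radius)
            for i in range(n):
                for b in range(m):
                    pi.append(i); pj.append(n + b)
                    sig.append(s_pl); att.append(float(chain.stickiness[i]))
            s_ll = 2 * ligand.bead_radius
            for a in range(m):
                for b in range(a + 2, m):
                    pi.append(n + a); pj.append(n + b)
                    sig.append(s_ll); att.append(0.0)
        self.pair_i = np.array(pi, dtype=int)
        self.pair_j = np.array(pj, dtype=int)
        self.pair_sigma = np.array(sig)
        self.pair_eps_att = np.array(att)
        self.pair_is_att = self.pair_eps_att > 0
        # WCA repulsion: cut at the LJ minimum; attractive wells: 2.5 sigma.
        self.pair_rc = np.where(
            self.pair_is_att, 2.5 * self.pair_sigma, 2 ** (1 / 6) * self.pair_sigma
        )
        self.pair_eps = np.where(self.pair_is_att, self.pair_eps_att, WCA_EPSILON)
        # Energy shift making U(rc) = 0.
        sr6 = (self.pair_sigma / self.pair_rc) ** 6
        self.pair_shift = 4 * self.pair_eps * (sr6 ** 2 - sr6)

    def forces(self, x: np.ndarray) -> np.ndarray:
        f = np.zeros_like(x)

        # Bonds
        d = x[self.bond_j] - x[self.bond_i]
        r = np.linalg.norm(d, axis=1)
        fmag = self.bond_k * (r - self.bond_b0) / np.maximum(r, 1e-12)
        fb = fmag[:, None] * d
        np.add.at(f, self.bond_i, fb)
        np.add.at(f, self.bond_j, -fb)

        # Angles
        if self.angle_k > 0 and len(self.angle_idx) > 0:
            i = self.angle_idx
            u = x[i] - x[i + 1]
            v = x[i + 2] - x[i + 1]
            nu = np.linalg.norm(u, axis=1)
            nv = np.linalg.norm(v, axis=1)
            hu = u / nu[:, None]
            hv = v / nv[:, None]
            cos = np.clip(np.einsum("ij,ij->i", hu, hv), -1.0, 1.0)
            sin = np.sqrt(np.maximum(1 - cos ** 2, 1e-12))
            theta = np.arccos(cos)
            coef = -self.angle_k * (theta - THETA0)
            dth_di = (cos[:, None] * hu - hv) / (nu * sin)[:, None]
            dth_dk = (cos[:, None] * hv - hu) / (nv * sin)[:, None]
            fi = coef[:, None] * dth_di
            fk = coef[:, None] * dth_dk
            np.add.at(f, i, fi)
            np.add.at(f, i + 2, fk)
            np.add.at(f, i + 1, -(fi + fk))

        # Non-bonded
        d = x[self.pair_j] - x[self.pair_i]
        r2 = np.einsum("ij,ij->i", d, d)
        rc2 = self.pair_rc ** 2
        act = r2 < rc2
        if np.any(act):
            r2a = np.maximum(r2[act], 1e-8)
            sr2 = self.pair_sigma[act] ** 2 / r2a
            sr6 = sr2 ** 3
            # dU/dr * (1/r): 24 eps (sr6 - 2 sr12) / r^2
            fmag = 24 * self.pair_eps[act] * (2 * sr6 ** 2 - sr6) / r2a
            fp = fmag[:, None] * d[act]
            np.add.at(f, self.pair_i[act], -fp)
            np.add.at(f, self.pair_j[act], fp)
        return f

    def energy(self, x: np.ndarray) -> float:
        d = x[self.bond_j] - x[self.bond_i]
        r = np.linalg.norm(d, axis=1)
        e = float(np.sum(0.5 * self.bond_k * (r - self.bond_b0) ** 2))
        if self.angle_k > 0 and len(self.angle_idx) > 0:
            i = self.angle_idx
            u = x[i] - x[i + 1]
            v = x[i + 2] - x[i + 1]
            cos = np.einsum("ij,ij->i", u, v) / (
                np.linalg.norm(u, axis=1) * np.linalg.norm(v, axis=1)
            )
            theta = np.arccos(np.clip(cos, -1, 1))
            e += float(np.sum(0.5 * self.angle_k * (theta - THETA0) ** 2))
        d = x[self.pair_j] - x[self.pair_i]
        r2 = np.einsum("ij,ij->i", d, d)
        act = r2 < self.pair_rc ** 2
        sr6 = (self.pair_sigma[act] ** 2 / r2[act]) ** 3
        e += float(
            np.sum(4 * self.pair_eps[act] * (sr6 ** 2 - sr6) - self.pair_shift[act])
        )
        return e


def _initial_positions(chain: ChainSpec, ligand: LigandSpec | None,
                       box: float, rng: np.random.Generator) -> np.ndarray:
    """Self-avoiding random-walk chain near the box centre, ligand random."""
    n = chain.n_residues
    center = np.full(3, box / 2)
    pos = [center.copy()]
    for _ in range(n - 1):
        for _attempt in range(200):
            step = rng.normal(size=3)
            step *= chain.bond_length / np.linalg.norm(step)
            cand = pos[-1] + step
            dists = np.linalg.norm(np.array(pos) - cand, axis=1)
            if np.all(dists[:-1] > 0.8 * chain.excluded_volume_sigma) if len(dists) > 1 else True:
                break
        pos.append(cand)
    x = np.array(pos)
    # recentre the chain and keep it inside the walls
    x += center - x.mean(axis=0)
    x = np.clip(x, 1.0, box - 1.0)
    if ligand is not None:
        lig0 = rng.uniform(low=3.0, high=box - 3.0, size=3)
        lig = [lig0 + np.array([2.0 * ligand.bead_radius * b, 0, 0])
               for b in range(ligand.n_beads)]
        x = np.vstack([x, np.clip(np.array(lig), 1.0, box - 1.0)])
    return x


def simulate_cg(chain: ChainSpec, ligand: LigandSpec | None,
                params: SimulationParams) -> Trajectory:
    """Run a BAOAB Langevin simulation of the bead chain plus ligand.

    Frames (including the initial configuration at t = 0) are stored every
    ``params.save_interval`` steps, giving a frame spacing of
    ``save_interval * dt`` ps.  The run is fully reproducible from
    ``params.seed``.

    Raises
    ------
    IntegrationError
        If coordinates become non-finite, reporting the failing step.
    """
    rng = np.random.default_rng(params.seed)
    ff = _ForceField(chain, ligand)
    topology = cg_topology(chain, ligand)
    masses = np.array([a.mass for a in topology])[:, None]

    x = _initial_positions(chain, ligand, params.box_size, rng)
    kbt = KB * params.temperature
    v = rng.normal(size=x.shape) * np.sqrt(kbt * ACCEL / masses)

    dt = params.dt
    c1 = np.exp(-params.friction * dt)
    c2 = np.sqrt(kbt * ACCEL / masses * (1 - c1 ** 2))

    def reflect(x: np.ndarray, v: np.ndarray) -> None:
        box = params.box_size
        low = x < 0
        x[low] = -x[low]
        v[low] = -v[low]
        high = x > box
        x[high] = 2 * box - x[high]
        v[high] = -v[high]

    frames = [Frame(x.copy(), 0.0)]
    a = ff.forces(x) / masses * ACCEL
    for step in range(1, params.n_steps + 1):
        v += 0.5 * dt * a
        x += 0.5 * dt * v
        reflect(x, v)
        v = c1 * v + c2 * rng.normal(size=x.shape)
        x += 0.5 * dt * v
        reflect(x, v)
        a = ff.forces(x) / masses * ACCEL
        v += 0.5 * dt * a
        if not np.all(np.isfinite(x)):
            raise IntegrationError(f"non-finite coordinates at step {step}")
        if step % params.save_interval == 0:
            frames.append(Frame(x.copy(), step * dt))

    return Trajectory(topology, frames, time_spacing=params.save_interval * dt)


def sample_conformer_mixture(spec: ConformerMixtureSpec, n_frames: int) -> Trajectory:
    """Draw frames from the weighted template mixture.

    Each frame is one template chosen by weight plus isotropic Gaussian
    displacement of width ``noise_sigma`` on every coordinate.  The draw
    sequence is reproducible from ``spec.seed``.  Frame times are spaced
    20 ps apart, mirroring a typical snapshot cadence; the mixture has no
    intrinsic kinetics.
    """
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    rng = np.random.default_rng(spec.seed)
    n_atoms = spec.templates[0].shape[0]
    choices = rng.choice(len(spec.templates), size=n_frames, p=spec.weights)
    frames = []
    for k, c in enumerate(choices):
        coords = spec.templates[c] + rng.normal(scale=spec.noise_sigma, size=(n_atoms, 3)) \
            if spec.noise_sigma > 0 else spec.templates[c].copy()
        frames.append(Frame(coords, k * 20.0))
    if spec.topology is not None:
        topology = list(spec.topology)
    else:
        topology = [
            AtomRecord("CA", i + 1, "ALA", "peptide", radius=2.0,
                       lj_sigma=4.0, mass=_RESIDUE_MASS)
            for i in range(n_atoms)
        ]
    traj = Trajectory(topology, frames, time_spacing=20.0)
    traj.template_choices = np.asarray(choices)  # ground truth for tests
    return traj


def ground_truth_sites(chain: ChainSpec, threshold: float) -> set[int]:
    """Residues (1-based) whose stickiness is at least ``threshold``."""
    return {i + 1 for i in range(chain.n_residues)
            if chain.stickiness[i] >= threshold}


# ---------------------------------------------------------------------------
# Backbone construction from dihedrals (template factory)
# ---------------------------------------------------------------------------

_B_N_CA, _B_CA_C, _B_C_N = 1.458, 1.525, 1.329
_A_N_CA_C, _A_CA_C_N, _A_C_N_CA = np.radians([111.2, 116.6, 121.7])


def _place_atom(a: np.ndarray, b: np.ndarray, c: np.ndarray,
                bond: float, angle: float, torsion: float) -> np.ndarray:
    """Natural-extension placement of atom D given A-B-C internal coords."""
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array([
        -bond * np.cos(angle),
        bond * np.sin(angle) * np.cos(torsion),
        -bond * np.sin(angle) * np.sin(torsion),
    ])
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def peptide_backbone(phi: Sequence[float], psi: Sequence[float],
                     start_number: int = 1) -> tuple[list[AtomRecord], np.ndarray]:
    """Build an N-CA-C backbone with the given dihedral angles (degrees).

    Uses ideal bond lengths and angles and a planar trans peptide bond
    (omega 180 deg).  The first residue's phi and the last residue's psi
    are not defined by the construction and are ignored.  Handy both as a
    secondary-structure test fixture (e.g. an ideal alpha helix at
    phi = -57, psi = -47) and as a rigid template for the conformer
    mixture generator.
    """
    phi = np.radians(np.asarray(phi, dtype=float))
    psi = np.radians(np.asarray(psi, dtype=float))
    if phi.shape != psi.shape:
        raise ValueError("phi and psi must have equal length")
    n = len(phi)
    if n < 2:
        raise ValueError("need at least two residues")

    coords = np.zeros((3 * n, 3))
    # residue 1
    coords[0] = [0.0, 0.0, 0.0]                       # N1
    coords[1] = [_B_N_CA, 0.0, 0.0]                   # CA1
    coords[2] = coords[1] + _B_CA_C * np.array(
        [-np.cos(_A_N_CA_C), np.sin(_A_N_CA_C), 0.0]
    )                                                 # C1
    for i in range(1, n):
        n_prev, ca_prev, c_prev = coords[3 * i - 3], coords[3 * i - 2], coords[3 * i - 1]
        n_i = _place_atom(n_prev, ca_prev, c_prev, _B_C_N, _A_CA_C_N, psi[i - 1])
        ca_i = _place_atom(ca_prev, c_prev, n_i, _B_N_CA, _A_C_N_CA, np.pi)
        c_i = _place_atom(c_prev, n_i, ca_i, _B_CA_C, _A_N_CA_C, phi[i])
        coords[3 * i:3 * i + 3] = [n_i, ca_i, c_i]

    topology = []
    for i in range(n):
        for name, mass, radius in (("N", 14.007, 1.55), ("CA", 12.011, 1.70),
                                   ("C", 12.011, 1.70)):
            topology.append(
                AtomRecord(name, start_number + i, "ALA", "peptide",
                           radius=radius, mass=mass,
                           lj_sigma=2 * radius * 2 ** (-1 / 6))
            )
    return topology, coords
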