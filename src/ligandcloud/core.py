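"""Core data model: atoms, frames, trajectories, sequences, and file I/O.

Units are fixed throughout the package: coordinates in angstrom (A), times
in picoseconds (ps), energies in kcal/mol, charges in elementary charges,
masses in atomic mass units.  Converters, where needed, live at the I/O
boundary only.

Residue numbering is 1-based and preserved from the input, so a c-Myc
fragment numbered 370-409 keeps that numbering in every report.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .errors import ConfigurationError, PDBParseError, TopologyParseError

__all__ = [
    "AtomRecord",
    "Frame",
    "Trajectory",
    "SequenceRecord",
    "MYC_370_409",
    "MYC_410_437",
    "CHARGED_RESIDUES",
    "count_charged_residues",
    "read_pdb_models",
    "write_pdb_models",
    "read_topology",
    "write_topology",
]

#: Van der Waals radii (A) keyed by element, used when a PDB file is read
#: without an accompanying topology table.
ELEMENT_RADII = {"H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "P": 1.80}

ELEMENT_MASSES = {"H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "S": 32.06, "P": 30.974}

_ROLES = ("peptide", "ligand")

# One- and three-letter amino-acid codes.
AA3_TO_1 = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C", "GLN": "Q",
    "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I", "LEU": "L", "LYS": "K",
    "MET": "M", "PHE": "F", "PRO": "P", "SER": "S", "THR": "T", "TRP": "W",
    "TYR": "Y", "VAL": "V",
}
AA1_TO_3 = {v: k for k, v in AA3_TO_1.items()}

#: Residues counted as charged at neutral pH.  Histidine is treated as
#: neutral: the published census of 12 charged residues out of 40 for
#: c-Myc 370-409 is only consistent with the {D, E, K, R} set.
CHARGED_RESIDUES = frozenset("DEKR")


@dataclass(frozen=True)
class AtomRecord:
    """One particle of the system: an atom, or a coarse-grained bead.

    The record carries everything the downstream stages need: the van der
    Waals ``radius`` for surface-area calculations, ``charge`` and the
    Lennard-Jones ``lj_epsilon``/``lj_sigma`` pair for non-bonded energies,
    and ``mass`` for centres of mass and gyration radii.
    """

    atom_name: str
    residue_index: int
    residue_name: str
    role: str
    radius: float
    charge: float = 0.0
    lj_epsilon: float = 0.0
    lj_sigma: float = 1.0
    mass: float = 12.0

    def __post_init__(self) -> None:
        if self.role not in _ROLES:
            raise ValueError(f"role must be one of {_ROLES}, got {self.role!r}")
        if not self.radius > 0:
            raise ValueError(f"radius must be positive, got {self.radius}")
        if not self.mass > 0:
            raise ValueError(f"mass must be positive, got {self.mass}")
        if not self.lj_sigma > 0:
            raise ValueError(f"lj_sigma must be positive, got {self.lj_sigma}")
        if self.lj_epsilon < 0:
            raise ValueError(f"lj_epsilon must be non-negative, got {self.lj_epsilon}")


@dataclass
class Frame:
    """A single snapshot: coordinates in A and a time stamp in ps."""

    coordinates: np.ndarray
    time: float

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if self.coordinates.ndim != 2 or self.coordinates.shape[1] != 3:
            raise ValueError("coordinates must have shape (n_atoms, 3)")
        if not np.all(np.isfinite(self.coordinates)):
            raise ValueError("coordinates must be finite")


class Trajectory:
    """An ordered, uniformly spaced sequence of frames over one topology.

    Parameters
    ----------
    topology
        One :class:`AtomRecord` per particle, in coordinate order.
    frames
        At least one :class:`Frame`; all frames must have the same atom
        count as the topology and strictly increasing, uniformly spaced
        times.
    time_spacing
        Spacing between consecutive frames in ps.  May be given explicitly
        or inferred from the frame times.
    """

    def __init__(
        self,
        topology: Sequence[AtomRecord],
        frames: Sequence[Frame],
        time_spacing: float | None = None,
    ) -> None:
        self.topology = list(topology)
        self.frames = list(frames)
        if len(self.frames) == 0:
            raise ValueError("a trajectory needs at least one frame")
        n_atoms = len(self.topology)
        for k, fr in enumerate(self.frames):
            if fr.coordinates.shape[0] != n_atoms:
                raise ValueError(
                    f"frame {k} has {fr.coordinates.shape[0]} atoms, "
                    f"topology has {n_atoms}"
                )
        times = np.array([fr.time for fr in self.frames])
        if len(times) > 1:
            deltas = np.diff(times)
            if np.any(deltas <= 0):
                raise ValueError("frame times must be strictly increasing")
            if not np.allclose(deltas, deltas[0], rtol=1e-9, atol=1e-9):
                raise ValueError("frame times must be uniformly spaced")
            inferred = float(deltas[0])
        else:
            inferred = float(time_spacing) if time_spacing else 1.0
        if time_spacing is not None and len(times) > 1:
            if not math.isclose(time_spacing, inferred, rel_tol=1e-9, abs_tol=1e-9):
                raise ValueError(
                    f"time_spacing {time_spacing} inconsistent with frame "
                    f"times (spacing {inferred})"
                )
        self.time_spacing = inferred

    # -- basic geometry access ------------------------------------------------

    @property
    def n_atoms(self) -> int:
        return len(self.topology)

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def times(self) -> np.ndarray:
        return np.array([fr.time for fr in self.frames])

    def coords(self) -> np.ndarray:
        """All coordinates as one (n_frames, n_atoms, 3) array."""
        return np.stack([fr.coordinates for fr in self.frames])

    # -- topology queries -----------------------------------------------------

    @property
    def peptide_indices(self) -> np.ndarray:
        return np.array([i for i, a in enumerate(self.topology) if a.role == "peptide"], dtype=int)

    @property
    def ligand_indices(self) -> np.ndarray:
        return np.array([i for i, a in enumerate(self.topology) if a.role == "ligand"], dtype=int)

    @property
    def has_ligand(self) -> bool:
        return self.ligand_indices.size > 0

    @property
    def residue_ids(self) -> np.ndarray:
        """Sorted unique residue numbers of the peptide (input numbering)."""
        return np.unique([a.residue_index for a in self.topology if a.role == "peptide"])

    def residue_atom_indices(self, residue_index: int) -> np.ndarray:
        return np.array(
            [i for i, a in enumerate(self.topology)
             if a.role == "peptide" and a.residue_index == residue_index],
            dtype=int,
        )

    def radii(self) -> np.ndarray:
        return np.array([a.radius for a in self.topology])

    def masses(self) -> np.ndarray:
        return np.array([a.mass for a in self.topology])

    def charges(self) -> np.ndarray:
        return np.array([a.charge for a in self.topology])

    def atom_indices_by_name(self, names: Iterable[str], role: str = "peptide") -> np.ndarray:
        wanted = set(names)
        return np.array(
            [i for i, a in enumerate(self.topology)
             if a.role == role and a.atom_name in wanted],
            dtype=int,
        )


@dataclass(frozen=True)
class SequenceRecord:
    """A peptide sequence with its first residue number (e.g. 370)."""

    identifier: str
    residues: str
    start_number: int = 1

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValueError("sequence must be non-empty")
        bad = set(self.residues) - set(AA1_TO_3)
        if bad:
            raise ValueError(f"non-standard residue letters: {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def residue_numbers(self) -> range:
        return range(self.start_number, self.start_number + len(self.residues))


#: The 40-residue c-Myc fragment (residues 370-409) targeted by 10074-A4.
MYC_370_409 = SequenceRecord("c-Myc_370-409", "LKRSFFALRDQIPELENNEKAPKVVILKKATAYILSVQAE", 370)

#: The 28-residue c-Myc fragment (residues 410-437) used as a negative control.
MYC_410_437 = SequenceRecord("c-Myc_410-437", "EQKLISEEDLLRKRREQLKHKLEQLRNS", 410)


def count_charged_residues(seq: SequenceRecord) -> int:
    """Count charged residues (Asp, Glu, Lys, Arg) in a sequence.

    Histidine is treated as neutral.  For c-Myc 370-409 this yields 12 of
    40 residues charged, i.e. nearly one-third of the chain.
    """
    return sum(1 for aa in seq.residues if aa in CHARGED_RESIDUES)


# ---------------------------------------------------------------------------
# Multi-model PDB I/O
# ---------------------------------------------------------------------------

def _element_of(atom_name: str) -> str:
    for ch in atom_name:
        if ch.isalpha():
            return ch.upper()
    return "C"


def _scan_model_atom_counts(path: Path) -> list[int]:
    """Count ATOM/HETATM records per MODEL block (naming mismatches)."""
    counts: list[int] = []
    current: int | None = None
    saw_model = False
    with open(path) as fh:
        for line in fh:
            rec = line[:6].strip()
            if rec == "MODEL":
                saw_model = True
                current = 0
            elif rec == "ENDMDL":
                counts.append(current or 0)
                current = None
            elif rec in ("ATOM", "HETATM"):
                if current is None:
                    if saw_model:
                        continue  # atoms outside MODEL blocks in a multi-model file
                    current = 0
                current += 1
    if current is not None:
        counts.append(current)
    return counts


def read_pdb_models(
    path: str | Path,
    chain_roles: Mapping[str, str],
    topology: Sequence[AtomRecord] | None = None,
    time_spacing: float = 20.0,
) -> Trajectory:
    """Read a multi-model PDB file into a :class:`Trajectory`.

    Each MODEL becomes one frame.  ``chain_roles`` maps chain identifiers to
    ``"peptide"`` or ``"ligand"``; a chain absent from the mapping is a
    configuration error.  If ``topology`` is supplied it provides the force
    field parameters; otherwise per-element defaults (radius and mass from
    small lookup tables, zero charge) are used.

    The default frame spacing of 20 ps matches a production run that stores
    a snapshot every 20 ps.
    """
    from biotite.structure.io.pdb import PDBFile

    path = Path(path)
    counts = _scan_model_atom_counts(path)
    if not counts or counts[0] == 0:
        raise PDBParseError(f"{path} contains no atoms")
    for k, c in enumerate(counts[1:], start=2):
        if c != counts[0]:
            raise PDBParseError(
                f"MODEL {k} has {c} atoms but MODEL 1 has {counts[0]}"
            )

    pdb = PDBFile.read(str(path))
    stack = pdb.get_structure(model=None)
    chains = stack.chain_id[:]
    roles = []
    for ch in chains:
        ch = str(ch)
        if ch not in chain_roles:
            raise ConfigurationError(f"chain {ch!r} has no role mapping")
        role = chain_roles[ch]
        if role not in _ROLES:
            raise ConfigurationError(f"chain {ch!r} mapped to unknown role {role!r}")
        roles.append(role)

    n_atoms = stack.array_length()
    if topology is not None:
        if len(topology) != n_atoms:
            raise ConfigurationError(
                f"topology has {len(topology)} atoms, PDB has {n_atoms}"
            )
        records = list(topology)
    else:
        records = []
        for i in range(n_atoms):
            name = str(stack.atom_name[i])
            elem = str(stack.element[i]) or _element_of(name)
            elem = elem if elem in ELEMENT_RADII else _element_of(name)
            radius = ELEMENT_RADII.get(elem, 1.8)
            records.append(
                AtomRecord(
                    atom_name=name,
                    residue_index=int(stack.res_id[i]),
                    residue_name=str(stack.res_name[i]),
                    role=roles[i],
                    radius=radius,
                    mass=ELEMENT_MASSES.get(elem, 12.0),
                    lj_sigma=2.0 * radius * 2 ** (-1 / 6),
                )
            )

    frames = [
        Frame(stack.coord[m], time=m * time_spacing)
        for m in range(stack.stack_depth())
    ]
    return Trajectory(records, frames, time_spacing=time_spacing)


def write_pdb_models(
    traj: Trajectory,
    path: str | Path,
    peptide_chain: str = "A",
    ligand_chain: str = "L",
) -> Path:
    """Write a trajectory as a standard multi-model PDB file.

    Coordinates are written with three decimals in fixed-width columns;
    ligand atoms are emitted as HETATM records on their own chain.
    Coordinates outside the representable PDB range (-999.999 to 9999.999)
    raise a :class:`ValueError` rather than producing a misaligned file.
    """
    import biotite.structure as struc
    from biotite.structure.io.pdb import PDBFile

    path = Path(path)
    all_coords = traj.coords()
    if all_coords.max() > 9999.999 or all_coords.min() < -999.999:
        raise ValueError("coordinate exceeds the fixed PDB field width")

    n = traj.n_atoms
    stack = struc.AtomArrayStack(traj.n_frames, n)
    stack.coord[:] = all_coords
    stack.chain_id = np.array(
        [peptide_chain if a.role == "peptide" else ligand_chain for a in traj.topology]
    )
    stack.res_id = np.array([a.residue_index for a in traj.topology])
    res_names = [
        AA1_TO_3.get(a.residue_name, a.residue_name)[:3] for a in traj.topology
    ]
    stack.res_name = np.array(res_names)
    stack.atom_name = np.array([a.atom_name[:4] for a in traj.topology])
    stack.element = np.array([_element_of(a.atom_name) for a in traj.topology])
    stack.hetero = np.array([a.role == "ligand" for a in traj.topology])

    pdb = PDBFile()
    pdb.set_structure(stack)
    pdb.write(str(path))
    if traj.n_frames == 1:
        # a one-frame stack is still a multi-model file: wrap it explicitly
        lines = path.read_text().splitlines()
        if not any(ln.startswith("MODEL") for ln in lines):
            atom_pos = [i for i, ln in enumerate(lines)
                        if ln[:6].strip() in ("ATOM", "HETATM")]
            lines.insert(atom_pos[0], "MODEL        1")
            lines.insert(atom_pos[-1] + 2, "ENDMDL")
            path.write_text("\n".join(lines) + "\n")
    return path


# ---------------------------------------------------------------------------
# Topology tables
# ---------------------------------------------------------------------------

_TOPOLOGY_COLUMNS = [
    "atom_name", "residue_index", "residue_name", "role",
    "radius", "charge", "lj_epsilon", "lj_sigma", "mass",
]

_MINUS_VARIANTS = str.maketrans({"−": "-", "–": "-"})


def read_topology(path: str | Path) -> list[AtomRecord]:
    """Read a tab-separated topology table into atom records.

    The file has a one-line header with the columns
    ``atom_name residue_index residue_name role radius charge lj_epsilon
    lj_sigma mass``.  Unicode minus signs in numeric fields are accepted
    (published tables often use them).  Parse and validation errors report
    the offending line number.
    """
    path = Path(path)
    text = path.read_text().translate(_MINUS_VARIANTS)
    lines = [ln for ln in text.splitlines()]
    if not lines:
        raise TopologyParseError(f"{path}: empty file")
    header = lines[0].rstrip("\n").split("\t")
    missing = [c for c in _TOPOLOGY_COLUMNS if c not in header]
    if missing:
        raise TopologyParseError(f"{path}:1: missing columns {missing}")
    col = {c: header.index(c) for c in _TOPOLOGY_COLUMNS}

    records = []
    for ln_no, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) < len(header):
            raise TopologyParseError(
                f"{path}:{ln_no}: expected {len(header)} fields, got {len(parts)}"
            )
        try:
            rec = AtomRecord(
                atom_name=parts[col["atom_name"]].strip(),
                residue_index=int(parts[col["residue_index"]]),
                residue_name=parts[col["residue_name"]].strip(),
                role=parts[col["role"]].strip(),
                radius=float(parts[col["radius"]]),
                charge=float(parts[col["charge"]]),
                lj_epsilon=float(parts[col["lj_epsilon"]]),
                lj_sigma=float(parts[col["lj_sigma"]]),
                mass=float(parts[col["mass"]]),
            )
        except (ValueError, TypeError) as exc:
            raise TopologyParseError(f"{path}:{ln_no}: {exc}") from exc
        records.append(rec)
    if not records:
        raise TopologyParseError(f"{path}: no atom records")
    return records


def write_topology(atoms: Sequence[AtomRecord], path: str | Path) -> Path:
    """Write atom records as the tab-separated topology table."""
    path = Path(path)
    buf = io.StringIO()
    buf.write("\t".join(_TOPOLOGY_COLUMNS) + "\n")
    for a in atoms:
        buf.write(
            f"{a.atom_name}\t{a.residue_index}\t{a.residue_name}\t{a.role}\t"
            f"{a.radius!r}\t{a.charge!r}\t{a.lj_epsilon!r}\t"
            f"{a.lj_sigma!r}\t{a.mass!r}\n"
        )
    path.write_text(buf.getvalue())
    return path
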