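"""MM/PBSA-style free-energy bookkeeping and comparisons.

This module does the arithmetic around end-point binding free energies:
dG = dH - T dS with uncertainty propagation, differences between systems
(S versus R enantiomer, target peptide versus negative-control segment),
the Boltzmann affinity ratio exp(-ddG / kT), and block averaging of
per-frame energy series sampled at a fixed cadence.

It deliberately does not solve the Poisson-Boltzmann equation or estimate
entropies: dH and T dS values are ingested from files or supplied records,
and only their bookkeeping is performed here.

Uncertainty propagation is the *linear* sum of standard deviations, not
quadrature.  The enthalpy and entropy estimates of an end-point method are
strongly correlated (both come from the same frames), and the linear rule
is the convention these summary tables follow.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigurationError

__all__ = [
    "KB",
    "Uncertain",
    "ThermoRecord",
    "ComparisonResult",
    "EnergySeries",
    "BlockStats",
    "free_energy",
    "compare",
    "block_stats",
    "REFERENCE_THERMO",
    "read_thermo_table",
    "write_thermo_table",
]

#: Boltzmann constant in kcal/mol/K.
KB = 0.0019872


@dataclass(frozen=True)
class Uncertain:
    """A value with a one-sigma uncertainty, both in kcal/mol here."""

    value: float
    sd: float = 0.0

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError("standard deviation must be non-negative")

    def __sub__(self, other: "Uncertain") -> "Uncertain":
        return Uncertain(self.value - other.value, self.sd + other.sd)

    def __str__(self) -> str:
        return f"{self.value:.1f} +/- {self.sd:.1f}"


def free_energy(dH: Uncertain, TdS: Uncertain) -> Uncertain:
    """dG = dH - T dS, value and sd rounded to one decimal.

    The sd is the linear sum sd(dH) + sd(TdS); see the module docstring
    for why quadrature is not used.
    """
    value = round(dH.value - TdS.value, 1)
    sd = round(dH.sd + TdS.sd, 1)
    return Uncertain(value, sd)


@dataclass(frozen=True)
class ThermoRecord:
    """One row of an MM/PBSA summary: a peptide/ligand-chirality system."""

    label: str
    dH: Uncertain
    TdS: Uncertain
    dG: Uncertain
    u_nonbonded: Uncertain

    @classmethod
    def from_components(cls, label: str, dH: Uncertain, TdS: Uncertain,
                        u_nonbonded: Uncertain) -> "ThermoRecord":
        """Build a record computing dG from its components."""
        return cls(label, dH, TdS, free_energy(dH, TdS), u_nonbonded)


@dataclass(frozen=True)
class ComparisonResult:
    """Differences a - b between two systems, and the affinity ratio."""

    ddG: float
    ddH: float
    dU: float
    affinity_ratio: float
    temperature: float


def compare(a: ThermoRecord, b: ThermoRecord, temperature: float = 300.0) -> ComparisonResult:
    """Compare two systems: ddG, ddH, dU (a minus b) and exp(-ddG/kT).

    An affinity ratio of ~40 at ddG = -2.2 kcal/mol and 300 K is why a
    2 kcal/mol preference makes the weaker binder effectively invisible.
    """
    ddG = round(a.dG.value - b.dG.value, 10)
    ddH = round(a.dH.value - b.dH.value, 10)
    dU = round(a.u_nonbonded.value - b.u_nonbonded.value, 10)
    ratio = math.exp(-ddG / (KB * temperature))
    return ComparisonResult(ddG, ddH, dU, ratio, temperature)


@dataclass
class EnergySeries:
    """Per-frame energies (kcal/mol) sampled every ``sampling_interval`` ps."""

    values: np.ndarray
    sampling_interval: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.size < 1:
            raise ValueError("need at least one value")
        if self.sampling_interval <= 0:
            raise ValueError("sampling_interval must be positive")


@dataclass(frozen=True)
class BlockStats:
    """Mean of block means, their sd, and a degenerate-data flag."""

    mean: float
    sd: float
    n_blocks: int
    insufficient_data: bool


def block_stats(series: EnergySeries, block: float = 200.0) -> BlockStats:
    """Block-average an energy series (default 200 ps blocks).

    The series is partitioned into contiguous blocks of ``block`` ps; a
    trailing partial block is dropped.  The sd is over block means
    (ddof 1).  A single block has no spread: its sd is reported as 0 with
    ``insufficient_data`` set.
    """
    if block < series.sampling_interval:
        raise ValueError("block must be at least the sampling interval")
    per_block = int(block // series.sampling_interval)
    n_blocks = series.values.size // per_block
    if n_blocks == 0:
        raise ValueError("series shorter than one block")
    trimmed = series.values[: n_blocks * per_block]
    means = trimmed.reshape(n_blocks, per_block).mean(axis=1)
    if n_blocks == 1:
        return BlockStats(float(means[0]), 0.0, 1, True)
    return BlockStats(float(means.mean()), float(means.std(ddof=1)), n_blocks, False)


def _rec(label: str, dh: tuple, tds: tuple, dg: tuple, u: tuple) -> ThermoRecord:
    return ThermoRecord(label, Uncertain(*dh), Uncertain(*tds),
                        Uncertain(*dg), Uncertain(*u))


#: Published MM/PBSA summary for 10074-A4 binding to two c-Myc segments
#: (kcal/mol), keyed by (peptide, ligand chirality).  The dG column is
#: kept exactly as printed: for the (370-409, R) row dH - TdS gives -2.4
#: while the printed dG is -2.3; the table preserves the printed value and
#: the discrepancy is documented rather than corrected.
REFERENCE_THERMO: dict[tuple[str, str], ThermoRecord] = {
    ("c-Myc_370-409", "S"): _rec("c-Myc_370-409/S",
                                 (-19.9, 6.5), (-15.4, 6.7), (-4.5, 13.2), (-38.6, 3.8)),
    ("c-Myc_370-409", "R"): _rec("c-Myc_370-409/R",
                                 (-16.7, 6.9), (-14.3, 7.8), (-2.3, 14.7), (-34.9, 4.6)),
    ("c-Myc_410-437", "S"): _rec("c-Myc_410-437/S",
                                 (-16.6, 6.9), (-15.5, 7.4), (-1.1, 14.3), (-35.8, 3.8)),
    ("c-Myc_410-437", "R"): _rec("c-Myc_410-437/R",
                                 (-11.2, 7.2), (-12.8, 10.0), (1.6, 17.2), (-25.7, 3.3)),
}

_COLUMNS = ["label", "dH", "dH_sd", "TdS", "TdS_sd", "dG", "dG_sd", "U", "U_sd"]


def write_thermo_table(records: list[ThermoRecord], path) -> None:
    """Write records as a tab-separated table mirroring the summary layout."""
    rows = [
        (r.label, r.dH.value, r.dH.sd, r.TdS.value, r.TdS.sd,
         r.dG.value, r.dG.sd, r.u_nonbonded.value, r.u_nonbonded.sd)
        for r in records
    ]
    pd.DataFrame(rows, columns=_COLUMNS).to_csv(path, sep="\t", index=False)


def read_thermo_table(path) -> list[ThermoRecord]:
    """Read a tab-separated thermodynamics table into records.

    Accepts unicode minus signs in numeric fields, as published tables
    often use them.
    """
    from .core import _MINUS_VARIANTS

    with open(path) as fh:
        text = fh.read().translate(_MINUS_VARIANTS)
    from io import StringIO

    df = pd.read_csv(StringIO(text), sep="\t")
    missing = [c for c in _COLUMNS if c not in df.columns]
    if missing:
        raise ConfigurationError(f"thermo table missing columns {missing}")
    return [
        _rec(row["label"], (row["dH"], row["dH_sd"]), (row["TdS"], row["TdS_sd"]),
             (row["dG"], row["dG_sd"]), (row["U"], row["U_sd"]))
        for _, row in df.iterrows()
    ]
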