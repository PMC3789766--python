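# Methods

This note records the models, numerical choices, and deliberate
approximations behind `ligandcloud`, and what the synthetic-data tests do
and do not demonstrate about real trajectories.

## Data model and units

A trajectory is a fixed topology (one record per atom or bead: name,
1-based residue number preserved from input, peptide/ligand role, van der
Waals radius, charge, Lennard-Jones ε/σ, mass) plus uniformly spaced
frames.  Units are fixed package-wide: Å, ps, kcal/mol, elementary
charges, amu.  Multi-model PDB is the interchange format (one MODEL per
frame, ligand atoms as HETATM, read/written through biotite with a
pre-scan that names the offending MODEL on atom-count mismatches);
force-field parameters travel in a tab-separated topology table.  Both
ASCII and unicode minus signs are accepted in numeric fields, because
published tables routinely use the latter.

Charged residues are {Asp, Glu, Lys, Arg}; histidine is treated as
neutral at physiological pH.  This is the convention under which the
c-Myc 370–409 fragment has 12 charged residues out of 40.

## ΔSASA binding detection

SASA uses the Shrake–Rupley construction: for each atom,
`n_sphere_points` (default 256) quasi-uniform points are placed on the
expanded sphere of radius r + probe (probe 1.4 Å) via the deterministic
golden-spiral construction; a point strictly inside any other atom's
expanded sphere is buried.  256 points keep per-atom areas stable to
about 1% (doubling the count moves them by < 2% on random clusters); the
test suite checks against a dense Monte-Carlo surface oracle at the 1%
level.  Atomistic inputs default to a small per-element radius table
(H 1.20, C 1.70, N 1.55, O 1.52, S/P 1.80 Å); coarse-grained inputs carry
bead radii in the topology.

The unbound reference is the *same frame* with ligand atoms deleted, so
ΔSASA is frame-local and non-negative by construction (removing occluders
can only expose surface).  A residue binds in a frame when its summed
ΔSASA strictly exceeds 10 Å²; events are maximal runs of binding frames
with no gap tolerance (one sub-threshold frame ends a run; configurable);
events shorter than the minimum duration (default 10 ns) are discarded;
binding-time percentages count frames inside retained events
(filtering-first; passing a zero minimum duration gives the unfiltered
ordering).  Sites merge residues at or above a percentage floor across
gaps of at most `max_gap` residues and are ranked by mean percentage over
the merged span.

## Clustering and ligand clouds

Kabsch superposition via SVD with the determinant correction, so the
rotation is always proper — mirror images are never matched by a
reflection.  Collinear subsets are rejected.  The all-pairs RMSD matrix
uses a batched formulation (stacked 3×3 SVDs per row), keeping
1000-frame problems in the seconds range; the default fitting subset is
backbone N/CA/C/O where present, otherwise all peptide beads.

Daura (GROMOS) clustering: repeatedly take the unassigned frame with the
most unassigned neighbours within the cutoff (default 2.0 Å), form a
cluster, remove it.  Ties break to the lowest frame index, making the
procedure deterministic.  Removed frames never re-enter, so populations
are fractions of all frames and cluster sizes are non-increasing.
Cumulative top-k percentages round half-up to the nearest integer.  Apo
and holo ensembles are clustered separately.  Ligand clouds superpose
each member's peptide onto its cluster representative and record the
mass-weighted ligand centre of mass.

## Interaction matrices

Contacts: any atom pair strictly closer than 4.0 Å with sequence
separation j > i + 2.  Energies: all inter-residue atom pairs with no
distance cutoff and no periodicity (the analysed systems are small and
the synthetic box is image-free by design); Lorentz–Berthelot combination
(arithmetic σ, geometric ε); Coulomb constant 332.0636 kcal·Å/(mol·e²).
Intra-residue pairs are excluded.  The hydrogen-bond criterion is
geometric — donor–acceptor ≤ 3.5 Å and H–D···A angle ≤ 30° — the common
trajectory-analysis default, adopted because occupancy is reported as a
named quantity without a published geometry; both numbers are
configurable.  Donors are supplied as (donor, hydrogen) index pairs; a
donor without a hydrogen is a configuration error.

## Chain metrics

Radius of gyration is mass-weighted over peptide atoms by default, with
the population (ddof 0) standard deviation over frames.  The random-coil
scaling law is fixed at R_g = 2.02·N^0.6 Å — the constants consistent
with the 18.5 Å expectation at N = 40 — and the native-state law defaults
to 2.2·N^0.38 Å; both are plain power laws exposed as data.

Secondary structure is a Ramachandran mesostate approximation, not a
hydrogen-bond-pattern (DSSP) or chemical-shift method: H for
φ ∈ [−100°, −30°], ψ ∈ [−80°, −5°]; PPII for φ ∈ [−110°, −50°],
ψ ∈ [120°, 180°]; E for φ ∈ [−180°, −90°], ψ ∈ [90°, 180°] excluding the
PPII window; otherwise coil.  Helix labels additionally require runs of
at least 3 residues (echoing the minimal helix); sheet has no run
requirement because no H-bond topology is available.  Terminal residues
lacking a dihedral are coil.  Atomistic backbones use true (φ, ψ);
one-bead chains fall back to virtual dihedrals over bead quadruplets
(i−2…i+1 and i−1…i+2), which places the windows on a different geometric
scale — users comparing against DSSP/PROSS output should recalibrate the
windows, which is why they are parameters.

## Free-energy bookkeeping

ΔG = ΔH − TΔS with values and uncertainties rounded to one decimal.
Uncertainty propagation is the linear sum of standard deviations, not
quadrature: the enthalpy and entropy estimates of an end-point method
come from the same frames and are strongly correlated, and the linear
rule is the one these summary tables follow (it reproduces every ΔG sd
in the bundled reference table exactly: 13.2 = 6.5 + 6.7, 14.7 = 6.9 +
7.8, 14.3 = 6.9 + 7.4, 17.2 = 7.2 + 10).  The bundled table preserves one
printed inconsistency as-is: the R-enantiomer row of the target segment
prints ΔG = −2.3 where ΔH − TΔS gives −2.4; the package reports what the
arithmetic yields and keeps the printed value in the reference fixture.
Affinity ratios use exp(−ΔΔG/kT) at 300 K (k = 0.0019872 kcal/mol/K).
Block statistics partition a series into contiguous blocks (default
200 ps), drop a trailing partial block, and report the sd of block means
(ddof 1); a single block reports sd 0 with an explicit
insufficient-data flag.

## Synthetic generators: what they emulate, and what they do not

`simulate_cg` is a one-bead-per-residue chain (bond length 3.8 Å, bead
σ 4.0 Å, average residue mass 110 amu) with harmonic bonds
(50 kcal/mol/Å²), harmonic angles (2 kcal/mol/rad² about 120°), WCA
excluded volume, and, between ligand beads and residue i, a
truncated-and-shifted Lennard-Jones well of depth ε_i cut at 2.5σ — the
per-residue "stickiness" that defines ground-truth binding sites.  A
designed site is a run of residues with ε ten times the background
(3.0 vs 0.3 kcal/mol), mirroring one strong site dominating weaker ones.
The default ligand surrogate uses three 2.5 Å beads: an extended
molecule occludes several residues at once, as a biaryl compound does.
Integration is BAOAB Langevin (dt 0.01 ps, friction 1 ps⁻¹, 300 K —
stability choices, not force-field physics) in a cubic box with
reflecting walls (default 60 Å), so no analysis ever sees a periodic
image.  All randomness flows through one integer seed; runs are bitwise
reproducible.

`sample_conformer_mixture` draws frames from rigid templates by weight
plus isotropic Gaussian noise — a clean multi-basin ensemble whose
cluster populations are known binomially.  `peptide_backbone` builds
N–CA–C backbones from (φ, ψ) lists with ideal geometry (natural-extension
placement, trans peptide bond), providing helical/extended templates and
secondary-structure fixtures.

Desk-scale test runs use 10⁵ Langevin steps (≈ 1 ns of model time,
~1000 frames) and scale the event-duration floor to a few frames
(0.005 ns), since synthetic binding kinetics are orders of magnitude
faster than the 10 ns floor appropriate to microsecond productions.
What passing these tests shows: the detection, clustering, and
bookkeeping machinery recovers designed ground truth under realistic
noise.  What it does not show: force-field realism — residue chemistry,
water structure, microsecond kinetics, true helix propensities, and
sheet content are all outside what a bead-spring surrogate can emulate.

## Known limitations

- SASA is point-sampled, not analytic; accuracy is set by the point
  count, and ligand-side SASA is not reported.
- The ΔSASA threshold's sensitivity to probe radius and radii set is
  exposed as parameters, not resolved.
- Energy matrices use no cutoff or reaction-field correction; on large
  periodic systems they would need one.
- The secondary-structure mesostates are a calibrated approximation;
  absolute contents differ from DSSP/PROSS on atomistic data.
- Free energies are bookkept, never computed: no solvation model, no
  entropy estimator.
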