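# ligandcloud

Ensemble analysis for small molecules binding intrinsically disordered
peptides.

Disordered proteins such as the c-Myc bHLHZip region never settle into a
single structure: they are "protein clouds", and a small-molecule binder
does not dock into one pocket but visits dispersed, interconverting sites
along the chain — a "ligand cloud".  `ligandcloud` implements the analysis
toolchain for this regime, plus coarse-grained synthetic-data generators
with known ground truth so every stage can be validated end to end:

- **ΔSASA binding sites** — per residue and frame,
  ΔSASA = SASA(peptide alone) − SASA(complex), both at the same
  coordinates (Shrake–Rupley, golden-spiral sphere points).  Residues with
  ΔSASA > 10 Å² are binding; maximal runs shorter than a minimum duration
  (default 10 ns) are discarded; the binding-time percentage per residue
  counts frames inside retained events, and contiguous high-percentage
  stretches are called as ranked sites.
- **Conformational clustering** — Kabsch superposition, all-pairs backbone
  RMSD, and greedy neighbour-count (GROMOS/Daura) clustering at a 2.0 Å
  cutoff; populations are fractions of all frames.  Per cluster, the
  **ligand cloud** is the scatter of ligand centres of mass after
  superposing each member on the representative.
- **Interaction matrices** — residue×residue contact probability
  (any atom pair < 4.0 Å, j > i+2), mean Lennard-Jones
  4ε[(σ/r)¹² − (σ/r)⁶] and Coulomb k·qᵢqⱼ/r energies
  (k = 332.0636 kcal·Å/mol·e², Lorentz–Berthelot combination), and
  hydrogen-bond occupancy (D···A ≤ 3.5 Å, H–D···A ≤ 30°), plus per-residue
  peptide–ligand profiles that exactly partition the total non-bonded
  energy.
- **Chain metrics** — radius-of-gyration distributions against empirical
  scaling laws (random coil: R_g = 2.02·N^0.6 Å, i.e. 18.5 Å at N = 40)
  and (φ, ψ)-window secondary-structure propensities (H/E/PPII/coil, helix
  runs ≥ 3).
- **Free-energy bookkeeping** — ΔG = ΔH − TΔS with linear uncertainty
  summation, S-vs-R and segment-vs-segment comparisons, affinity ratios
  exp(−ΔΔG/kT), and 200 ps block statistics.  The Poisson–Boltzmann and
  entropy machinery behind ΔH/TΔS is out of scope; values are ingested
  from tables.
- **Synthetic generators** — a BAOAB Langevin bead-spring chain with
  per-residue ligand "stickiness" (designed binding sites), a weighted
  template-mixture conformer sampler (known cluster populations), and a
  backbone builder from (φ, ψ) dihedrals.

## Worked example

Free-energy bookkeeping over the bundled reference summary for 10074-A4
binding the c-Myc 370–409 target segment and the 410–437 negative control
(`python examples/free_energy.py`):

```
S vs R on the target segment:
  ddG = -2.2 kcal/mol   ddH = -3.2   dU = -3.7
  affinity ratio exp(-ddG/kT) = 40.1

target segment vs negative control (S form): ddG = -3.4 kcal/mol
```

The 2.2 kcal/mol enantiomer gap means the S form outbinds the R form about
40-fold at 300 K; the 3.4 kcal/mol segment gap is why the control segment
cannot compete.  Site detection on synthetic ground truth
(`python examples/binding_sites.py`, residues 3–15 designed sticky):

```
called sites (ranked by mean percentage):
  rank 1: residues 3-15 (mean 73.6%)
designed site: residues 3-15
```

The other examples cover cluster-population recovery (a 60/40 template
mixture comes back as 62.6%/37.4% at 1000 frames, and the cumulative
top-8 occupancy bookkeeping gives 77% for the bound ensemble versus 50%
for the free one), interaction matrices on a charged chain, and chain
dimensions (a simulated 40-mer at R_g ≈ 18 Å versus the 18.5 Å coil
expectation).

A thin CLI mirrors the library: `ligandcloud run --config config.yaml`
executes the full pipeline from a YAML file and prints a markdown summary;
per-stage subcommands (`simulate`, `sasa-binding`, `cluster`,
`interactions`, `metrics`, `energetics`, `report`) run individual stages.

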