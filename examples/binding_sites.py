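"""Detect a designed binding site on a synthetic disordered chain.

Simulates a 40-residue bead chain whose residues 3-15 attract a 3-bead
ligand ten times more strongly than the rest, then runs the dSASA
pipeline: per-frame buried surface per residue, duration-filtered binding
events, binding-time percentages, and called sites.
"""

import numpy as np

from ligandcloud import (
    ChainSpec,
    LigandSpec,
    SasaParams,
    SimulationParams,
    binding_percentage,
    call_sites,
    delta_sasa,
    ground_truth_sites,
    segment_events,
    simulate_cg,
)

stickiness = np.full(40, 0.3)
stickiness[2:15] = 3.0                       # residues 3-15: the designed site
chain = ChainSpec(n_residues=40, stickiness=stickiness)
ligand = LigandSpec(n_beads=3)
params = SimulationParams(n_steps=100_000, save_interval=100, seed=1)

print("simulating", params.n_steps, "Langevin steps ...")
traj = simulate_cg(chain, ligand, params)

series = delta_sasa(traj, SasaParams())
events = segment_events(series, threshold=10.0, min_duration=0.005)
pct = binding_percentage(events, traj.n_frames, series.residue_ids)
sites = call_sites(pct, min_pct=max(2.0, 0.25 * pct.max()), max_gap=2)

print("\nbinding-time percentage (frames inside retained events):")
for r, p in pct.items():
    bar = "#" * int(p / 2)
    print(f"  residue {r:2d}  {p:5.1f}%  {bar}")

truth = ground_truth_sites(chain, threshold=1.0)
print("\ncalled sites (ranked by mean percentage):")
for s in sites:
    print(f"  rank {s.rank}: residues {s.start}-{s.end} (mean {s.mean_percentage:.1f}%)")
print(f"designed site: residues {min(truth)}-{max(truth)}")
print("\nA residue's percentage is the share of frames it spends in binding")
print("events (dSASA > 10 A^2 sustained beyond the duration floor); the")
print("top-ranked site should coincide with the sticky residues.")
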