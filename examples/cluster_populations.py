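"""Cluster a two-basin synthetic ensemble and recover its weights.

Draws 1000 frames from two rigid templates mixed 60/40 with 0.5 A noise,
clusters them with the greedy neighbour-count (GROMOS) scheme at a 2.0 A
cutoff, and reports populations.  Also shows the cumulative top-8
bookkeeping used to compare a ligand-bound ensemble (77%) against a free
one (50%).
"""

import numpy as np

from ligandcloud import (
    ConformerMixtureSpec,
    cluster_population_report,
    daura_cluster,
    pairwise_rmsd_matrix,
    sample_conformer_mixture,
)

rng = np.random.default_rng(0)
compact = rng.normal(size=(10, 3)) * 3.0
shifted = rng.normal(size=(10, 3)) * 3.0 + np.array([0.0, 0.0, 25.0])

spec = ConformerMixtureSpec([compact, shifted], [0.6, 0.4],
                            noise_sigma=0.5, seed=11)
traj = sample_conformer_mixture(spec, 1000)

rmsd = pairwise_rmsd_matrix(traj)
clusters = daura_cluster(rmsd, cutoff=2.0)
print("clusters found:", clusters.n_clusters)
for _, row in clusters.to_frame().iterrows():
    print(f"  cluster {int(row['cluster'])}: {row['population_pct']:.1f}% "
          f"(representative frame {int(row['representative_frame'])})")
print("mixture weights were 60% / 40%: populations recover them to ~1%.\n")

holo = [14.3, 13.9, 13.7, 10.4, 7.5, 6.9, 5.4, 5.2]
apo = [10.5, 8.6, 7.8, 6.4, 6.1, 4.5, 3.5, 3.0]
_, cum_holo = cluster_population_report(holo, top_k=8)
_, cum_apo = cluster_population_report(apo, top_k=8)
print(f"cumulative top-8 occupancy, ligand-bound ensemble: {cum_holo}%")
print(f"cumulative top-8 occupancy, free ensemble:         {cum_apo}%")
print("A higher cumulative occupancy means the bound ensemble is more")
print("condensed: the ligand narrows the conformational distribution.")
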