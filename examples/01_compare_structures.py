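"""Compare variant structures around a mutation site.

Builds a synthetic wild-type chain plus jittered replicas and two
mutants with a planted local perturbation, computes the pairwise Cα
RMSD matrix in a 5 Å window around the site, clusters it, and reports
each cluster's WT/mutant composition.
"""

import numpy as np

from ensdock import (
    SynthConfig,
    composition,
    distance_window,
    hierarchical_cluster,
    make_chain,
    make_mutant,
    pairwise_rmsd,
    parse_mutation_spec,
)

cfg = SynthConfig(seed=42, n_residues=60, mutation_magnitude=1.0, mutation_radius=5.0)
wt = make_chain(cfg)
site = 30

structures, labels = [], {}
rng = np.random.default_rng(7)
for k in range(4):  # jittered WT replicas stand in for WT models/crystals
    coords = wt.coords + rng.normal(scale=0.05, size=wt.coords.shape)
    s = wt.with_coords(coords, id=f"WT_rep{k}")
    structures.append(s)
    labels[s.id] = "WT"
for k in range(4):  # mutant replicas share one planted perturbation
    mut = make_mutant(wt, parse_mutation_spec(f"A{site}G"), cfg)
    coords = mut.coords + rng.normal(scale=0.05, size=mut.coords.shape)
    s = mut.with_coords(coords, id=f"mut_rep{k}")
    structures.append(s)
    labels[s.id] = "mutant"

window = distance_window(wt, site, 5.0)
matrix = pairwise_rmsd(structures, window)
result = hierarchical_cluster(matrix, k=2)
summary = composition(result, labels)

print(f"5 A window around residue {site}: residues {sorted(window.resnums)}")
print(f"pairwise RMSD range: {matrix.values[matrix.values > 0].min():.2f}"
      f"-{matrix.values.max():.2f} A")
print(summary.to_tsv())
print("Each row is one cluster: with a 1 A planted perturbation the WT and")
print("mutant replicas separate into pure clusters (100/0 and 0/100).")
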