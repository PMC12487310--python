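"""Infer population structure: PCA, Evanno deltaK and a neighbor-joining tree.

The admixture model is fitted by EM for K = 1..5 with 10 random restarts
per K; the Evanno statistic deltaK = mean|L''(K)| / sd(L(K)) peaks at the
supported number of subpopulations (2 here, by construction).
"""

import numpy as np

from panelgwas import (
    admixture_fit,
    evanno_delta_k,
    ibs_distance,
    neighbor_joining,
    pca_genotypes,
    write_tree_newick,
)
from panelgwas.synthetic import SimulationConfig, simulate_population

cfg = SimulationConfig(n_accessions=100, n_markers=300, rng_seed=4,
                       base_missing_rate=0.0, translocation=None)
gm, _, truth = simulate_population(cfg)

scores, frac = pca_genotypes(gm, 10)
print(f"PC1 {100 * frac[0]:.1f}% and PC2 {100 * frac[1]:.1f}% of variance; "
      f"first 10 PCs {100 * frac.sum():.1f}%")

rng = np.random.default_rng(0)
reps = []
for K in range(1, 6):
    seeds = [int(s) for s in rng.integers(0, 2**31 - 1, 10)]
    reps.extend(admixture_fit(gm, K, seeds))
table = evanno_delta_k(reps)
print(table.round(2).to_string(index=False))
interior = table.dropna(subset=["delta_K"])
print(f"deltaK argmax: K = {int(interior.loc[interior['delta_K'].idxmax(), 'K'])}")

tree = neighbor_joining(ibs_distance(gm), gm.accession_ids)
newick = write_tree_newick(tree)
print(f"NJ tree: {tree.count(tips=True)} tips, "
      f"midpoint-rooted, Newick length {len(newick)} chars")
# deltaK is undefined at the boundary K values; its peak at K = 2 matches
# the two subpopulations the generator drew the panel from.
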