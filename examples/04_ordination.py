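"""Spearman clustering and PCA of synthetic enzyme profiles.

High-temperature springs carry far fewer annotations, so they separate in
the sample dendrogram; volcanic provinces are enriched in
cellulose-degrading families, which shows up in the PCA of photosynthate
families but not of cell families.
"""

import tempfile
from pathlib import Path

from thermenz import SimulationConfig, run_pipeline

cfg = SimulationConfig(n_sites=10, n_contigs_per_sample=250,
                       volcanic_cellulose_enrichment=4.0, seed=8)
res = run_pipeline(Path(tempfile.mkdtemp()), sim_config=cfg)

tree = res["ordinations"]["sample_cluster"]
print("sample dendrogram leaf order (Spearman, complete linkage):")
print(" ", " ".join(tree.leaf_order))
print("\nnewick:", tree.to_newick()[:90], "...")

for side in ("cell", "photosynthate"):
    p = res["ordinations"].get(f"pca_{side}")
    if p is not None:
        ev = p.explained_variance_fraction
        print(f"\n{side}-family PCA: PC1 {ev[0]:.2f}, PC2 {ev[1]:.2f} of variance")
        # provinces of the most separated samples along PC1
        provinces = res["truth"].sample_province
        order = p.scores["PC1"].sort_values()
        print(f"  PC1 extremes: {order.index[0]} ({provinces[order.index[0]]}) ... "
              f"{order.index[-1]} ({provinces[order.index[-1]]})")
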