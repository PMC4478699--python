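"""Cluster and ordinate the communities by their transcript COG profiles.

Correlation distance (1 - Pearson r) between community cDNA COG-abundance
profiles, UPGMA dendrogram, and PCA scores.  Writes
results/communities.nwk and results/pca_scores.tsv.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from amdcomp.abundance import relative_abundance, tabulate
from amdcomp.ingest import read_annotated_table
from amdcomp.multivariate import average_linkage, correlation_distance, pca_scores

OUT = Path(__file__).resolve().parents[1] / "results"

def main() -> None:
    reads_path = OUT / "reads.tsv"
    if not reads_path.exists():
        raise SystemExit("run analysis/01_simulate_communities.py first")
    reads = read_annotated_table(reads_path)
    profiles = relative_abundance(tabulate(reads, level="cog", layer="cDNA")).values.T

    dist = correlation_distance(profiles)
    dendro = average_linkage(dist)
    (OUT / "communities.nwk").write_text(dendro.to_newick() + "\n")
    print("community dendrogram (correlation distance, average linkage):")
    print(" ", dendro.to_newick())
    first = dendro.merges[0, :2].astype(int)
    print(f"most similar transcript profiles: {dendro.labels[first[0]]} and "
          f"{dendro.labels[first[1]]} (distance {dendro.heights[0]:.4f})")

    pca = pca_scores(profiles)
    pca.scores.to_csv(OUT / "pca_scores.tsv", sep="\t", index_label="community")
    pc = pca.explained_variance_ratio * 100
    print(f"PCA of COG transcript profiles: PC1 {pc[0]:.1f}%, PC2 {pc[1]:.1f}%")

if __name__ == "__main__":
    main()
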