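"""Community-wide COG screen and indicator calls; per-taxon gene screen.

All C(4,2)=6 community pairs are tested per COG with the two-tailed Fisher
exact test on transcript counts, BH-corrected jointly; a COG significantly
higher (lower) in one community than in all three others becomes a higher
(lower) indicator of that community.  The same machinery is then restricted
to the most active genus's reads, with within-taxon denominators.

Writes results/pairwise_tests.tsv, results/indicators.tsv and
results/per_taxon_tests.tsv.
"""

import json
import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from amdcomp.abundance import tabulate
from amdcomp.differential import (
    call_indicators,
    indicator_counts,
    pairwise_screen,
    per_taxon_gene_screen,
)
from amdcomp.ingest import read_annotated_table

OUT = Path(__file__).resolve().parents[1] / "results"
ALPHA = 0.05

def main() -> None:
    reads_path = OUT / "reads.tsv"
    if not reads_path.exists():
        raise SystemExit("run analysis/01_simulate_communities.py first")
    reads = read_annotated_table(reads_path)

    cogs = tabulate(reads, level="cog", layer="cDNA")
    results, significant = pairwise_screen(cogs, alpha=ALPHA)
    results.to_csv(OUT / "pairwise_tests.tsv", sep="\t", index=False)
    n_tested = results["feature"].nunique()
    print(f"{len(significant)} of {n_tested} COGs differ significantly in "
          f"transcript share across the four communities (BH-adjusted p < {ALPHA})")

    calls = call_indicators(results, alpha=ALPHA)
    calls.to_csv(OUT / "indicators.tsv", sep="\t", index=False)
    counts = indicator_counts(calls, communities=cogs.communities)
    print("indicator COGs per community (higher / lower):")
    for community, row in counts.iterrows():
        print(f"  {community}: {row['higher']} higher, {row['lower']} lower")

    truth = json.loads((OUT / "truth.json").read_text())
    planted = {(p["feature"].split("|")[1], p["community"], p["direction"])
               for p in truth["planted"]}
    called = set(zip(calls["feature"], calls["community"], calls["direction"]))
    hit = planted & called
    print(f"planted indicators recovered: {len(hit)}/{len(planted)}")

    active_genus = truth["activity_multipliers"]
    # screen the genus contributing the most transcripts
    reads_cdna = reads[reads["layer"] == "cDNA"]
    genus = reads_cdna["genus"].value_counts().idxmax()
    taxon_results, taxon_sig, matrix = per_taxon_gene_screen(reads, genus, alpha=ALPHA)
    taxon_results.to_csv(OUT / "per_taxon_tests.tsv", sep="\t", index=False)
    print(f"within {genus} ({int(matrix.column_totals.sum())} transcripts): "
          f"{len(taxon_sig)} of {taxon_results['feature'].nunique()} genes "
          f"differ significantly between communities")

if __name__ == "__main__":
    main()
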