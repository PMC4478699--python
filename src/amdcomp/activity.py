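"""Transcriptionally active taxa and DNA/cDNA discordance.

A taxon's *activity* in a community is read straight off the cDNA layer:
its relative abundance among protein-coding transcripts.  Comparing that
with the DNA layer exposes the two interesting discordance patterns —
taxa that dominate the community's DNA yet contribute almost no transcripts
("abundant-inactive", the dominant-but-quiet pattern), and rare taxa doing
an outsized share of the transcription ("active-rare").
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .abundance import AbundanceTable

FLAG_ABUNDANT_INACTIVE = "abundant-inactive"
FLAG_ACTIVE_RARE = "active-rare"
FLAG_DNA_ABSENT_ACTIVE = "dna-absent-active"


def activity_profiles(dna: AbundanceTable, cdna: AbundanceTable) -> pd.DataFrame:
    """Join DNA and cDNA abundances per (taxon, community) and rank by cDNA.

    The activity ratio is cdna_abundance / dna_abundance (NaN where the taxon
    is absent from the DNA layer).  Ranks are dense within each community,
    1 = most transcriptionally active; ties broken lexicographically by taxon
    label so output is deterministic.
    """
    if set(dna.communities) != set(cdna.communities):
        raise ValueError(
            f"community sets differ: DNA {sorted(dna.communities)} "
            f"vs cDNA {sorted(cdna.communities)}"
        )
    taxa = sorted(set(dna.features) | set(cdna.features))
    d = dna.values.reindex(taxa, fill_value=0.0)
    c = cdna.values.reindex(taxa, fill_value=0.0)[dna.communities]
    frames = []
    for community in dna.communities:
        df = pd.DataFrame(
            {
                "community": community,
                "taxon": taxa,
                "dna_abundance": d[community].to_numpy(),
                "cdna_abundance": c[community].to_numpy(),
            }
        )
        df = df.sort_values(
            ["cdna_abundance", "taxon"], ascending=[False, True]
        ).reset_index(drop=True)
        df["rank_cdna"] = np.arange(1, len(df) + 1)
        frames.append(df)
    out = pd.concat(frames, ignore_index=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = out["cdna_abundance"] / out["dna_abundance"]
    out["activity_ratio"] = ratio.where(out["dna_abundance"] > 0, np.nan)
    return out


def rank_active_taxa(dna: AbundanceTable, cdna: AbundanceTable, k: int) -> pd.DataFrame:
    """Top-k transcriptionally active taxa per community with full profiles."""
    if k < 1:
        raise ValueError("k must be >= 1")
    profiles = activity_profiles(dna, cdna)
    return (
        profiles[profiles["rank_cdna"] <= k]
        .sort_values(["community", "rank_cdna"])
        .reset_index(drop=True)
    )


def discordance_flags(
    profiles: pd.DataFrame,
    ratio_threshold: float = 0.1,
    dna_floor_percent: float = 5.0,
) -> pd.DataFrame:
    """Flag taxa whose DNA and cDNA abundances disagree strongly.

    * ``abundant-inactive`` — DNA abundance >= the floor but the cDNA/DNA
      ratio is below ``ratio_threshold``;
    * ``active-rare`` — the converse: cDNA abundance >= the floor while the
      ratio exceeds ``1 / ratio_threshold``;
    * ``dna-absent-active`` — transcripts observed with no DNA signal at all
      (the ratio is undefined, never a division error).

    Both thresholds are analysis settings, not community properties; the
    defaults (floor 5%, ratio 0.1) mark order-of-magnitude discordance of
    community-dominant taxa.
    """
    if ratio_threshold <= 0:
        raise ValueError("ratio_threshold must be positive")
    out = profiles.copy()
    ratio = out["activity_ratio"]
    flags = np.full(len(out), "", dtype=object)
    dna_absent = (out["dna_abundance"] == 0) & (out["cdna_abundance"] > 0)
    abundant_inactive = (out["dna_abundance"] >= dna_floor_percent) & (
        ratio < ratio_threshold
    )
    active_rare = (out["cdna_abundance"] >= dna_floor_percent) & (
        ratio > 1.0 / ratio_threshold
    )
    flags[abundant_inactive.to_numpy(dtype=bool)] = FLAG_ABUNDANT_INACTIVE
    flags[active_rare.fillna(False).to_numpy(dtype=bool)] = FLAG_ACTIVE_RARE
    flags[dna_absent.to_numpy(dtype=bool)] = FLAG_DNA_ABSENT_ACTIVE
    out["flag"] = flags
    return out
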