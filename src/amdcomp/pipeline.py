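"""End-to-end run orchestration.

``run_pipeline`` chains the full analysis — simulate (or load) annotated
reads, tabulate counts, compute relative abundances, run the pairwise
Fisher screen, call indicator features, rank transcriptionally active taxa,
flag DNA/cDNA discordance, and cluster/ordinate community profiles — and
leaves every stage's table on disk plus a machine-readable ``summary.json``.

Artifacts are write-once: a stage never overwrites an earlier stage's
output, and re-running into a populated directory is an error.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import abundance, activity, differential, multivariate, simulate
from .ingest import read_annotated_table

logger = logging.getLogger(__name__)

SUMMARY_SCHEMA_VERSION = 1


@dataclass
class RunConfig:
    """Parameters for one pipeline run."""

    output_dir: Path
    seed: int = 0
    alpha: float = 0.05
    bh_family: str = "joint"
    screen_level: str = "cog"
    min_abundance_percent: float = 1.0
    top_k: int = 3
    ratio_threshold: float = 0.1
    dna_floor_percent: float = 5.0
    reads_path: Path | None = None  # analyse an existing table instead of simulating
    simulation: simulate.SimulationConfig | None = None

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        self.output_dir = Path(self.output_dir)
        if self.reads_path is not None:
            self.reads_path = Path(self.reads_path)
            if not self.reads_path.exists():
                raise ValueError(f"reads_path {self.reads_path} does not exist")


def _fresh(path: Path) -> Path:
    if path.exists():
        raise FileExistsError(f"refusing to overwrite existing artifact {path}")
    return path


class _Stage:
    """Context manager logging wall-time per pipeline stage to stderr."""

    def __init__(self, name: str):
        self.name = name

    def __enter__(self):
        self.t0 = time.perf_counter()
        logger.info("stage %s: start", self.name)
        return self

    def __exit__(self, exc_type, exc, tb):
        dt = time.perf_counter() - self.t0
        if exc_type is None:
            logger.info("stage %s: done in %.2fs", self.name, dt)
        else:
            logger.error("stage %s: FAILED after %.2fs (%s)", self.name, dt, exc)
        return False


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage; returns (and writes) the summary dictionary."""
    out = config.output_dir
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {
        "schema_version": SUMMARY_SCHEMA_VERSION,
        "seed": config.seed,
        "alpha": config.alpha,
        "bh_family": config.bh_family,
    }

    with _Stage("simulate"):
        if config.reads_path is None:
            sim = config.simulation or simulate.SimulationConfig.realistic(seed=config.seed)
            dna_cm, cdna_cm, truth = simulate.simulate_paired_counts(sim)
            reads = simulate.to_read_table(dna_cm, cdna_cm)
            simulate.write_read_table(reads, _fresh(out / "reads.tsv"))
            truth.to_json(_fresh(out / "truth.json"))
            summary["simulated"] = True
        else:
            summary["simulated"] = False

    with _Stage("ingest"):
        source = config.reads_path or out / "reads.tsv"
        reads = read_annotated_table(source)
        summary["reads_parsed"] = int(len(reads))
        summary["reads_per_layer"] = {
            layer: int(n) for layer, n in reads["layer"].value_counts().items()
        }

    with _Stage("abundance"):
        genus_dna = abundance.tabulate(reads, level="genus", layer="DNA")
        genus_cdna = abundance.tabulate(reads, level="genus", layer="cDNA")
        screen_cdna = abundance.tabulate(reads, level=config.screen_level, layer="cDNA")
        ab_genus_dna = abundance.relative_abundance(genus_dna)
        ab_genus_cdna = abundance.relative_abundance(genus_cdna)
        ab_screen_cdna = abundance.relative_abundance(screen_cdna)
        screen_cdna.to_tsv(_fresh(out / f"counts_{config.screen_level}_cdna.tsv"))
        ab_genus_dna.to_tsv(_fresh(out / "abundance_genus_dna.tsv"))
        ab_genus_cdna.to_tsv(_fresh(out / "abundance_genus_cdna.tsv"))
        abundance.filter_min_abundance(
            ab_genus_cdna, config.min_abundance_percent
        ).to_tsv(_fresh(out / "abundance_genus_cdna_filtered.tsv"))
        summary["communities"] = list(screen_cdna.communities)

    with _Stage("screen"):
        results, significant = differential.pairwise_screen(
            screen_cdna, alpha=config.alpha, family=config.bh_family
        )
        results.to_csv(_fresh(out / "pairwise_tests.tsv"), sep="\t", index=False)
        testable = results[~results["degenerate"]]
        summary["screen"] = {
            "level": config.screen_level,
            "features_tested": int(testable["feature"].nunique()),
            "bh_family_size": int(len(testable)),
            "significant_features": int(len(significant)),
        }

    with _Stage("indicators"):
        calls = differential.call_indicators(results, alpha=config.alpha)
        calls.to_csv(_fresh(out / "indicators.tsv"), sep="\t", index=False)
        counts = differential.indicator_counts(calls, communities=screen_cdna.communities)
        summary["indicators"] = {
            community: {
                "higher": int(row["higher"]),
                "lower": int(row["lower"]),
                "total": int(row["total"]),
            }
            for community, row in counts.iterrows()
        }

    with _Stage("activity"):
        profiles = activity.activity_profiles(ab_genus_dna, ab_genus_cdna)
        flagged = activity.discordance_flags(
            profiles,
            ratio_threshold=config.ratio_threshold,
            dna_floor_percent=config.dna_floor_percent,
        )
        flagged.to_csv(_fresh(out / "activity.tsv"), sep="\t", index=False)
        top = flagged[flagged["rank_cdna"] <= config.top_k]
        summary["top_active_taxa"] = {
            community: group.sort_values("rank_cdna")["taxon"].tolist()
            for community, group in top.groupby("community", observed=True)
        }
        summary["discordant_taxa"] = int((flagged["flag"] != "").sum())

    with _Stage("cluster"):
        profile_matrix = ab_screen_cdna.values.T  # communities x features
        dist = multivariate.correlation_distance(profile_matrix)
        dendro = multivariate.average_linkage(dist)
        _fresh(out / "communities.nwk").write_text(dendro.to_newick() + "\n")
        pca = multivariate.pca_scores(profile_matrix)
        pca.scores.to_csv(_fresh(out / "pca_scores.tsv"), sep="\t", index_label="community")
        summary["cluster"] = {
            "newick": dendro.to_newick(),
            "merge_heights": [float(h) for h in dendro.heights],
            "pc_variance_percent": [
                round(float(r) * 100.0, 6) for r in pca.explained_variance_ratio
            ],
        }

    with open(_fresh(out / "summary.json"), "w") as fh:
        json.dump(summary, fh, indent=1, sort_keys=True)
    return summary
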