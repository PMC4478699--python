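"""Synthetic paired metagenome/metatranscriptome (DNA/cDNA) count data.

The generator emulates the study design the rest of the package analyses:
a small number of acid-mine-drainage communities, each a mixture of genera
expressing clusters of orthologous groups (COGs).  Features are
``(genus, COG)`` pairs.  The DNA layer of each community is one multinomial
draw from that community's composition; the cDNA layer is a multinomial draw
from the same composition re-weighted by a per-genus *activity multiplier*
(so a genus can be abundant in DNA yet almost silent in cDNA, or vice versa)
and optionally perturbed by *planted indicator* features whose expected
proportion in one community is multiplied by a known fold-change.

Everything downstream (tabulation, Fisher screens, indicator calling,
activity ranking, clustering) can therefore be tested against exact known
truth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .abundance import CountMatrix

# single-letter COG functional classes, cycled over synthetic COGs
COG_CATEGORY_ALPHABET = "JAKLBDYVTMNZWUOCGEFHIPQ"

#: genera observed in acid-mine-drainage communities, used by default so
#: synthetic tables read like real annotation output
AMD_GENERA = (
    "Acidithiobacillus",
    "Leptospirillum",
    "Acidiphilium",
    "Ferroplasma",
    "Thermoplasma",
    "ARMAN",
    "Sulfobacillus",
    "Acidimicrobium",
    "Metallibacterium",
    "Ferrovum",
    "Acidibacillus",
    "Alicyclobacillus",
)

DEFAULT_COMMUNITIES_4 = ("DBS", "FK", "YFS", "YFP")


def feature_label(genus: str, cog: str) -> str:
    return f"{genus}|{cog}"


def split_feature(label: str) -> tuple[str, str]:
    genus, _, cog = label.partition("|")
    return genus, cog


@dataclass(frozen=True)
class PlantedIndicator:
    """A known differential feature: one community's expected proportion is
    multiplied by ``fold_change`` (direction ``"higher"``) or divided by it
    (``"lower"``) in the given layer, then the vector is re-normalised.

    ``fold_change`` must be >= 1 so the stored direction is unambiguous
    (a fold of exactly 1 is a no-op either way).
    """

    feature: str
    community: str
    fold_change: float
    direction: str  # "higher" | "lower"
    layer: str = "cDNA"

    def __post_init__(self) -> None:
        if self.direction not in ("higher", "lower"):
            raise ValueError(f"direction must be 'higher' or 'lower', got {self.direction!r}")
        if not self.fold_change >= 1.0:
            raise ValueError("fold_change must be >= 1 (use direction='lower' to deplete)")
        if self.layer not in ("DNA", "cDNA"):
            raise ValueError(f"layer must be 'DNA' or 'cDNA', got {self.layer!r}")

    @property
    def multiplier(self) -> float:
        return self.fold_change if self.direction == "higher" else 1.0 / self.fold_change


@dataclass
class SimulationConfig:
    """Study-design parameters for one paired simulation.

    Defaults mirror the design the analysis is built for: four communities,
    a genus-by-COG composition shared as a baseline, per-genus activity
    multipliers linking the DNA layer to the cDNA layer, and read depths at
    desk scale (tens of thousands of protein-coding reads per library).
    """

    n_communities: int = 4
    n_genera: int = 12
    n_cogs: int = 150
    depth_dna: int = 50_000
    depth_cdna: int = 20_000
    baseline_proportions: np.ndarray | None = None  # len n_genera*n_cogs; None = uniform
    activity_multipliers: np.ndarray | None = None  # per genus; None = all 1.0
    planted_indicators: tuple[PlantedIndicator, ...] = ()
    seed: int = 0
    genus_labels: tuple[str, ...] | None = None
    cog_labels: tuple[str, ...] | None = None
    community_labels: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if self.n_communities < 2:
            raise ValueError("need at least 2 communities")
        if self.depth_dna < 1 or self.depth_cdna < 1:
            raise ValueError("read depths must be >= 1")
        if self.genus_labels is None:
            base = list(AMD_GENERA)
            while len(base) < self.n_genera:
                base.append(f"Genus{len(base):02d}")
            self.genus_labels = tuple(base[: self.n_genera])
        if len(self.genus_labels) != self.n_genera:
            raise ValueError("genus_labels length must equal n_genera")
        if self.cog_labels is None:
            self.cog_labels = tuple(f"COG{i + 1:04d}" for i in range(self.n_cogs))
        if len(self.cog_labels) != self.n_cogs:
            raise ValueError("cog_labels length must equal n_cogs")
        if self.community_labels is None:
            if self.n_communities == 4:
                self.community_labels = DEFAULT_COMMUNITIES_4
            else:
                self.community_labels = tuple(f"S{i + 1:02d}" for i in range(self.n_communities))
        if len(self.community_labels) != self.n_communities:
            raise ValueError("community_labels length must equal n_communities")
        n_features = self.n_genera * self.n_cogs
        if self.baseline_proportions is None:
            self.baseline_proportions = np.full(n_features, 1.0 / n_features)
        self.baseline_proportions = np.asarray(self.baseline_proportions, dtype=float)
        if self.baseline_proportions.shape != (n_features,):
            raise ValueError(
                f"baseline_proportions must have length {n_features} "
                f"(n_genera * n_cogs), got {self.baseline_proportions.shape}"
            )
        if (self.baseline_proportions < 0).any():
            raise ValueError("baseline_proportions must be non-negative")
        if abs(self.baseline_proportions.sum() - 1.0) > 1e-12:
            raise ValueError("baseline_proportions must sum to 1 within 1e-12")
        if self.activity_multipliers is None:
            self.activity_multipliers = np.ones(self.n_genera)
        self.activity_multipliers = np.asarray(self.activity_multipliers, dtype=float)
        if self.activity_multipliers.shape != (self.n_genera,):
            raise ValueError("activity_multipliers must have one entry per genus")
        if (self.activity_multipliers <= 0).any():
            raise ValueError("activity_multipliers must be positive")
        self.planted_indicators = tuple(self.planted_indicators)
        features = set(self.feature_labels)
        for plant in self.planted_indicators:
            if plant.feature not in features:
                raise ValueError(f"planted feature {plant.feature!r} does not exist")
            if plant.community not in self.community_labels:
                raise ValueError(f"planted community {plant.community!r} does not exist")

    @property
    def feature_labels(self) -> list[str]:
        return [feature_label(g, c) for g in self.genus_labels for c in self.cog_labels]

    @property
    def feature_genus_index(self) -> np.ndarray:
        return np.repeat(np.arange(self.n_genera), self.n_cogs)

    @classmethod
    def realistic(cls, seed: int = 0, **overrides) -> "SimulationConfig":
        """A heterogeneous four-community configuration.

        Baseline genus weights follow a lognormal rank-abundance curve and
        COG weights within a genus a second lognormal, so a handful of
        genus/COG combinations dominate as in real annotation profiles.
        Activity multipliers are lognormal around 1 except that the most
        DNA-abundant genus is made nearly silent (multiplier 0.01) — the
        dominant-but-inactive pattern.
        """
        proto = cls(seed=seed, **{k: v for k, v in overrides.items() if k != "seed"})
        rng = np.random.default_rng(seed)
        genus_w = rng.lognormal(mean=0.0, sigma=1.0, size=proto.n_genera)
        cog_w = rng.lognormal(mean=0.0, sigma=0.8, size=(proto.n_genera, proto.n_cogs))
        weights = (genus_w[:, None] * cog_w).ravel()
        baseline = weights / weights.sum()
        mult = rng.lognormal(mean=0.0, sigma=0.7, size=proto.n_genera)
        mult[np.argmax(genus_w)] = 0.01  # dominant taxon, transcriptionally quiet
        overrides.setdefault("baseline_proportions", baseline)
        overrides.setdefault("activity_multipliers", mult)
        return cls(seed=seed, **overrides)


@dataclass
class CommunityTruth:
    """Exact expected proportions per community and layer, plus the plants."""

    dna_proportions: pd.DataFrame  # features x communities
    cdna_proportions: pd.DataFrame
    planted: tuple[PlantedIndicator, ...]
    activity_multipliers: pd.Series  # per genus

    def __post_init__(self) -> None:
        for df in (self.dna_proportions, self.cdna_proportions):
            sums = df.to_numpy().sum(axis=0)
            if not np.allclose(sums, 1.0, atol=1e-12):
                raise ValueError("truth proportion columns must sum to 1 within 1e-12")

    def proportions(self, layer: str) -> pd.DataFrame:
        if layer == "DNA":
            return self.dna_proportions
        if layer == "cDNA":
            return self.cdna_proportions
        raise ValueError(f"unknown layer {layer!r}")

    def planted_features(self, direction: str | None = None) -> set[tuple[str, str]]:
        """(feature, community) pairs planted, optionally one direction only."""
        return {
            (p.feature, p.community)
            for p in self.planted
            if direction is None or p.direction == direction
        }

    def to_json(self, path) -> None:
        payload = {
            "dna_proportions": {
                c: self.dna_proportions[c].to_dict() for c in self.dna_proportions.columns
            },
            "cdna_proportions": {
                c: self.cdna_proportions[c].to_dict() for c in self.cdna_proportions.columns
            },
            "activity_multipliers": self.activity_multipliers.to_dict(),
            "planted": [
                {
                    "feature": p.feature,
                    "community": p.community,
                    "fold_change": p.fold_change,
                    "direction": p.direction,
                    "layer": p.layer,
                }
                for p in self.planted
            ],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


def _apply_plants(p: np.ndarray, feature_idx: dict[str, int], plants, community: str,
                  layer: str) -> np.ndarray:
    """Multiply planted features into a proportion vector and re-normalise."""
    q = p.copy()
    for plant in plants:
        if plant.community != community or plant.layer != layer:
            continue
        q[feature_idx[plant.feature]] *= plant.multiplier
    if (q < 0).any():
        raise ValueError("proportion vector has a negative entry after planting")
    if (q > 1.0 + 1e-12).any():
        raise ValueError(
            "planted fold-change is too large: an expected proportion exceeds 1 "
            "before re-normalisation"
        )
    return q / q.sum()


def community_expectations(config: SimulationConfig) -> CommunityTruth:
    """Exact expected proportions implied by a configuration (no sampling)."""
    features = config.feature_labels
    idx = {f: i for i, f in enumerate(features)}
    genus_of = config.feature_genus_index
    mult = config.activity_multipliers[genus_of]
    dna_cols = {}
    cdna_cols = {}
    for community in config.community_labels:
        dna_p = _apply_plants(
            config.baseline_proportions, idx, config.planted_indicators, community, "DNA"
        )
        cdna_base = dna_p * mult
        cdna_base = cdna_base / cdna_base.sum()
        cdna_p = _apply_plants(cdna_base, idx, config.planted_indicators, community, "cDNA")
        dna_cols[community] = dna_p
        cdna_cols[community] = cdna_p
    return CommunityTruth(
        dna_proportions=pd.DataFrame(dna_cols, index=features),
        cdna_proportions=pd.DataFrame(cdna_cols, index=features),
        planted=config.planted_indicators,
        activity_multipliers=pd.Series(
            config.activity_multipliers, index=list(config.genus_labels)
        ),
    )


def simulate_paired_counts(
    config: SimulationConfig,
) -> tuple[CountMatrix, CountMatrix, CommunityTruth]:
    """Draw one paired DNA/cDNA dataset.

    Each community x layer column is a single multinomial draw of the
    configured depth from the truth proportions.  Draw order is fixed
    (communities in label order, DNA before cDNA) so a given seed always
    produces bit-identical matrices.
    """
    truth = community_expectations(config)
    rng = np.random.default_rng(config.seed)
    features = config.feature_labels
    dna_counts = {}
    cdna_counts = {}
    for community in config.community_labels:
        dna_counts[community] = rng.multinomial(
            config.depth_dna, truth.dna_proportions[community].to_numpy()
        )
        cdna_counts[community] = rng.multinomial(
            config.depth_cdna, truth.cdna_proportions[community].to_numpy()
        )
    dna = CountMatrix(pd.DataFrame(dna_counts, index=features), level="feature", layer="DNA")
    cdna = CountMatrix(pd.DataFrame(cdna_counts, index=features), level="feature", layer="cDNA")
    return dna, cdna, truth


def simulate_null(
    config: SimulationConfig, n_reps: int
) -> list[tuple[CountMatrix, CountMatrix]]:
    """Independent replicates with no planted effects (all communities share
    one proportion vector per layer).  Replicate ``i`` uses seed
    ``config.seed + i`` so every replicate is individually reproducible.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    if config.planted_indicators:
        raise ValueError("null simulation requires empty planted_indicators")
    out = []
    for i in range(n_reps):
        rep_config = replace(config, seed=config.seed + i)
        dna, cdna, _ = simulate_paired_counts(rep_config)
        out.append((dna, cdna))
    return out


# ---------------------------------------------------------------------------
# annotated read-table emission (the TSV dialect amdcomp.ingest consumes)
# ---------------------------------------------------------------------------

READ_TABLE_COLUMNS = (
    "read_id",
    "sample",
    "layer",
    "genus",
    "species",
    "cog_id",
    "cog_category",
    "kegg_pathway",
)


def _feature_annotations(features: list[str]) -> pd.DataFrame:
    """Deterministic per-feature annotation columns derived from the label."""
    rows = []
    for label in features:
        genus, cog = split_feature(label)
        cog_num = int(cog.replace("COG", "")) if cog.startswith("COG") else hash(cog) % 10_000
        rows.append(
            {
                "feature": label,
                "genus": genus,
                "species": f"{genus}_sp{1 + (cog_num % 2)}",
                "cog_id": cog,
                "cog_category": COG_CATEGORY_ALPHABET[cog_num % len(COG_CATEGORY_ALPHABET)],
                "kegg_pathway": f"map{((cog_num % 40) + 1) * 10:05d}",
            }
        )
    return pd.DataFrame(rows).set_index("feature")


def to_read_table(dna: CountMatrix, cdna: CountMatrix) -> pd.DataFrame:
    """Expand paired count matrices into one row per read.

    Reads are annotated with genus, species, COG id, COG category and KEGG
    pathway derived deterministically from the feature label, so tabulating
    the emitted table at any level reproduces the matrix (or a coarsening
    of it) exactly.
    """
    annot = _feature_annotations(dna.features)
    frames = []
    for cm in (dna, cdna):
        for community in cm.communities:
            col = cm.counts[community]
            expanded = (
                annot.loc[np.repeat(col.index.to_numpy(), col.to_numpy())]
                .rename_axis("feature")
                .reset_index()
            )
            expanded.insert(0, "layer", cm.layer)
            expanded.insert(0, "sample", community)
            expanded.insert(
                0,
                "read_id",
                [f"{community}:{cm.layer}:{i:07d}" for i in range(len(expanded))],
            )
            frames.append(expanded)
    table = pd.concat(frames, ignore_index=True)
    return table[list(READ_TABLE_COLUMNS) + ["feature"]]


def write_read_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# dummy FASTA with planted exact duplicates, for dereplication tests
# ---------------------------------------------------------------------------

def write_synthetic_fasta(
    path, n_unique: int = 80, n_duplicates: int = 20, seed: int = 0,
    length_range: tuple[int, int] = (60, 120),
) -> tuple[int, int]:
    """Write random reads with ``n_duplicates`` planted exact copies.

    Returns ``(n_kept_expected, n_removed_expected)`` — dereplication must
    keep exactly one read per distinct sequence.  Unique sequences are drawn
    rejection-free by construction (distinct random suffixes).
    """
    rng = np.random.default_rng(seed)
    bases = np.array(list("ACGT"))
    seqs = []
    seen = set()
    while len(seqs) < n_unique:
        n = rng.integers(length_range[0], length_range[1] + 1)
        s = "".join(rng.choice(bases, size=n))
        if s not in seen:
            seen.add(s)
            seqs.append(s)
    dup_sources = rng.choice(n_unique, size=n_duplicates, replace=True)
    records = [(f"read{i:04d}", s) for i, s in enumerate(seqs)]
    records += [
        (f"dup{j:04d}", seqs[src]) for j, src in enumerate(dup_sources)
    ]
    order = rng.permutation(len(records))
    with open(path, "w") as fh:
        for k in order:
            rid, s = records[k]
            fh.write(f">{rid}\n{s}\n")
    return n_unique, n_duplicates
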