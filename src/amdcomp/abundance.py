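"""Count matrices and relative-abundance profiles.

The central statistic of the whole analysis is the relative abundance of a
feature (taxon, gene, COG, COG category or KEGG pathway) within one community
and one sequencing layer::

    abundance(f, c) = 100 * a / b

where ``a`` is the number of reads assigned to the feature in community ``c``
and ``b`` is the total number of reads assigned to *any* feature at that
annotation level in ``c``.  Reads lacking an annotation at the requested level
are excluded from both numerator and denominator; this choice changes every
percentage and is therefore explicit and configurable nowhere else.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: annotation levels and the read-table column each one tabulates
LEVEL_COLUMNS = {
    "genus": "genus",
    "species": "species",
    "cog": "cog_id",
    "cog_category": "cog_category",
    "kegg_pathway": "kegg_pathway",
    "gene": "gene",
    "feature": "feature",
}

LAYERS = ("DNA", "cDNA")


@dataclass
class CountMatrix:
    """Integer read counts, features x communities, for one layer.

    Parameters
    ----------
    counts
        DataFrame indexed by feature label with one column per community.
    level
        Annotation level the features live at (key of :data:`LEVEL_COLUMNS`).
    layer
        ``"DNA"`` or ``"cDNA"``.
    """

    counts: pd.DataFrame
    level: str
    layer: str

    def __post_init__(self) -> None:
        if self.layer not in LAYERS:
            raise ValueError(f"layer must be one of {LAYERS}, got {self.layer!r}")
        if self.level not in LEVEL_COLUMNS:
            raise ValueError(f"unknown annotation level {self.level!r}")
        if self.counts.index.duplicated().any():
            dups = self.counts.index[self.counts.index.duplicated()].tolist()
            raise ValueError(f"duplicate feature labels: {dups}")
        values = self.counts.to_numpy()
        if (values < 0).any():
            raise ValueError("counts must be non-negative")
        if not np.issubdtype(values.dtype, np.integer):
            if not np.allclose(values, np.round(values)):
                raise ValueError("counts must be integers")
            self.counts = self.counts.astype(np.int64)

    @property
    def features(self) -> list[str]:
        return list(self.counts.index)

    @property
    def communities(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def column_totals(self) -> pd.Series:
        """Per-community total of assigned reads (the ``b`` of the formula)."""
        return self.counts.sum(axis=0)

    @property
    def zero_communities(self) -> list[str]:
        """Communities with no assigned reads; downstream ops refuse these."""
        totals = self.column_totals
        return list(totals.index[totals == 0])

    def restrict(self, features) -> "CountMatrix":
        return CountMatrix(self.counts.loc[list(features)].copy(), self.level, self.layer)

    def to_tsv(self, path) -> None:
        self.counts.to_csv(path, sep="\t", index_label=self.level)

    @classmethod
    def from_tsv(cls, path, level: str, layer: str) -> "CountMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        df.index = df.index.astype(str)
        return cls(df, level=level, layer=layer)


@dataclass
class AbundanceTable:
    """Relative abundances in percent; every column sums to 100."""

    values: pd.DataFrame
    level: str
    layer: str

    def __post_init__(self) -> None:
        vals = self.values.to_numpy(dtype=float)
        if (vals < -1e-12).any() or (vals > 100 + 1e-9).any():
            raise ValueError("abundances must lie in [0, 100]")
        col_sums = vals.sum(axis=0)
        if not np.allclose(col_sums, 100.0, atol=1e-9):
            raise ValueError(f"columns must sum to 100, got {col_sums}")

    @property
    def features(self) -> list[str]:
        return list(self.values.index)

    @property
    def communities(self) -> list[str]:
        return list(self.values.columns)

    def to_tsv(self, path) -> None:
        self.values.to_csv(path, sep="\t", index_label=self.level)

    def to_long(self) -> pd.DataFrame:
        long = self.values.reset_index(names=self.level).melt(
            id_vars=self.level, var_name="community", value_name="abundance_percent"
        )
        long["layer"] = self.layer
        return long


def tabulate(reads: pd.DataFrame, level: str, layer: str) -> CountMatrix:
    """Count reads per (feature, community) at one annotation level.

    ``reads`` is an annotated read table (see :mod:`amdcomp.ingest`).  Reads of
    the other layer, and reads whose annotation at ``level`` is missing, are
    excluded from the tabulation entirely — they contribute to neither ``a``
    nor ``b``.  Features are ordered lexicographically so output is
    deterministic regardless of input order.
    """
    column = LEVEL_COLUMNS.get(level)
    if column is None:
        raise ValueError(f"unknown annotation level {level!r}")
    if column not in reads.columns:
        raise ValueError(f"read table has no {column!r} column for level {level!r}")
    sub = reads[reads["layer"] == layer]
    annotated = sub[sub[column].notna() & (sub[column].astype(str) != "")]
    communities = sorted(reads["sample"].astype(str).unique())
    table = (
        annotated.groupby([column, "sample"], observed=True)
        .size()
        .unstack(fill_value=0)
        .reindex(columns=communities, fill_value=0)
    )
    table = table.sort_index()
    table.index = table.index.astype(str)
    return CountMatrix(table.astype(np.int64), level=level, layer=layer)


def relative_abundance(matrix: CountMatrix) -> AbundanceTable:
    """Per-column percentages ``100 * a / b``; refuses empty communities."""
    totals = matrix.column_totals
    empty = matrix.zero_communities
    if empty:
        raise ValueError(
            f"community {empty[0]!r} has zero assigned reads at level "
            f"{matrix.level!r}; cannot compute relative abundance"
        )
    values = matrix.counts.div(totals, axis=1) * 100.0
    return AbundanceTable(values, level=matrix.level, layer=matrix.layer)


def filter_min_abundance(
    table: AbundanceTable, threshold_percent: float, pool_other: bool = True
) -> AbundanceTable:
    """Keep features reaching ``threshold_percent`` (inclusive) somewhere.

    A feature is retained iff its abundance is >= the threshold in at least
    one community.  With ``pool_other=True`` the discarded mass is pooled into
    a single ``"other"`` row so columns still sum to 100; otherwise the result
    is returned unpooled and re-normalised over the kept features.
    """
    if threshold_percent < 0:
        raise ValueError("threshold must be >= 0")
    keep = (table.values >= threshold_percent).any(axis=1)
    kept = table.values.loc[keep]
    if keep.all():
        return AbundanceTable(kept.copy(), level=table.level, layer=table.layer)
    if pool_other:
        other = table.values.loc[~keep].sum(axis=0)
        out = pd.concat([kept, other.to_frame("other").T])
    else:
        out = kept.div(kept.sum(axis=0), axis=1) * 100.0
    return AbundanceTable(out, level=table.level, layer=table.layer)
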