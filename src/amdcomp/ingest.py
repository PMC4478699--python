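"""Input parsing and validation.

Three kinds of input feed the analysis:

* annotated read tables — one row per protein-coding read with sample,
  layer (DNA or cDNA), taxonomy and function labels;
* FASTA read sets, dereplicated by removing replicate sequences that share
  100% nucleotide identity and length (exact string equality);
* a geochemistry table of the sampled sites (pH, temperature, dissolved
  oxygen and organic carbon, iron species, sulfate, metals), validated with
  an iron mass balance: total iron should equal ferrous plus ferric iron.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, fields

import numpy as np
import pandas as pd
from Bio import SeqIO

logger = logging.getLogger(__name__)

REQUIRED_READ_COLUMNS = ("read_id", "sample", "layer")
VALID_LAYERS = frozenset({"DNA", "cDNA"})

#: geochemistry table column headers -> record attributes
GEOCHEM_COLUMNS = {
    "Sample": "sample",
    "pH": "pH",
    "Temperature": "temperature",
    "DO": "DO",
    "DOC": "DOC",
    "T-Fe": "T_Fe",
    "Fe2+": "Fe2",
    "Fe3+": "Fe3",
    "SO42-": "SO4",
    "Al": "Al",
    "Pb": "Pb",
    "Zn": "Zn",
    "Cu": "Cu",
    "Cd": "Cd",
    "Cr": "Cr",
    "Mn": "Mn",
}


def read_annotated_table(path, strict: bool = True) -> pd.DataFrame:
    """Load and validate a tab-separated annotated read table.

    Required columns: ``read_id``, ``sample``, ``layer``; unknown columns are
    preserved untouched.  Rows whose layer is not DNA or cDNA are a hard
    error naming the row and offending value when ``strict`` (default), or
    skipped with a log line otherwise.  Duplicate ``(sample, layer,
    read_id)`` triples are always a hard error.
    """
    table = pd.read_csv(path, sep="\t", dtype=str)
    for col in REQUIRED_READ_COLUMNS:
        if col not in table.columns:
            raise ValueError(f"annotated read table is missing required column {col!r}")
    bad_layer = ~table["layer"].isin(VALID_LAYERS)
    if bad_layer.any():
        row = int(np.flatnonzero(bad_layer.to_numpy())[0])
        value = table["layer"].iloc[row]
        if strict:
            raise ValueError(
                f"row {row + 2} has invalid layer {value!r} (expected DNA or cDNA)"
            )
        logger.warning(
            "skipping %d rows with invalid layer (first: row %d, value %r)",
            int(bad_layer.sum()), row + 2, value,
        )
        table = table[~bad_layer].reset_index(drop=True)
    dup = table.duplicated(subset=["sample", "layer", "read_id"])
    if dup.any():
        first = table.loc[dup, ["sample", "layer", "read_id"]].iloc[0]
        raise ValueError(
            f"duplicate read id {first['read_id']!r} within "
            f"({first['sample']}, {first['layer']})"
        )
    logger.info("parsed %d annotated reads from %s", len(table), path)
    return table


def dereplicate_reads(fasta_path) -> tuple[list[str], list[str]]:
    """Remove replicate reads sharing 100% nucleotide identity and length.

    Sequences are compared as uppercased strings, so identity is exact and
    equal length is implied; ambiguity codes are not wildcards (``N != A``).
    Within each set of identical sequences the first read in file order is
    kept.  Returns ``(kept_ids, removed_ids)``, a partition of the input.
    """
    kept: list[str] = []
    removed: list[str] = []
    seen_seqs: set[str] = set()
    seen_ids: set[str] = set()
    n = 0
    for record in SeqIO.parse(str(fasta_path), "fasta"):
        n += 1
        if record.id in seen_ids:
            raise ValueError(f"duplicate FASTA id {record.id!r}")
        seen_ids.add(record.id)
        seq = str(record.seq).upper()
        if seq in seen_seqs:
            removed.append(record.id)
        else:
            seen_seqs.add(seq)
            kept.append(record.id)
    if n == 0:
        logger.warning("FASTA file %s contains no records", fasta_path)
    return kept, removed


@dataclass
class GeochemRecord:
    """One site's physicochemical measurements (concentrations in mg/l)."""

    sample: str
    pH: float
    temperature: float
    DO: float | None = None
    DOC: float | None = None
    T_Fe: float | None = None
    Fe2: float | None = None
    Fe3: float | None = None
    SO4: float | None = None
    Al: float | None = None
    Pb: float | None = None
    Zn: float | None = None
    Cu: float | None = None
    Cd: float | None = None
    Cr: float | None = None
    Mn: float | None = None

    def __post_init__(self) -> None:
        if not self.pH > 0:
            raise ValueError(f"sample {self.sample!r}: pH must be positive")
        for f in fields(self):
            if f.name in ("sample", "pH", "temperature"):
                continue
            value = getattr(self, f.name)
            if value is not None and value < 0:
                raise ValueError(f"sample {self.sample!r}: {f.name} must be >= 0")


def _parse_concentration(raw, column: str):
    """'ND' (not detected) and blanks are missing, never imputed as zero."""
    if raw is None or (isinstance(raw, float) and np.isnan(raw)):
        return None
    text = str(raw).strip()
    if text == "" or text.upper() == "ND":
        return None
    try:
        return float(text)
    except ValueError:
        raise ValueError(f"non-numeric value {raw!r} in column {column!r}") from None


def read_geochem(path) -> list[GeochemRecord]:
    """Parse a tab-separated geochemistry table with the standard headers."""
    table = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in ("Sample", "pH", "Temperature") if c not in table.columns]
    if missing:
        raise ValueError(f"geochemistry table missing columns: {missing}")
    records = []
    for _, row in table.iterrows():
        kwargs = {"sample": str(row["Sample"]).strip()}
        for col, attr in GEOCHEM_COLUMNS.items():
            if col == "Sample" or col not in table.columns:
                continue
            value = _parse_concentration(row[col], col)
            if attr in ("pH", "temperature") and value is None:
                raise ValueError(f"sample {kwargs['sample']!r}: {col} is required")
            kwargs[attr] = value
        records.append(GeochemRecord(**kwargs))
    return records


def geochem_frame(records: list[GeochemRecord]) -> pd.DataFrame:
    """Records as a numeric DataFrame indexed by sample (missing = NaN)."""
    rows = {
        r.sample: {f.name: getattr(r, f.name) for f in fields(GeochemRecord)[1:]}
        for r in records
    }
    return pd.DataFrame.from_dict(rows, orient="index").astype(float)


def validate_iron_balance(record: GeochemRecord, tolerance_mg_per_l: float = 15.0) -> str:
    """Check total iron against ferrous + ferric iron.

    Returns ``"pass"`` when ``|T_Fe - (Fe2 + Fe3)| <= tolerance`` and
    ``"warn"`` otherwise — never an error, since published tables can be
    internally inconsistent at the rounding level.  Missing iron values also
    warn (the balance cannot be verified).
    """
    if record.T_Fe is None or record.Fe2 is None or record.Fe3 is None:
        logger.warning("sample %s: iron balance unverifiable (missing value)", record.sample)
        return "warn"
    gap = abs(record.T_Fe - (record.Fe2 + record.Fe3))
    if gap <= tolerance_mg_per_l:
        return "pass"
    logger.warning(
        "sample %s: Fe2+ + Fe3+ = %.6g differs from T-Fe = %.6g by %.6g mg/l",
        record.sample, record.Fe2 + record.Fe3, record.T_Fe, gap,
    )
    return "warn"
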