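"""Taxonomic profile ingestion, sample QC and species presence calling.

Species-level read-pair counts per sample (parsed from Kraken2 reports or
a samples x species TSV) are held in a plain pandas DataFrame: rows are
samples, columns are species, values are non-negative integer read-pair
counts.  Relative abundance divides each species count by the sample's
total microbial read count.  A species is called *present* in a sample
only when it clears both an abundance and an absolute read-count
threshold; everything else is set to zero read counts so that downstream
stages see a consistent matrix.
"""

from __future__ import annotations

import glob
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DataError

#: default thresholds: entries at or below these are counted as absent
RA_THRESHOLD = 0.005
COUNT_THRESHOLD = 10
MIN_TOTAL_READS = 100


@dataclass
class SampleProfile:
    """Species-level read-pair counts for one sample."""

    sample_id: str
    counts: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for sp, c in self.counts.items():
            if c < 0:
                raise DataError(
                    f"negative read count for {sp!r} in sample {self.sample_id!r}"
                )


def parse_kraken2_report(path: str, sample_id: str | None = None) -> SampleProfile:
    """Parse a standard 6-column Kraken2 report into species-level counts.

    Only rank-code ``S`` rows are kept.  The clade-level read count
    (column 2) is used, so reads assigned to subspecies/strains roll up
    into their species.  Leading indentation in the name field is
    stripped.  An empty file yields an empty profile.
    """
    if sample_id is None:
        sample_id = os.path.basename(path)
        for suffix in (".kraken2.report", ".kreport", ".report", ".tsv", ".txt"):
            if sample_id.endswith(suffix):
                sample_id = sample_id[: -len(suffix)]
                break
    counts: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 6:
                raise DataError(
                    f"{path}: line {lineno}: expected 6 tab-separated columns, "
                    f"got {len(fields)}"
                )
            rank = fields[3].strip()
            if rank != "S":
                continue
            try:
                clade_reads = int(fields[1])
            except ValueError as exc:
                raise DataError(
                    f"{path}: line {lineno}: clade read count {fields[1]!r} "
                    "is not an integer"
                ) from exc
            name = fields[5].strip()
            counts[name] = counts.get(name, 0) + clade_reads
    return SampleProfile(sample_id=sample_id, counts=counts)


def parse_kraken2_reports(directory: str, pattern: str = "*") -> list[SampleProfile]:
    """Parse every report file in *directory* (one report per sample)."""
    paths = sorted(glob.glob(os.path.join(directory, pattern)))
    return [parse_kraken2_report(p) for p in paths if os.path.isfile(p)]


def build_count_matrix(profiles: list[SampleProfile]) -> pd.DataFrame:
    """Assemble per-sample profiles into a samples x species count matrix.

    The species axis is the union over samples; missing entries are 0.
    """
    ids = [p.sample_id for p in profiles]
    dupes = {s for s in ids if ids.count(s) > 1}
    if dupes:
        raise DataError(f"duplicate sample ids: {sorted(dupes)}")
    if not profiles:
        return pd.DataFrame(dtype=np.int64)
    mat = pd.DataFrame.from_dict(
        {p.sample_id: p.counts for p in profiles}, orient="index"
    )
    mat = mat.fillna(0).astype(np.int64)
    mat = mat.reindex(index=ids, columns=sorted(mat.columns))
    mat.index.name = "sample_id"
    return mat


def total_reads(counts: pd.DataFrame) -> pd.Series:
    """Per-sample total microbial read-pair count (row sums)."""
    return counts.sum(axis=1)


def qc_samples(counts: pd.DataFrame, min_total: int = MIN_TOTAL_READS) -> pd.DataFrame:
    """Drop samples with fewer than *min_total* microbial read pairs.

    Samples with a total >= *min_total* are retained.  Species columns
    that become all-zero are deliberately kept; the decontamination
    read-count filter handles them later.
    """
    if counts.empty:
        return counts
    keep = total_reads(counts) >= min_total
    return counts.loc[keep]


def relative_abundance(counts: pd.DataFrame) -> pd.DataFrame:
    """Row-normalise counts to per-sample relative abundances in [0, 1]."""
    totals = total_reads(counts)
    if (totals <= 0).any():
        bad = totals.index[totals <= 0].tolist()
        raise DataError(
            f"samples with zero microbial reads (run qc_samples first): {bad[:5]}"
        )
    return counts.div(totals, axis=0)


@dataclass
class PresenceMatrix:
    """Presence/absence calls plus the zeroed count matrix behind them.

    ``abundance`` keeps the relative abundances computed against the
    *original* per-sample totals; zeroing absent entries does not change
    the denominator.
    """

    present: pd.DataFrame            # bool, samples x species
    zeroed_counts: pd.DataFrame      # int, absent entries set to 0
    abundance: pd.DataFrame          # float, original-denominator RA
    totals: pd.Series                # original per-sample totals
    ra_threshold: float = RA_THRESHOLD
    count_threshold: int = COUNT_THRESHOLD
    rule: str = "both"

    @property
    def samples(self) -> pd.Index:
        return self.present.index

    @property
    def species(self) -> pd.Index:
        return self.present.columns

    def species_detected(self) -> list[str]:
        """Species present in at least one sample."""
        return self.present.columns[self.present.any(axis=0)].tolist()


def call_presence(
    counts: pd.DataFrame,
    ra_threshold: float = RA_THRESHOLD,
    count_threshold: int = COUNT_THRESHOLD,
    rule: str = "both",
    totals: pd.Series | None = None,
) -> PresenceMatrix:
    """Call species presence per sample and zero out absent entries.

    With ``rule="both"`` (default) an entry is present only when its
    read-pair count exceeds *count_threshold* AND its relative abundance
    exceeds *ra_threshold*; failing either threshold marks it absent.
    ``rule="either"`` is the permissive alternative (present when either
    threshold is exceeded).  *totals* supplies the denominators when
    re-calling presence on an already-zeroed matrix; by default the row
    sums of *counts* are used.
    """
    if ra_threshold < 0 or count_threshold < 0:
        raise DataError("presence thresholds must be non-negative")
    if rule not in ("both", "either"):
        raise DataError(f"unknown presence rule {rule!r}")
    if totals is None:
        totals = total_reads(counts)
    if (totals <= 0).any():
        bad = totals.index[totals <= 0].tolist()
        raise DataError(f"samples with zero total reads: {bad[:5]}")
    abundance = counts.div(totals, axis=0)
    above_count = counts.gt(count_threshold)
    above_ra = abundance.gt(ra_threshold)
    if rule == "both":
        present = above_count & above_ra
    else:
        present = above_count | above_ra
    zeroed = counts.where(present, 0).astype(np.int64)
    return PresenceMatrix(
        present=present,
        zeroed_counts=zeroed,
        abundance=abundance,
        totals=totals,
        ra_threshold=ra_threshold,
        count_threshold=count_threshold,
        rule=rule,
    )


# ---------------------------------------------------------------- I/O

def read_count_matrix_tsv(path: str) -> pd.DataFrame:
    """Read a samples x species TSV (first column sample_id, header species)."""
    mat = pd.read_csv(path, sep="\t", index_col=0)
    if mat.index.has_duplicates:
        raise DataError(f"{path}: duplicate sample ids")
    if mat.columns.has_duplicates:
        raise DataError(f"{path}: duplicate species names")
    try:
        mat = mat.astype(np.int64)
    except (ValueError, TypeError) as exc:
        raise DataError(f"{path}: non-integer counts") from exc
    if (mat.to_numpy() < 0).any():
        raise DataError(f"{path}: negative counts")
    mat.index = mat.index.astype(str)
    mat.index.name = "sample_id"
    return mat


def write_count_matrix_tsv(counts: pd.DataFrame, path: str) -> None:
    counts.to_csv(path, sep="\t", index_label="sample_id")


def write_presence_tsv(present: pd.DataFrame, path: str) -> None:
    present.astype(int).to_csv(path, sep="\t", index_label="sample_id")


def read_metadata_tsv(path: str) -> pd.DataFrame:
    """Read per-sample batch metadata (sample_id plus one column per variable)."""
    meta = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if meta.index.has_duplicates:
        raise DataError(f"{path}: duplicate sample ids in metadata")
    meta.index = meta.index.astype(str)
    meta.index.name = "sample_id"
    if meta.isna().any().any() or (meta == "").any().any():
        raise DataError(f"{path}: empty batch labels in metadata")
    return meta


def check_metadata_covers(counts: pd.DataFrame, meta: pd.DataFrame) -> None:
    """Every sample in the count matrix must have a metadata row."""
    missing = counts.index.difference(meta.index)
    if len(missing):
        raise DataError(
            f"{len(missing)} samples missing from metadata, e.g. "
            f"{missing[:3].tolist()}"
        )
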