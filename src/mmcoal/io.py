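"""Alignment and sample-metadata input/output.

Reads pre-aligned consensus allele sequences (one haploid sequence per
individual, FASTA) together with a tab-separated metadata table assigning each
individual a sampling locality, a regional label (North/South) and an
ingroup/outgroup role.  Provides haplogroup classification by a diagnostic
site and the segregating-site table used downstream.

Coordinates are 1-based inclusive column indices throughout.  Columns
containing a gap ("-") or an ambiguous base ("N") in any retained ingroup
sequence are excluded from ``effective_length`` and from all per-site
statistics; this single rule keeps S, theta_S and pi mutually consistent.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

VALID_REGIONS = ("North", "South", "none")
VALID_ROLES = ("ingroup", "outgroup")

METADATA_COLUMNS = ("id", "locality", "region", "role", "taxon")

BASES = ("A", "C", "G", "T")
MISSING = ("-", "N")


class AlignmentError(ValueError):
    """Sequences do not form a valid alignment."""


class MetadataError(ValueError):
    """Metadata table inconsistent with the FASTA records."""


@dataclasses.dataclass(frozen=True)
class SampleRecord:
    """Per-individual metadata: identifier, locality code, region, role."""

    id: str
    locality: str
    region: str = "none"
    role: str = "ingroup"
    taxon: str = ""

    def __post_init__(self) -> None:
        if self.region not in VALID_REGIONS:
            raise MetadataError(
                f"sample {self.id!r}: region {self.region!r} not in {VALID_REGIONS}"
            )
        if self.role not in VALID_ROLES:
            raise MetadataError(
                f"sample {self.id!r}: role {self.role!r} not in {VALID_ROLES}"
            )
        if self.role == "outgroup" and self.region != "none":
            raise MetadataError(
                f"outgroup sample {self.id!r} must have region 'none'"
            )


class LabeledAlignment:
    """Aligned haploid sequences with per-sample metadata.

    Parameters
    ----------
    samples
        Ordered sample records, one per sequence.
    matrix
        2-D array of single characters over {A, C, G, T, -, N}, one row per
        sample.  Lower-case input is upper-cased.
    """

    def __init__(self, samples: Sequence[SampleRecord], matrix: np.ndarray) -> None:
        samples = list(samples)
        matrix = np.char.upper(np.asarray(matrix, dtype="U1"))
        if matrix.ndim != 2:
            raise AlignmentError("matrix must be 2-D (samples x columns)")
        if len(samples) != matrix.shape[0]:
            raise AlignmentError(
                f"{len(samples)} sample records but {matrix.shape[0]} sequences"
            )
        ids = [s.id for s in samples]
        if len(set(ids)) != len(ids):
            raise MetadataError("duplicate sample ids")
        bad = set(np.unique(matrix)) - set(BASES) - set(MISSING)
        if bad:
            raise AlignmentError(f"invalid characters in alignment: {sorted(bad)}")
        self.samples = samples
        self.matrix = matrix

    # -- basic accessors -------------------------------------------------
    @property
    def length(self) -> int:
        return self.matrix.shape[1]

    @property
    def n(self) -> int:
        return self.matrix.shape[0]

    @property
    def ids(self) -> list[str]:
        return [s.id for s in self.samples]

    def index_of(self, sample_id: str) -> int:
        try:
            return self.ids.index(sample_id)
        except ValueError:
            raise MetadataError(f"unknown sample id {sample_id!r}") from None

    def ingroup_indices(self) -> np.ndarray:
        return np.array(
            [i for i, s in enumerate(self.samples) if s.role == "ingroup"], dtype=int
        )

    def outgroup_indices(self) -> np.ndarray:
        return np.array(
            [i for i, s in enumerate(self.samples) if s.role == "outgroup"], dtype=int
        )

    def ingroup(self) -> "LabeledAlignment":
        idx = self.ingroup_indices()
        return LabeledAlignment([self.samples[i] for i in idx], self.matrix[idx])

    def subset(self, sample_ids: Iterable[str]) -> "LabeledAlignment":
        idx = [self.index_of(s) for s in sample_ids]
        return LabeledAlignment([self.samples[i] for i in idx], self.matrix[idx])

    # -- retained columns ------------------------------------------------
    def retained_mask(self) -> np.ndarray:
        """Boolean mask of columns free of gaps and Ns in every ingroup row."""
        ing = self.matrix[self.ingroup_indices()]
        missing = (ing == "-") | (ing == "N")
        return ~missing.any(axis=0)

    @property
    def effective_length(self) -> int:
        return int(self.retained_mask().sum())

    def column(self, pos: int) -> np.ndarray:
        """Alignment column at 1-based position ``pos``."""
        if not 1 <= pos <= self.length:
            raise IndexError(
                f"column {pos} out of range [1, {self.length}]"
            )
        return self.matrix[:, pos - 1]

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"LabeledAlignment(n={self.n}, length={self.length}, "
            f"effective_length={self.effective_length})"
        )


def read_alignment(fasta_path: str | Path, metadata_path: str | Path) -> LabeledAlignment:
    """Read a FASTA alignment plus its metadata table.

    Every FASTA record id must appear exactly once in the metadata and vice
    versa; all records must have equal length.  Input sample order (FASTA
    order) is preserved.
    """
    records = list(SeqIO.parse(str(fasta_path), "fasta"))
    if not records:
        raise AlignmentError(f"no FASTA records in {fasta_path}")
    lengths = {len(r.seq) for r in records}
    if len(lengths) != 1:
        offender = next(r for r in records if len(r.seq) != len(records[0].seq))
        raise AlignmentError(
            f"record {offender.id!r} has length {len(offender.seq)}, "
            f"expected {len(records[0].seq)}"
        )
    meta = read_metadata(metadata_path)
    fasta_ids = [r.id for r in records]
    if len(set(fasta_ids)) != len(fasta_ids):
        raise MetadataError("duplicate FASTA record ids")
    missing = set(fasta_ids) - set(meta.index)
    if missing:
        raise MetadataError(f"FASTA ids absent from metadata: {sorted(missing)}")
    extra = set(meta.index) - set(fasta_ids)
    if extra:
        raise MetadataError(f"metadata ids absent from FASTA: {sorted(extra)}")
    samples = [
        SampleRecord(
            id=rid,
            locality=str(meta.at[rid, "locality"]),
            region=str(meta.at[rid, "region"]),
            role=str(meta.at[rid, "role"]),
            taxon=str(meta.at[rid, "taxon"]),
        )
        for rid in fasta_ids
    ]
    matrix = np.array([list(str(r.seq).upper()) for r in records], dtype="U1")
    return LabeledAlignment(samples, matrix)


def read_metadata(metadata_path: str | Path) -> pd.DataFrame:
    """Read the tab-separated metadata table (id, locality, region, role, taxon)."""
    try:
        meta = pd.read_csv(metadata_path, sep="\t", dtype=str)
    except pd.errors.EmptyDataError:
        raise MetadataError(f"empty metadata file {metadata_path}") from None
    missing_cols = set(METADATA_COLUMNS) - set(meta.columns)
    if missing_cols:
        raise MetadataError(f"metadata missing columns: {sorted(missing_cols)}")
    if meta["id"].duplicated().any():
        dupes = meta.loc[meta["id"].duplicated(), "id"].tolist()
        raise MetadataError(f"duplicate metadata ids: {dupes}")
    return meta.set_index("id", drop=False).fillna("")


def write_alignment(
    aln: LabeledAlignment, fasta_path: str | Path, metadata_path: str | Path | None = None
) -> None:
    """Write FASTA (and optionally the metadata table) back to disk."""
    records = [
        SeqRecord(Seq("".join(row)), id=s.id, description="")
        for s, row in zip(aln.samples, aln.matrix)
    ]
    SeqIO.write(records, str(fasta_path), "fasta")
    if metadata_path is not None:
        write_metadata(aln.samples, metadata_path)


def write_metadata(samples: Sequence[SampleRecord], metadata_path: str | Path) -> None:
    df = pd.DataFrame(
        [(s.id, s.locality, s.region, s.role, s.taxon) for s in samples],
        columns=list(METADATA_COLUMNS),
    )
    df.to_csv(metadata_path, sep="\t", index=False)


def classify_haplogroup(
    aln: LabeledAlignment, diagnostic_column: int, allele_map: Mapping[str, str]
) -> list[str]:
    """Label each ingroup sample by its base at one diagnostic column.

    Bases not covered by ``allele_map`` (including gaps and Ns) are labelled
    ``"unassigned"``.  A pure function of the single diagnostic column.
    """
    if len(allele_map) < 2:
        raise ValueError("allele_map must cover at least 2 bases")
    col = aln.column(diagnostic_column)
    mapping = {k.upper(): v for k, v in allele_map.items()}
    return [
        mapping.get(col[i], "unassigned") for i in aln.ingroup_indices()
    ]


def segregating_site_table(aln: LabeledAlignment) -> pd.DataFrame:
    """Table of columns polymorphic among ingroup samples.

    One row per segregating column with the 1-based column index, per-sample
    alleles, and major/minor allele counts.  Gap/N never counts as an allele,
    and per the missing-data rule columns with any ingroup gap/N are excluded
    entirely, so every row has >= 2 distinct alleles among ingroup samples.
    """
    ing_idx = aln.ingroup_indices()
    if len(ing_idx) < 2:
        raise ValueError("need at least 2 ingroup samples")
    ing = aln.matrix[ing_idx]
    ids = [aln.samples[i].id for i in ing_idx]
    mask = aln.retained_mask()
    rows = []
    for j in np.nonzero(mask)[0]:
        col = ing[:, j]
        alleles, counts = np.unique(col, return_counts=True)
        if len(alleles) < 2:
            continue
        order = np.argsort(counts)[::-1]
        alleles, counts = alleles[order], counts[order]
        row: dict[str, object] = {"position": int(j) + 1}
        row.update({sid: col[i] for i, sid in enumerate(ids)})
        row["major_allele"] = alleles[0]
        row["major_count"] = int(counts[0])
        row["minor_allele"] = alleles[-1]
        row["minor_count"] = int(counts[-1])
        row["n_alleles"] = len(alleles)
        rows.append(row)
    cols = ["position", *ids, "major_allele", "major_count", "minor_allele",
            "minor_count", "n_alleles"]
    return pd.DataFrame(rows, columns=cols)


def write_site_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False)
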