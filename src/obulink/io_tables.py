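"""Shared tabular data model and readers/writers for the formats the pipeline touches.

The common currency of every stage is the :class:`CountMatrix`, a features x
samples table of non-negative abundances (16S ASVs or KS/AD OBUs).  All
on-disk tables are plain TSV (tab-separated, no quoting, UTF-8); sequences
travel as FASTQ (Phred+33) and FASTA.
"""

from __future__ import annotations

import dataclasses
import io
import os
from dataclasses import dataclass, field
from typing import IO, Iterable, Iterator, Optional, Sequence

import numpy as np
import pandas as pd

RANKS = ("domain", "phylum", "class", "order", "family", "genus", "species")

SOURCES = ("seawater", "sediment", "soil")
MEDIA = ("none", "MBA", "MBG", "SWA", "SWG")

FEATURE_KINDS = ("ASV", "OBU_KS", "OBU_AD")


class ParseError(ValueError):
    """Malformed input file; message names the offending record/row."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SequenceRecord:
    """One sequencing read: id, DNA sequence, optional Phred qualities, sample."""

    read_id: str
    sequence: str
    qualities: Optional[tuple[int, ...]] = None
    sample_id: str = ""

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"read {self.read_id!r}: empty sequence")
        if self.qualities is not None and len(self.qualities) != len(self.sequence):
            raise ValueError(
                f"read {self.read_id!r}: quality length {len(self.qualities)} "
                f"!= sequence length {len(self.sequence)}"
            )


@dataclass
class CountMatrix:
    """Feature-by-sample abundance table.

    ``counts`` is a features x samples array; integer-valued unless
    ``normalized`` is set (total-sum scaling produces fractional values).
    """

    feature_ids: list[str]
    sample_ids: list[str]
    counts: np.ndarray
    feature_kind: str = "ASV"
    normalized: bool = False

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.shape != (len(self.feature_ids), len(self.sample_ids)):
            raise ValueError(
                f"counts shape {self.counts.shape} inconsistent with "
                f"{len(self.feature_ids)} features x {len(self.sample_ids)} samples"
            )
        if len(set(self.feature_ids)) != len(self.feature_ids):
            raise ValueError("duplicate feature ids")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample ids")
        if np.any(self.counts < 0):
            raise ValueError("negative counts")
        if self.feature_kind not in FEATURE_KINDS:
            raise ValueError(f"unknown feature_kind {self.feature_kind!r}")
        if not self.normalized and not np.allclose(self.counts, np.round(self.counts)):
            raise ValueError("non-integer counts in an un-normalized matrix")

    # -- convenience -------------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.counts, index=self.feature_ids, columns=self.sample_ids)
        df.index.name = "feature_id"
        return df

    @classmethod
    def from_frame(
        cls, df: pd.DataFrame, feature_kind: str = "ASV", normalized: bool = False
    ) -> "CountMatrix":
        return cls(
            feature_ids=[str(i) for i in df.index],
            sample_ids=[str(c) for c in df.columns],
            counts=df.to_numpy(dtype=float),
            feature_kind=feature_kind,
            normalized=normalized,
        )

    def select_samples(self, sample_ids: Sequence[str]) -> "CountMatrix":
        idx = [self.sample_ids.index(s) for s in sample_ids]
        return CountMatrix(
            feature_ids=list(self.feature_ids),
            sample_ids=list(sample_ids),
            counts=self.counts[:, idx].copy(),
            feature_kind=self.feature_kind,
            normalized=self.normalized,
        )

    def select_features(self, feature_ids: Sequence[str]) -> "CountMatrix":
        idx = [self.feature_ids.index(f) for f in feature_ids]
        return CountMatrix(
            feature_ids=list(feature_ids),
            sample_ids=list(self.sample_ids),
            counts=self.counts[idx, :].copy(),
            feature_kind=self.feature_kind,
            normalized=self.normalized,
        )


@dataclass
class TaxonomyTable:
    """feature_id -> 7-rank lineage; unassigned ranks carry 'unclassified_<parent>'.

    Encoding missing ranks as ``unclassified_<parent>`` keeps genus aggregation
    total: every species maps to exactly one (possibly unclassified) genus.
    """

    lineages: dict[str, dict[str, str]]

    def __post_init__(self) -> None:
        for fid, lineage in self.lineages.items():
            missing = [r for r in RANKS if r not in lineage]
            if missing:
                raise ValueError(f"{fid}: missing ranks {missing}")
            # ranks must form a path: no assigned rank below an unclassified one
            seen_unclassified = False
            for r in RANKS:
                unc = lineage[r].startswith("unclassified")
                if seen_unclassified and not unc:
                    raise ValueError(
                        f"{fid}: rank {r} assigned below an unclassified rank"
                    )
                seen_unclassified = seen_unclassified or unc

    def rank_of(self, feature_id: str, rank: str) -> str:
        return self.lineages[feature_id][rank]

    @classmethod
    def from_assignments(cls, partial: dict[str, dict[str, str]]) -> "TaxonomyTable":
        """Fill unassigned ranks with unclassified_<nearest assigned ancestor>."""
        out = {}
        for fid, lineage in partial.items():
            filled = {}
            parent = "root"
            broken = False
            for r in RANKS:
                name = lineage.get(r)
                if name and not broken:
                    filled[r] = name
                    parent = name
                else:
                    # once a rank is missing, everything below stays
                    # unclassified so lineages remain proper paths
                    broken = True
                    filled[r] = f"unclassified_{parent}"
            out[fid] = filled
        return cls(out)


@dataclass
class SampleMetadata:
    """sample_id -> environmental source, culture medium, replicate label."""

    records: dict[str, dict[str, str]]

    def __post_init__(self) -> None:
        for sid, rec in self.records.items():
            if rec.get("source") not in SOURCES:
                raise ValueError(f"sample {sid}: unknown source {rec.get('source')!r}")
            if rec.get("medium") not in MEDIA:
                raise ValueError(f"sample {sid}: unknown medium {rec.get('medium')!r}")

    def source(self, sample_id: str) -> str:
        return self.records[sample_id]["source"]

    def medium(self, sample_id: str) -> str:
        return self.records[sample_id]["medium"]

    def samples_for(self, source: Optional[str] = None, medium: Optional[str] = None) -> list[str]:
        out = []
        for sid, rec in self.records.items():
            if source is not None and rec["source"] != source:
                continue
            if medium is not None and rec["medium"] != medium:
                continue
            out.append(sid)
        return out

    def require_covers(self, matrix: CountMatrix) -> None:
        missing = [s for s in matrix.sample_ids if s not in self.records]
        if missing:
            raise ValueError(f"samples without metadata: {missing}")


# ---------------------------------------------------------------------------
# FASTQ / FASTA
# ---------------------------------------------------------------------------


def read_fastq(path: str | os.PathLike | IO[str], sample_id: str = "") -> Iterator[SequenceRecord]:
    """Yield reads from a 4-line-per-record FASTQ file (Sanger/Phred+33).

    Raises :class:`ParseError` naming the 1-based record index on any
    malformed record (bad header, length mismatch, truncation).
    """
    close = False
    if hasattr(path, "read"):
        handle = path
    else:
        handle = open(path, "r", encoding="utf-8")
        close = True
    try:
        idx = 0
        while True:
            header = handle.readline()
            if not header:
                return
            if header.strip() == "" and not handle.readline():
                return  # trailing blank line
            idx += 1
            seq = handle.readline()
            plus = handle.readline()
            qual = handle.readline()
            if not qual:
                raise ParseError(f"record {idx}: truncated FASTQ record")
            header, seq, plus, qual = (s.rstrip("\n") for s in (header, seq, plus, qual))
            if not header.startswith("@"):
                raise ParseError(f"record {idx}: header does not start with '@'")
            if not plus.startswith("+"):
                raise ParseError(f"record {idx}: separator line does not start with '+'")
            if len(seq) != len(qual):
                raise ParseError(
                    f"record {idx}: quality length {len(qual)} != sequence length {len(seq)}"
                )
            if not seq:
                raise ParseError(f"record {idx}: empty sequence")
            phred = tuple(ord(c) - 33 for c in qual)
            if any(q < 0 for q in phred):
                raise ParseError(f"record {idx}: quality character below '!'")
            yield SequenceRecord(
                read_id=header[1:].split()[0],
                sequence=seq.upper(),
                qualities=phred,
                sample_id=sample_id,
            )
    finally:
        if close:
            handle.close()


def write_fastq(records: Iterable[SequenceRecord], path: str | os.PathLike | IO[str]) -> None:
    close = False
    if hasattr(path, "write"):
        handle = path
    else:
        handle = open(path, "w", encoding="utf-8")
        close = True
    try:
        for rec in records:
            qual = rec.qualities or tuple([30] * len(rec.sequence))
            handle.write(
                f"@{rec.read_id}\n{rec.sequence}\n+\n"
                + "".join(chr(q + 33) for q in qual)
                + "\n"
            )
    finally:
        if close:
            handle.close()


def write_fasta(clusters: Iterable, path: str | os.PathLike | IO[str]) -> None:
    """Write cluster centroids as FASTA, one record per cluster id.

    Accepts any iterable of objects with ``obu_id`` and ``centroid``
    attributes, or (id, sequence) tuples.
    """
    close = False
    if hasattr(path, "write"):
        handle = path
    else:
        handle = open(path, "w", encoding="utf-8")
        close = True
    try:
        for c in clusters:
            if isinstance(c, tuple):
                cid, seq = c
            else:
                cid, seq = c.obu_id, c.centroid
            if not seq:
                raise ValueError(f"cluster {cid}: empty centroid sequence")
            handle.write(f">{cid}\n{seq}\n")
    finally:
        if close:
            handle.close()


def read_fasta(path: str | os.PathLike | IO[str]) -> list[tuple[str, str]]:
    close = False
    if hasattr(path, "read"):
        handle = path
    else:
        handle = open(path, "r", encoding="utf-8")
        close = True
    try:
        out: list[tuple[str, str]] = []
        name = None
        chunks: list[str] = []
        for line in handle:
            line = line.rstrip("\n")
            if line.startswith(">"):
                if name is not None:
                    out.append((name, "".join(chunks)))
                name = line[1:].split()[0]
                chunks = []
            elif line:
                if name is None:
                    raise ParseError("sequence data before first FASTA header")
                chunks.append(line.upper())
        if name is not None:
            out.append((name, "".join(chunks)))
        return out
    finally:
        if close:
            handle.close()


# ---------------------------------------------------------------------------
# TSV tables
# ---------------------------------------------------------------------------


def read_count_table(
    path: str | os.PathLike | IO[str], feature_kind: str = "ASV", normalized: bool = False
) -> CountMatrix:
    """Read a TSV count table (first column feature_id, header row of samples).

    Integer cells unless ``normalized``; any negative or non-numeric cell is a
    :class:`ParseError` naming the row and column.
    """
    df = _read_tsv(path)
    if df.columns[0] != "feature_id":
        raise ParseError(f"first column must be 'feature_id', got {df.columns[0]!r}")
    feature_ids = [str(v) for v in df.iloc[:, 0]]
    dupes = pd.Series(feature_ids)[pd.Series(feature_ids).duplicated()].tolist()
    if dupes:
        raise ParseError(f"duplicated feature ids: {sorted(set(dupes))}")
    sample_ids = [str(c) for c in df.columns[1:]]
    counts = np.empty((len(feature_ids), len(sample_ids)), dtype=float)
    for j, col in enumerate(df.columns[1:]):
        for i, raw in enumerate(df[col]):
            try:
                val = float(raw)
            except (TypeError, ValueError):
                raise ParseError(
                    f"non-numeric cell at row {feature_ids[i]!r}, column {col!r}: {raw!r}"
                ) from None
            if val < 0:
                raise ParseError(f"negative cell at row {feature_ids[i]!r}, column {col!r}")
            if not normalized and val != int(val):
                raise ParseError(
                    f"non-integer cell at row {feature_ids[i]!r}, column {col!r}: {raw!r}"
                )
            counts[i, j] = val
    return CountMatrix(feature_ids, sample_ids, counts, feature_kind, normalized)


def write_count_table(matrix: CountMatrix, path: str | os.PathLike | IO[str]) -> None:
    """Write a CountMatrix as TSV; lossless round-trip with read_count_table."""
    close = False
    if hasattr(path, "write"):
        handle = path
    else:
        handle = open(path, "w", encoding="utf-8")
        close = True
    try:
        handle.write("\t".join(["feature_id", *matrix.sample_ids]) + "\n")
        for i, fid in enumerate(matrix.feature_ids):
            if matrix.normalized:
                cells = [repr(float(v)) for v in matrix.counts[i]]
            else:
                cells = [str(int(round(v))) for v in matrix.counts[i]]
            handle.write("\t".join([fid, *cells]) + "\n")
    finally:
        if close:
            handle.close()


def read_taxonomy(path: str | os.PathLike | IO[str]) -> TaxonomyTable:
    """Read a TSV taxonomy table: feature_id + one column per rank."""
    df = _read_tsv(path)
    expected = ["feature_id", *RANKS]
    if list(df.columns) != expected:
        raise ParseError(f"taxonomy header must be {expected}, got {list(df.columns)}")
    lineages = {}
    for _, row in df.iterrows():
        fid = str(row["feature_id"])
        if fid in lineages:
            raise ParseError(f"duplicated feature id {fid!r} in taxonomy")
        lineages[fid] = {r: str(row[r]) for r in RANKS}
    return TaxonomyTable(lineages)


def write_taxonomy(tax: TaxonomyTable, path: str | os.PathLike | IO[str]) -> None:
    close = False
    if hasattr(path, "write"):
        handle = path
    else:
        handle = open(path, "w", encoding="utf-8")
        close = True
    try:
        handle.write("feature_id\t" + "\t".join(RANKS) + "\n")
        for fid in tax.lineages:
            handle.write(fid + "\t" + "\t".join(tax.lineages[fid][r] for r in RANKS) + "\n")
    finally:
        if close:
            handle.close()


def read_sample_metadata(path: str | os.PathLike | IO[str]) -> SampleMetadata:
    df = _read_tsv(path)
    expected = ["sample_id", "source", "medium", "replicate"]
    if list(df.columns) != expected:
        raise ParseError(f"metadata header must be {expected}, got {list(df.columns)}")
    records = {}
    for _, row in df.iterrows():
        sid = str(row["sample_id"])
        if sid in records:
            raise ParseError(f"duplicated sample id {sid!r} in metadata")
        records[sid] = {
            "source": str(row["source"]),
            "medium": str(row["medium"]),
            "replicate": str(row["replicate"]),
        }
    return SampleMetadata(records)


def write_sample_metadata(meta: SampleMetadata, path: str | os.PathLike | IO[str]) -> None:
    close = False
    if hasattr(path, "write"):
        handle = path
    else:
        handle = open(path, "w", encoding="utf-8")
        close = True
    try:
        handle.write("sample_id\tsource\tmedium\treplicate\n")
        for sid, rec in meta.records.items():
            handle.write(f"{sid}\t{rec['source']}\t{rec['medium']}\t{rec['replicate']}\n")
    finally:
        if close:
            handle.close()


def _read_tsv(path: str | os.PathLike | IO[str]) -> pd.DataFrame:
    try:
        df = pd.read_csv(
            path, sep="\t", dtype=str, header=0, quoting=3, keep_default_na=False
        )
    except pd.errors.EmptyDataError:
        raise ParseError("empty table file") from None
    return df
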