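"""Sequence and annotation I/O.

Reads the formats the pipeline consumes (4-line FASTQ, optionally
gzip-compressed; FASTA; a 3-column exon-boundary table; a minimal GTF
subset) and defines the two core containers, :class:`SequenceRecord` and
:class:`TranscriptModel`.

Conventions used throughout the package:

* All coordinates are 1-based and inclusive on transcript sequences
  (``donor_pos 1322`` means the 1322nd base of the donor mRNA).
* Sequences are normalised to uppercase DNA over ``{A, C, G, T, N}``:
  lowercase is uppercased, ``U`` (RNA) becomes ``T``, anything else
  becomes ``N``.
* Base qualities are carried through FASTQ round-trips but never
  interpreted; the detection method is quality-blind.
"""

from __future__ import annotations

import gzip
import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Optional, Sequence, Union

import pandas as pd
from Bio import SeqIO

PathLike = Union[str, Path]

_VALID = set("ACGTN")
_NORMALISE = {ord(c): "N" for c in "BDEFHIJKLMOPQRSVWXYZ"}
_NORMALISE[ord("U")] = "T"


class ParseError(ValueError):
    """Malformed input file."""


def normalise_seq(seq: str) -> str:
    """Uppercase, map U->T (RNA input) and any other symbol to N."""
    return seq.upper().translate(_NORMALISE)


@dataclass
class SequenceRecord:
    """A named DNA sequence with optional per-base qualities."""

    id: str
    seq: str
    qual: Optional[str] = None

    def __post_init__(self) -> None:
        self.seq = normalise_seq(self.seq)
        if not self.seq:
            raise ValueError(f"record {self.id!r}: empty sequence")
        if self.qual is not None and len(self.qual) != len(self.seq):
            raise ValueError(
                f"record {self.id!r}: quality length {len(self.qual)} != "
                f"sequence length {len(self.seq)}"
            )

    def __len__(self) -> int:
        return len(self.seq)


@dataclass
class TranscriptModel:
    """An mRNA with its exon structure and optional CDS interval.

    ``exon_ends`` holds the 1-based transcript coordinate of the *last*
    base of each exon, in exon order; the last entry must equal the
    transcript length. ``cds_start``/``cds_end`` (1-based, inclusive,
    stop codon included) are optional and only consumed by the reading
    frame check.
    """

    transcript_id: str
    gene: str
    seq: str
    exon_ends: list[int] = field(default_factory=list)
    cds_start: Optional[int] = None
    cds_end: Optional[int] = None

    def __post_init__(self) -> None:
        self.seq = normalise_seq(self.seq)
        if not self.seq:
            raise ValueError(f"{self.transcript_id}: empty sequence")
        self.exon_ends = [int(e) for e in self.exon_ends]
        if not self.exon_ends:
            self.exon_ends = [len(self.seq)]
        if any(b <= a for a, b in zip(self.exon_ends, self.exon_ends[1:])):
            raise ValueError(
                f"{self.transcript_id}: exon_ends not strictly increasing: "
                f"{self.exon_ends}"
            )
        if self.exon_ends[0] < 1:
            raise ValueError(f"{self.transcript_id}: exon_ends must be >= 1")
        if self.exon_ends[-1] != len(self.seq):
            raise ValueError(
                f"{self.transcript_id}: last exon end {self.exon_ends[-1]} != "
                f"sequence length {len(self.seq)}"
            )
        if (self.cds_start is None) != (self.cds_end is None):
            raise ValueError(f"{self.transcript_id}: cds_start/cds_end must come together")
        if self.cds_start is not None:
            if not (1 <= self.cds_start < self.cds_end <= len(self.seq)):
                raise ValueError(
                    f"{self.transcript_id}: invalid CDS interval "
                    f"[{self.cds_start}, {self.cds_end}]"
                )
            if (self.cds_end - self.cds_start + 1) % 3:
                raise ValueError(
                    f"{self.transcript_id}: CDS length not a multiple of 3"
                )

    def __len__(self) -> int:
        return len(self.seq)

    @property
    def n_exons(self) -> int:
        return len(self.exon_ends)

    def exon_start(self, exon_index: int) -> int:
        """1-based transcript coordinate of the first base of an exon."""
        self._check_exon(exon_index)
        return 1 if exon_index == 1 else self.exon_ends[exon_index - 2] + 1

    def exon_end(self, exon_index: int) -> int:
        self._check_exon(exon_index)
        return self.exon_ends[exon_index - 1]

    def exon_of(self, pos: int) -> int:
        """Index (1-based) of the exon containing transcript position ``pos``."""
        if not 1 <= pos <= len(self.seq):
            raise ValueError(f"{self.transcript_id}: position {pos} out of range")
        for i, end in enumerate(self.exon_ends, start=1):
            if pos <= end:
                return i
        raise AssertionError("unreachable")

    def _check_exon(self, exon_index: int) -> None:
        if not 1 <= exon_index <= self.n_exons:
            raise ValueError(
                f"{self.transcript_id}: exon {exon_index} does not exist "
                f"(transcript has {self.n_exons} exons)"
            )


# ---------------------------------------------------------------------------
# FASTQ
# ---------------------------------------------------------------------------

def _open_text(path: PathLike, compressed: Optional[bool] = None,
               mode: str = "rt") -> io.TextIOBase:
    path = Path(path)
    if compressed is None:
        compressed = path.suffix == ".gz"
    if compressed:
        return gzip.open(path, mode)  # type: ignore[return-value]
    return open(path, mode)


def read_fastq(path: PathLike, compressed: Optional[bool] = None
               ) -> Iterator[SequenceRecord]:
    """Stream records from a 4-line FASTQ file, transparently gunzipping.

    Strict 4-line records are required (one line each of header, sequence,
    separator, quality) so that every sequence line the scanner sees is a
    complete read — the same guarantee ``grep`` on an unwrapped FASTQ gives.
    Raises :class:`ParseError` naming the offending line for truncated
    records, malformed headers/separators, and seq/qual length mismatches.
    """
    with _open_text(path, compressed) as fh:
        lineno = 0
        while True:
            header = fh.readline()
            if header == "":
                return
            lineno += 1
            header = header.rstrip("\n")
            if not header.startswith("@"):
                raise ParseError(f"{path}: line {lineno}: expected '@' header, "
                                 f"got {header[:30]!r}")
            block = [fh.readline() for _ in range(3)]
            if any(line == "" for line in block):
                raise ParseError(
                    f"{path}: truncated FASTQ record starting at line {lineno}"
                )
            seq, sep, qual = (line.rstrip("\n") for line in block)
            if not sep.startswith("+"):
                raise ParseError(f"{path}: line {lineno + 2}: expected '+' "
                                 f"separator, got {sep[:30]!r}")
            if len(seq) != len(qual):
                raise ParseError(
                    f"{path}: line {lineno + 3}: quality length {len(qual)} "
                    f"!= sequence length {len(seq)}"
                )
            yield SequenceRecord(id=header[1:].split()[0], seq=seq, qual=qual)
            lineno += 3


def write_fastq(records: Iterable[SequenceRecord], path: PathLike,
                compressed: Optional[bool] = None) -> int:
    """Write 4-line FASTQ (gzip if the path ends in .gz); returns record count."""
    n = 0
    with _open_text(path, compressed, "wt") as fh:
        for rec in records:
            qual = rec.qual if rec.qual is not None else "I" * len(rec.seq)
            fh.write(f"@{rec.id}\n{rec.seq}\n+\n{qual}\n")
            n += 1
    return n


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: PathLike) -> list[SequenceRecord]:
    """Read FASTA into a list of records (order preserved).

    Ids are the first whitespace-separated token of the header. Empty files
    and duplicate ids are errors.
    """
    with _open_text(path) as fh:
        records = [
            SequenceRecord(id=r.id, seq=str(r.seq))
            for r in SeqIO.parse(fh, "fasta")
        ]
    if not records:
        raise ParseError(f"{path}: no FASTA records found")
    seen: set[str] = set()
    for rec in records:
        if rec.id in seen:
            raise ParseError(f"{path}: duplicate FASTA id {rec.id!r}")
        seen.add(rec.id)
    return records


def write_fasta(records: Iterable[SequenceRecord], path: PathLike,
                width: int = 70) -> int:
    n = 0
    with _open_text(path, mode="wt") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.seq), width):
                fh.write(rec.seq[i:i + width] + "\n")
            n += 1
    return n


# ---------------------------------------------------------------------------
# Exon tables and transcript models
# ---------------------------------------------------------------------------

EXON_TABLE_COLUMNS = ["transcript_id", "exon_index", "exon_end"]


def read_exon_table(path: PathLike) -> pd.DataFrame:
    """Read a TSV with columns transcript_id/exon_index/exon_end.

    Optional columns ``gene``, ``cds_start`` and ``cds_end`` (constant per
    transcript) are carried through when present.
    """
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in EXON_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: exon table lacks columns {missing}")
    return df


def write_exon_table(df: pd.DataFrame, path: PathLike) -> None:
    df.to_csv(path, sep="\t", index=False)


def load_transcript_model(fasta: PathLike, exon_table: PathLike,
                          transcript_id: Optional[str] = None,
                          gene: Optional[str] = None,
                          cds_start: Optional[int] = None,
                          cds_end: Optional[int] = None) -> TranscriptModel:
    """Combine a FASTA sequence with its exon-boundary table.

    When ``transcript_id`` is omitted the FASTA must contain exactly one
    record. Validates exon monotonicity and that the last exon end equals
    the sequence length. CDS coordinates may come from the function
    arguments or from optional ``cds_start``/``cds_end`` table columns.
    """
    records = {r.id: r for r in read_fasta(fasta)}
    if transcript_id is None:
        if len(records) != 1:
            raise ValueError(
                f"{fasta} holds {len(records)} records; transcript_id required"
            )
        transcript_id = next(iter(records))
    if transcript_id not in records:
        raise ValueError(f"transcript {transcript_id!r} not in {fasta}")
    table = read_exon_table(exon_table)
    rows = table[table["transcript_id"] == transcript_id]
    if rows.empty:
        raise ValueError(f"transcript {transcript_id!r} not in exon table {exon_table}")
    rows = rows.sort_values("exon_index")
    if list(rows["exon_index"]) != list(range(1, len(rows) + 1)):
        raise ParseError(
            f"{exon_table}: exon_index for {transcript_id!r} is not 1..n"
        )
    if gene is None:
        gene = str(rows["gene"].iloc[0]) if "gene" in rows.columns else transcript_id
    if cds_start is None and "cds_start" in rows.columns:
        v = rows["cds_start"].iloc[0]
        if pd.notna(v):
            cds_start, cds_end = int(v), int(rows["cds_end"].iloc[0])
    return TranscriptModel(
        transcript_id=transcript_id,
        gene=gene,
        seq=records[transcript_id].seq,
        exon_ends=[int(e) for e in rows["exon_end"]],
        cds_start=cds_start,
        cds_end=cds_end,
    )


def read_gtf_exons(path: PathLike) -> pd.DataFrame:
    """Project exon features of a GTF subset onto transcript coordinates.

    Convenience reader: consumes only ``exon`` feature rows carrying
    ``transcript_id`` (and optionally ``gene_id``) attributes, orders the
    exons 5'->3' (descending genomic start on the minus strand) and returns
    the cumulative-length exon table the rest of the package uses. Anything
    beyond exon order and boundary coordinates is ignored.
    """
    exons: dict[str, list[tuple[int, int, str, str]]] = {}
    with _open_text(path) as fh:
        for raw in fh:
            if not raw.strip() or raw.startswith("#"):
                continue
            parts = raw.rstrip("\n").split("\t")
            if len(parts) < 9 or parts[2] != "exon":
                continue
            attrs = dict(
                (kv.strip().split(" ", 1)[0],
                 kv.strip().split(" ", 1)[1].strip().strip('"'))
                for kv in parts[8].rstrip(";").split(";") if kv.strip()
            )
            tid = attrs.get("transcript_id")
            if tid is None:
                raise ParseError(f"{path}: exon row without transcript_id")
            exons.setdefault(tid, []).append(
                (int(parts[3]), int(parts[4]), parts[6], attrs.get("gene_id", tid))
            )
    rows = []
    for tid, feats in exons.items():
        strand = feats[0][2]
        feats.sort(key=lambda f: f[0], reverse=(strand == "-"))
        total = 0
        for i, (start, end, _, gene_id) in enumerate(feats, start=1):
            total += end - start + 1
            rows.append({"transcript_id": tid, "exon_index": i,
                         "exon_end": total, "gene": gene_id})
    if not rows:
        raise ParseError(f"{path}: no exon features found")
    return pd.DataFrame(rows)
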