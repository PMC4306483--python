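"""Exact anchor search over FASTQ streams — ``grep`` semantics.

Every read is searched for every anchor k-mer as an exact substring, in
both orientations, with zero mismatch tolerance. This deliberately
mirrors running ``grep <kmer>`` on the sequence lines of a FASTQ file,
which is the discovery operation the pipeline is built around; the only
differences are that records are parsed (so header/quality lines can
never match) and that reverse-complement matches are found too.

Hits are orientation-normalised: a read matching the reverse-complement
anchor is stored reverse-complemented, so ``read_seq`` is always in
transcript orientation and downstream split alignment needs no strand
logic. Memory is bounded by the number of hits, not the input size.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Iterator

import pandas as pd

from .anchors import Anchor, reverse_complement
from .seqio import PathLike, SequenceRecord

logger = logging.getLogger(__name__)


@dataclass
class ReadHit:
    """One anchor occurrence in one (orientation-normalised) read."""

    read_id: str
    read_seq: str
    anchor: Anchor
    offset: int  # 1-based position of the anchor's first base in read_seq
    source_orientation: str  # "as_read" | "reverse_complemented"

    def __post_init__(self) -> None:
        k = self.anchor.k
        if not 1 <= self.offset <= len(self.read_seq) - k + 1:
            raise ValueError(f"hit offset {self.offset} out of range")
        if self.read_seq[self.offset - 1:self.offset - 1 + k] != self.anchor.forward_seq:
            raise ValueError("read_seq does not carry the anchor at offset")


def _occurrences(haystack: str, needle: str) -> Iterator[int]:
    """Yield 0-based positions of all (possibly overlapping) occurrences."""
    i = haystack.find(needle)
    while i != -1:
        yield i
        i = haystack.find(needle, i + 1)


def scan_reads(reads: Iterable[SequenceRecord],
               anchors: list[Anchor]) -> list[ReadHit]:
    """Single pass over ``reads`` collecting exact anchor hits.

    A read is reported once per distinct (boundary anchor, offset); the
    forward and revcomp orientations of the same boundary k-mer count as
    one anchor for this purpose. Reads shorter than an anchor are skipped
    silently; unmatched reads produce nothing (an empty result is valid).
    """
    if not anchors:
        raise ValueError("anchor list is empty")
    # One searcher per distinct boundary k-mer, regardless of how many
    # orientation variants were supplied.
    searchers: dict[tuple, Anchor] = {}
    for a in anchors:
        searchers.setdefault(a.key + (a.forward_seq,), a)
    hits: list[ReadHit] = []
    n_reads = 0
    for read in reads:
        n_reads += 1
        rc_cache: str | None = None
        seen: set[tuple] = set()
        for key, anchor in searchers.items():
            fwd = anchor.forward_seq
            if len(fwd) > len(read.seq):
                continue
            for i in _occurrences(read.seq, fwd):
                tag = (key, i + 1, "as_read")
                if tag not in seen:
                    seen.add(tag)
                    hits.append(ReadHit(read_id=read.id, read_seq=read.seq,
                                        anchor=anchor, offset=i + 1,
                                        source_orientation="as_read"))
            rc_anchor = reverse_complement(fwd)
            for i in _occurrences(read.seq, rc_anchor):
                if rc_cache is None:
                    rc_cache = reverse_complement(read.seq)
                offset = len(read.seq) - i - len(fwd) + 1
                tag = (key, offset, "reverse_complemented")
                if tag not in seen:
                    seen.add(tag)
                    hits.append(ReadHit(read_id=read.id, read_seq=rc_cache,
                                        anchor=anchor, offset=offset,
                                        source_orientation="reverse_complemented"))
    logger.info("scanned %d reads with %d anchor k-mer(s): %d hit(s)",
                n_reads, len(searchers), len(hits))
    for key in searchers:
        n = sum(1 for h in hits if h.anchor.key + (h.anchor.forward_seq,) == key)
        logger.info("anchor %s (%s exon %d %s): %d hit(s)",
                    key[3], key[0], key[1], key[2], n)
    return hits


def count_matches(reads: Iterable[SequenceRecord], anchor: Anchor) -> int:
    """Number of (read, offset) occurrences of one anchor, both orientations.

    Equals ``len(scan_reads(reads, [anchor]))``; streaming counterpart for
    presence/absence checks such as scanning for a reciprocal-fusion
    anchor that should find nothing.
    """
    return len(scan_reads(reads, [anchor]))


HIT_COLUMNS = ["read_id", "offset", "anchor_seq", "orientation", "read_seq",
               "transcript_id", "exon_index", "side", "boundary_pos", "k"]


def write_hits(hits: Iterable[ReadHit], path: PathLike) -> None:
    rows = [{
        "read_id": h.read_id, "offset": h.offset,
        "anchor_seq": h.anchor.forward_seq, "orientation": h.source_orientation,
        "read_seq": h.read_seq, "transcript_id": h.anchor.transcript_id,
        "exon_index": h.anchor.exon_index, "side": h.anchor.side,
        "boundary_pos": h.anchor.boundary_pos, "k": h.anchor.k,
    } for h in hits]
    pd.DataFrame(rows, columns=HIT_COLUMNS).to_csv(path, sep="\t", index=False)


def read_hits(path: PathLike) -> list[ReadHit]:
    df = pd.read_csv(path, sep="\t")
    out = []
    for r in df.itertuples():
        anchor = Anchor(seq=str(r.anchor_seq), transcript_id=str(r.transcript_id),
                        exon_index=int(r.exon_index), side=str(r.side),
                        boundary_pos=int(r.boundary_pos), orientation="forward",
                        k=int(r.k))
        out.append(ReadHit(read_id=str(r.read_id), read_seq=str(r.read_seq),
                           anchor=anchor, offset=int(r.offset),
                           source_orientation=str(r.orientation)))
    return out
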