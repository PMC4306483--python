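"""Exon-boundary anchor k-mers.

A fusion created by a genomic rearrangement plus splicing joins the two
partner mRNAs at exon boundaries, so a k-mer taken flush against an exon
boundary of the candidate gene is the highest-yield exact search term for
junction-spanning reads: reads from the wild-type transcript contain it
too, but only a chimeric read continues into foreign sequence right after
it. Anchors are emitted in both orientations because the sequencer reads
either strand of the cDNA.

The default k of 20 gives, for 100 bp reads, an expected chance-hit rate
of about 81 * 4**-20 ~ 7e-11 per read; the enforced CLI minimum of 12
keeps that below ~5e-6.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import pandas as pd

from .seqio import PathLike, TranscriptModel

logger = logging.getLogger(__name__)

SIDES = ("exon_end", "exon_start")
DEFAULT_K = 20
MIN_K = 12

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    """Reverse complement over {A,C,G,T,N}; error on any other symbol."""
    bad = set(seq) - set("ACGTN")
    if bad:
        raise ValueError(f"illegal symbol(s) in sequence: {sorted(bad)}")
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class Anchor:
    """An exon-boundary k-mer with provenance.

    ``boundary_pos`` is the 1-based transcript coordinate of the boundary
    base: for ``side="exon_end"`` the anchor covers transcript positions
    ``[boundary_pos-k+1, boundary_pos]``; for ``side="exon_start"`` it
    covers ``[boundary_pos, boundary_pos+k-1]``. ``seq`` is the k-mer as
    searched; for ``orientation="revcomp"`` it is the reverse complement
    of the transcript substring.
    """

    seq: str
    transcript_id: str
    exon_index: int
    side: str
    boundary_pos: int
    orientation: str
    k: int

    def __post_init__(self) -> None:
        if self.side not in SIDES:
            raise ValueError(f"side must be one of {SIDES}, got {self.side!r}")
        if self.orientation not in ("forward", "revcomp"):
            raise ValueError(f"bad orientation {self.orientation!r}")
        if len(self.seq) != self.k:
            raise ValueError(f"anchor seq length {len(self.seq)} != k={self.k}")

    @property
    def forward_seq(self) -> str:
        """The anchor k-mer in transcript orientation."""
        return self.seq if self.orientation == "forward" else reverse_complement(self.seq)

    @property
    def key(self) -> tuple[str, int, str]:
        """Identity of the underlying boundary k-mer, orientation-free."""
        return (self.transcript_id, self.exon_index, self.side)

    def donor_span(self) -> tuple[int, int]:
        """Transcript interval (1-based, inclusive) covered by the anchor."""
        if self.side == "exon_end":
            return self.boundary_pos - self.k + 1, self.boundary_pos
        return self.boundary_pos, self.boundary_pos + self.k - 1


def design_anchors(model: TranscriptModel, k: int = DEFAULT_K,
                   exons: Optional[Sequence[int]] = None,
                   sides: Sequence[str] = SIDES,
                   min_k: int = MIN_K) -> list[Anchor]:
    """Derive boundary anchors for the requested exons and sides.

    Emits a forward and a reverse-complement anchor per (exon, side),
    ordered by exon index, then side (exon_end first), then orientation.
    Anchors containing N are suppressed with a warning since exact
    matching of N is undefined. ``k`` below ``min_k`` or larger than the
    exon is an error.
    """
    if k < min_k:
        raise ValueError(f"k={k} below minimum anchor length {min_k}")
    for side in sides:
        if side not in SIDES:
            raise ValueError(f"side must be one of {SIDES}, got {side!r}")
    exon_list = sorted(set(int(e) for e in exons)) if exons is not None \
        else list(range(1, model.n_exons + 1))
    out: list[Anchor] = []
    for exon in exon_list:
        start, end = model.exon_start(exon), model.exon_end(exon)
        if end - start + 1 < k:
            raise ValueError(
                f"{model.transcript_id}: exon {exon} is {end - start + 1} nt, "
                f"shorter than k={k}"
            )
        for side in [s for s in SIDES if s in sides]:
            if side == "exon_end":
                boundary, kmer = end, model.seq[end - k:end]
            else:
                boundary, kmer = start, model.seq[start - 1:start - 1 + k]
            if "N" in kmer:
                logger.warning(
                    "suppressing anchor at %s exon %d %s: contains N",
                    model.transcript_id, exon, side,
                )
                continue
            for orientation, seq in (("forward", kmer),
                                     ("revcomp", reverse_complement(kmer))):
                out.append(Anchor(seq=seq, transcript_id=model.transcript_id,
                                  exon_index=exon, side=side,
                                  boundary_pos=boundary,
                                  orientation=orientation, k=k))
    return out


ANCHOR_COLUMNS = ["seq", "transcript_id", "exon_index", "side",
                  "boundary_pos", "orientation", "k"]


def write_anchors(anchors: Iterable[Anchor], path: PathLike) -> None:
    pd.DataFrame([vars(a) for a in anchors])[ANCHOR_COLUMNS].to_csv(
        path, sep="\t", index=False)


def read_anchors(path: PathLike) -> list[Anchor]:
    df = pd.read_csv(path, sep="\t")
    return [Anchor(seq=r.seq, transcript_id=str(r.transcript_id),
                   exon_index=int(r.exon_index), side=r.side,
                   boundary_pos=int(r.boundary_pos),
                   orientation=r.orientation, k=int(r.k))
            for r in df.itertuples()]
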