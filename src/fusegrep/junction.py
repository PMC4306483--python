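"""Split alignment of anchor-bearing reads and junction calling.

Each read recruited by the anchor scan is partitioned into a segment
explained by the candidate transcript and a segment explained by a
partner sequence. Alignment is *exact maximal extension* — mismatch-free,
like the anchor search itself: starting from the anchor's known placement
on the candidate, the match is extended base-by-base in both directions;
the unexplained remainder is seeded into a k-mer index of the partner
set and likewise extended exactly. Sequencing errors are tolerated only
insofar as each flank must reach ``min_flank`` matched bases, not by
scored alignment.

When the two partners share bases at the junction (microhomology) the
breakpoint is ambiguous within that window; the canonical call assigns
all shared bases to the donor, so a junction is reported as the last
donor base followed by the first acceptor base after the homology block.
Partner hits on the reverse strand are supported (genomic partner
regions may be transcribed in either direction) and flagged, with
coordinates reported on the forward strand of the supplied sequence.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence, Union

import pandas as pd

from .anchors import Anchor, reverse_complement
from .scan import ReadHit
from .seqio import PathLike, SequenceRecord, TranscriptModel

logger = logging.getLogger(__name__)

DEFAULT_MIN_FLANK = 20
DEFAULT_SEED_LEN = 16


@dataclass
class SplitAlignment:
    """A read partitioned into donor-matching and acceptor-matching parts.

    Read coordinates are 1-based on the orientation-normalised read.
    ``microhomology_len > 0``, a non-empty ``insertion_seq`` and a blunt
    junction are mutually exclusive outcomes.
    """

    read_id: str
    read_seq: str
    donor_ref_id: str
    donor_read_end: int       # last read base matching the donor
    donor_ref_pos: int        # donor coordinate aligned to donor_read_end
    acceptor_ref_id: str
    acceptor_read_start: int  # first read base matching the acceptor
    acceptor_ref_pos: int     # acceptor coordinate aligned to acceptor_read_start
    microhomology_len: int
    insertion_seq: str
    acceptor_orientation: str = "forward"  # strand of the partner sequence
    donor_read_start: int = 1
    acceptor_read_end: int = 0

    def __post_init__(self) -> None:
        if self.acceptor_read_end == 0:
            self.acceptor_read_end = len(self.read_seq)
        expected_mh = max(0, self.donor_read_end - self.acceptor_read_start + 1)
        if self.microhomology_len != expected_mh:
            raise ValueError("inconsistent microhomology length")
        gap = self.acceptor_read_start - self.donor_read_end - 1
        if (gap > 0) != bool(self.insertion_seq) or (gap > 0 and len(self.insertion_seq) != gap):
            raise ValueError("insertion_seq inconsistent with read coordinates")


@dataclass
class NoCall:
    """A read that could not be split-aligned, with the reason why."""

    read_id: str
    reason: str  # "short_flank" | "ambiguous" | "no_partner_match" | "short_donor_flank"
    loci: list[tuple] = field(default_factory=list)


@dataclass
class JunctionCall:
    """A canonical junction aggregated over supporting reads."""

    donor_id: str
    donor_pos: int
    acceptor_id: str
    acceptor_pos: int
    support: int
    microhomology_len: int
    insertion_seq: str
    acceptor_orientation: str = "forward"
    in_frame: Optional[bool] = None

    def __post_init__(self) -> None:
        if self.support < 1:
            raise ValueError("support must be >= 1")


class PartnerIndex:
    """Exact k-mer index over a partner search set, both strands."""

    def __init__(self, partners: Sequence[SequenceRecord],
                 seed_len: int = DEFAULT_SEED_LEN):
        if not partners:
            raise ValueError("partner set is empty")
        self.seed_len = seed_len
        self.partners = {p.id: p.seq for p in partners}
        if len(self.partners) != len(partners):
            raise ValueError("duplicate partner ids")
        # kmer -> list of (partner_id, orientation, 0-based position in the
        # oriented sequence)
        self.index: dict[str, list[tuple[str, str, int]]] = defaultdict(list)
        for pid, seq in self.partners.items():
            for orientation, s in (("forward", seq),
                                   ("revcomp", reverse_complement(seq))):
                for i in range(len(s) - seed_len + 1):
                    kmer = s[i:i + seed_len]
                    if "N" not in kmer:
                        self.index[kmer].append((pid, orientation, i))

    def oriented_seq(self, pid: str, orientation: str) -> str:
        seq = self.partners[pid]
        return seq if orientation == "forward" else reverse_complement(seq)


def _extend(read: str, ref: str, read_pos0: int, ref_pos0: int) -> tuple[int, int]:
    """Maximal exact extension of a diagonal; returns 0-based read [lo, hi]."""
    lo = read_pos0
    while lo > 0 and ref_pos0 - (read_pos0 - lo) - 1 >= 0 \
            and read[lo - 1] == ref[ref_pos0 - (read_pos0 - lo) - 1]:
        lo -= 1
    hi = read_pos0
    while hi + 1 < len(read) and ref_pos0 + (hi - read_pos0) + 1 < len(ref) \
            and read[hi + 1] == ref[ref_pos0 + (hi - read_pos0) + 1]:
        hi += 1
    return lo, hi


def split_align(hit: ReadHit, donor: TranscriptModel,
                partners: Union[PartnerIndex, Sequence[SequenceRecord]],
                min_flank: int = DEFAULT_MIN_FLANK,
                seed_len: int = DEFAULT_SEED_LEN) -> Union[SplitAlignment, NoCall]:
    """Split one anchor hit into candidate- and partner-matching parts.

    For an ``exon_end`` anchor the candidate transcript is the 5' (donor)
    fusion partner and the partner set is searched with the read suffix;
    for an ``exon_start`` anchor the roles are mirrored. Both flanks must
    reach ``min_flank`` exactly matched bases or the read is a no-call;
    distinct partner loci tying on maximal extension give an ambiguous
    no-call listing the loci.
    """
    if not isinstance(partners, PartnerIndex):
        partners = PartnerIndex(partners, seed_len=seed_len)
    seed_len = partners.seed_len
    anchor = hit.anchor
    if anchor.transcript_id != donor.transcript_id:
        raise ValueError(
            f"hit anchor belongs to {anchor.transcript_id!r}, "
            f"not {donor.transcript_id!r}"
        )
    read = hit.read_seq
    span_start, span_end = anchor.donor_span()
    # Verify and extend the anchor placement on the candidate transcript.
    if donor.seq[span_start - 1:span_end] != anchor.forward_seq:
        raise ValueError("anchor sequence does not match the donor transcript")
    read_a0 = hit.offset - 1                # 0-based anchor start in read
    ref_a0 = span_start - 1                 # 0-based anchor start in donor
    c_lo, c_hi = _extend(read, donor.seq, read_a0, ref_a0)
    cand_len = c_hi - c_lo + 1
    if cand_len < min_flank:
        return NoCall(hit.read_id, "short_donor_flank")
    diag = ref_a0 - read_a0                 # donor coord0 = read coord0 + diag

    if anchor.side == "exon_end":
        unexplained = (c_hi + 1, len(read) - 1)    # 0-based inclusive
    else:
        unexplained = (0, c_lo - 1)
    useg_len = unexplained[1] - unexplained[0] + 1
    if useg_len < seed_len:
        return NoCall(hit.read_id, "short_flank")

    # Seed every k-mer of the unexplained segment; collect candidate loci
    # as (partner, orientation, diagonal) and extend each exactly once.
    loci: dict[tuple[str, str, int], tuple[int, int]] = {}
    for s in range(unexplained[0], unexplained[1] - seed_len + 2):
        kmer = read[s:s + seed_len]
        for pid, orientation, pos in partners.index.get(kmer, ()):
            d = pos - s
            key = (pid, orientation, d)
            ext = _extend(read, partners.oriented_seq(pid, orientation), s, pos)
            prev = loci.get(key)
            if prev is None or ext[1] - ext[0] > prev[1] - prev[0]:
                loci[key] = ext
    if not loci:
        return NoCall(hit.read_id, "no_partner_match")
    best_span = max(hi - lo + 1 for lo, hi in loci.values())
    best = [(key, lohi) for key, lohi in loci.items()
            if lohi[1] - lohi[0] + 1 == best_span]
    if best_span < min_flank:
        return NoCall(hit.read_id, "short_flank")
    distinct = {(key[0], key[1], key[2]) for key, _ in best}
    if len(distinct) > 1:
        return NoCall(hit.read_id, "ambiguous", loci=sorted(distinct))
    (pid, orientation, pdiag), (p_lo, p_hi) = best[0]
    oriented_len = len(partners.oriented_seq(pid, orientation))

    def partner_fwd_pos(read_pos0: int) -> int:
        """1-based forward-strand partner coordinate for a read position."""
        pos0 = read_pos0 + pdiag
        if orientation == "forward":
            return pos0 + 1
        return oriented_len - pos0

    if anchor.side == "exon_end":
        donor_read_end0, acceptor_read_start0 = c_hi, p_lo
        donor_ref_pos = donor_read_end0 + diag + 1
        acceptor_ref_pos = partner_fwd_pos(acceptor_read_start0)
        donor_id, acceptor_id = donor.transcript_id, pid
        donor_read_start0, acceptor_read_end0 = c_lo, p_hi
    else:
        donor_read_end0, acceptor_read_start0 = p_hi, c_lo
        donor_ref_pos = partner_fwd_pos(donor_read_end0)
        acceptor_ref_pos = acceptor_read_start0 + diag + 1
        donor_id, acceptor_id = pid, donor.transcript_id
        donor_read_start0, acceptor_read_end0 = p_lo, c_hi
    gap = acceptor_read_start0 - donor_read_end0 - 1
    insertion = read[donor_read_end0 + 1:acceptor_read_start0] if gap > 0 else ""
    return SplitAlignment(
        read_id=hit.read_id, read_seq=read,
        donor_ref_id=donor_id,
        donor_read_end=donor_read_end0 + 1,
        donor_ref_pos=donor_ref_pos,
        acceptor_ref_id=acceptor_id,
        acceptor_read_start=acceptor_read_start0 + 1,
        acceptor_ref_pos=acceptor_ref_pos,
        microhomology_len=max(0, donor_read_end0 - acceptor_read_start0 + 1),
        insertion_seq=insertion,
        acceptor_orientation=orientation if anchor.side == "exon_end" else "forward",
        donor_read_start=donor_read_start0 + 1,
        acceptor_read_end=acceptor_read_end0 + 1,
    )


def canonicalise(split: SplitAlignment) -> tuple[int, int]:
    """Donor-maximal canonical breakpoint (donor_pos, acceptor_pos).

    Within a microhomology window every shared base is assigned to the
    donor: the donor breakpoint is the donor coordinate at
    ``donor_read_end`` and the acceptor breakpoint is the acceptor
    coordinate aligned to the following read position. Idempotent, and
    the identity for blunt or inserted junctions.
    """
    donor_pos = split.donor_ref_pos
    shift = split.donor_read_end + 1 - split.acceptor_read_start
    if shift <= 0:  # blunt or insertion: acceptor coordinate unchanged
        return donor_pos, split.acceptor_ref_pos
    if split.acceptor_orientation == "forward":
        return donor_pos, split.acceptor_ref_pos + shift
    return donor_pos, split.acceptor_ref_pos - shift


def call_junctions(splits: Iterable[Union[SplitAlignment, NoCall]],
                   min_support: int = 1) -> list[JunctionCall]:
    """Aggregate split alignments into canonical junction calls.

    Splits agreeing on the canonical (donor, donor_pos, acceptor,
    acceptor_pos, insertion, strand) are merged; calls below
    ``min_support`` are dropped; output is sorted by support (desc), then
    donor_pos (asc) to break ties.
    """
    groups: dict[tuple, list[SplitAlignment]] = defaultdict(list)
    for s in splits:
        if isinstance(s, NoCall):
            continue
        donor_pos, acceptor_pos = canonicalise(s)
        key = (s.donor_ref_id, donor_pos, s.acceptor_ref_id, acceptor_pos,
               s.insertion_seq, s.acceptor_orientation)
        groups[key].append(s)
    calls = [
        JunctionCall(
            donor_id=key[0], donor_pos=key[1], acceptor_id=key[2],
            acceptor_pos=key[3], support=len(members),
            microhomology_len=max(m.microhomology_len for m in members),
            insertion_seq=key[4], acceptor_orientation=key[5],
        )
        for key, members in groups.items()
        if len(members) >= min_support
    ]
    calls.sort(key=lambda c: (-c.support, c.donor_pos))
    return calls


JUNCTION_COLUMNS = ["donor_id", "donor_pos", "acceptor_id", "acceptor_pos",
                    "support", "microhomology_len", "insertion_seq",
                    "acceptor_orientation", "in_frame"]


def write_junctions(calls: Iterable[JunctionCall], path: PathLike) -> None:
    pd.DataFrame([vars(c) for c in calls], columns=JUNCTION_COLUMNS).to_csv(
        path, sep="\t", index=False)


def junctions_to_json(calls: Iterable[JunctionCall]) -> list[dict]:
    return [vars(c) for c in calls]
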