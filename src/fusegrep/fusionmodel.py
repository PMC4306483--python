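"""Fusion-transcript assembly, ORF prediction and domain bookkeeping.

Given a canonical junction (last donor base, first acceptor base) the
predicted fusion mRNA is simply donor[1..donor_pos] + acceptor
[acceptor_pos..end]. From it the longest ATG-initiated open reading
frame is taken as the putative coding sequence; the reported ORF length
excludes the stop codon, so protein length is always ORF length / 3.
Frame preservation across the junction is checked from the wild-type CDS
annotations alone: the fusion is in-frame iff the donor's codon phase at
the junction is continued by the acceptor's phase, i.e.

    (donor_pos - donor.cds_start + 1) mod 3 == (acceptor_pos - acceptor.cds_start) mod 3.

Protein domains of the wild-type partners are classified as retained,
truncated or lost in the fusion protein by intersecting their wild-type
amino-acid intervals with the donor-derived prefix / acceptor-derived
suffix of the fusion protein.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional

import pandas as pd
from Bio.Seq import Seq

from .seqio import PathLike, TranscriptModel

logger = logging.getLogger(__name__)

STOP_CODONS = ("TAA", "TAG", "TGA")


@dataclass
class FusionTranscript:
    """An assembled chimeric mRNA with exon, ORF and protein annotation."""

    seq: str
    donor_id: str
    acceptor_id: str
    donor_pos: int
    acceptor_pos: int
    junction_offset: int                  # position in seq of the last donor base
    donor_exons: list[int] = field(default_factory=list)
    acceptor_exons: list[int] = field(default_factory=list)
    orf_start: Optional[int] = None       # 1-based, stop codon excluded
    orf_end: Optional[int] = None
    protein: Optional[str] = None
    in_frame: Optional[bool] = None

    @property
    def orf_length(self) -> Optional[int]:
        if self.orf_start is None:
            return None
        return self.orf_end - self.orf_start + 1

    @property
    def donor_protein_junction_aa(self) -> Optional[int]:
        """Number of donor-derived residues in the fusion protein.

        A codon is donor-derived if it starts at or before the junction
        (the junction codon, when split, is counted to the donor). None
        when there is no ORF or the ORF lies entirely in the acceptor part.
        """
        if self.orf_start is None or self.orf_start > self.junction_offset:
            return None
        return (self.junction_offset - self.orf_start) // 3 + 1


@dataclass
class DomainRecord:
    """A named protein domain in wild-type amino-acid coordinates."""

    name: str
    source: str  # "donor" | "acceptor"
    aa_start: int
    aa_end: int

    def __post_init__(self) -> None:
        if self.source not in ("donor", "acceptor"):
            raise ValueError(f"bad domain source {self.source!r}")
        if not 1 <= self.aa_start <= self.aa_end:
            raise ValueError(f"bad domain interval [{self.aa_start}, {self.aa_end}]")


def assemble_fusion(donor: TranscriptModel, donor_pos: int,
                    acceptor: TranscriptModel, acceptor_pos: int) -> FusionTranscript:
    """Concatenate donor[1..donor_pos] with acceptor[acceptor_pos..end].

    Retained exons: every donor exon ending at or before the cut plus the
    exon containing it (a cut exactly at an exon's last base therefore
    retains whole exons only), and the acceptor exon containing the
    acceptor breakpoint plus everything downstream. ORF/protein fields
    are left unset; see :func:`annotate_fusion`.
    """
    if not 1 <= donor_pos <= len(donor.seq):
        raise ValueError(f"donor_pos {donor_pos} outside {donor.transcript_id}")
    if not 1 <= acceptor_pos <= len(acceptor.seq):
        raise ValueError(f"acceptor_pos {acceptor_pos} outside {acceptor.transcript_id}")
    seq = donor.seq[:donor_pos] + acceptor.seq[acceptor_pos - 1:]
    donor_last = donor.exon_of(donor_pos)
    acceptor_first = acceptor.exon_of(acceptor_pos)
    return FusionTranscript(
        seq=seq,
        donor_id=donor.transcript_id, acceptor_id=acceptor.transcript_id,
        donor_pos=donor_pos, acceptor_pos=acceptor_pos,
        junction_offset=donor_pos,
        donor_exons=list(range(1, donor_last + 1)),
        acceptor_exons=list(range(acceptor_first, acceptor.n_exons + 1)),
    )


def find_orf(seq: str) -> Optional[tuple[int, int, str]]:
    """Longest ATG-initiated ORF with an in-frame stop, forward strand.

    Returns (orf_start, orf_end, protein) with 1-based inclusive
    coordinates excluding the stop codon, or None when no ATG-initiated
    ORF terminates before the sequence ends. Ties on length are broken by
    the smaller start coordinate. All three frames are searched; the
    transcript orientation is known, so the reverse strand is not.
    """
    if not seq:
        raise ValueError("empty sequence")
    best: Optional[tuple[int, int]] = None  # (length, start0)
    for frame in range(3):
        next_stop: Optional[int] = None  # 0-based start of next in-frame stop
        # Walk codons right-to-left, tracking the nearest downstream stop.
        starts = range(frame, len(seq) - 2, 3)
        stops_after: dict[int, Optional[int]] = {}
        for i in reversed(starts):
            codon = seq[i:i + 3]
            if codon in STOP_CODONS:
                next_stop = i
            stops_after[i] = next_stop
        for i in starts:
            if seq[i:i + 3] == "ATG":
                stop = stops_after[i]
                if stop is not None and stop > i:
                    length = stop - i
                    if best is None or length > best[0] or \
                            (length == best[0] and i < best[1]):
                        best = (length, i)
    if best is None:
        return None
    length, start0 = best
    orf = seq[start0:start0 + length]
    protein = str(Seq(orf).translate(table=1))
    return start0 + 1, start0 + length, protein


def check_in_frame(donor: TranscriptModel, donor_pos: int,
                   acceptor: TranscriptModel, acceptor_pos: int) -> Optional[bool]:
    """Does the acceptor continue the donor's reading frame at the junction?

    True/False from the phase comparison above; None (unknown) when either
    CDS annotation is missing or the junction falls outside either CDS
    (the reason is logged).
    """
    if donor.cds_start is None or acceptor.cds_start is None:
        logger.info("in-frame check unknown: CDS annotation missing")
        return None
    if not donor.cds_start <= donor_pos <= donor.cds_end:
        logger.info("in-frame check unknown: donor breakpoint %d outside CDS "
                    "[%d, %d]", donor_pos, donor.cds_start, donor.cds_end)
        return None
    if not acceptor.cds_start <= acceptor_pos <= acceptor.cds_end:
        logger.info("in-frame check unknown: acceptor breakpoint %d outside CDS "
                    "[%d, %d]", acceptor_pos, acceptor.cds_start, acceptor.cds_end)
        return None
    return bool((donor_pos - donor.cds_start + 1) % 3
                == (acceptor_pos - acceptor.cds_start) % 3)


def annotate_fusion(fusion: FusionTranscript,
                    donor: Optional[TranscriptModel] = None,
                    acceptor: Optional[TranscriptModel] = None) -> FusionTranscript:
    """Fill ORF, protein and in-frame fields of an assembled fusion in place."""
    orf = find_orf(fusion.seq)
    if orf is not None:
        fusion.orf_start, fusion.orf_end, fusion.protein = orf
    if donor is not None and acceptor is not None:
        fusion.in_frame = check_in_frame(donor, fusion.donor_pos,
                                         acceptor, fusion.acceptor_pos)
    return fusion


def map_domains(fusion: FusionTranscript,
                donor_domains: Iterable[DomainRecord],
                acceptor_domains: Iterable[DomainRecord],
                donor_protein_junction_aa: int,
                acceptor_protein_junction_aa: int = 1,
                donor_protein_len: Optional[int] = None,
                acceptor_protein_len: Optional[int] = None) -> list[dict]:
    """Classify wild-type domains as retained / truncated / lost in the fusion.

    ``donor_protein_junction_aa`` is the number of donor-derived residues
    in the fusion protein; ``acceptor_protein_junction_aa`` is the
    wild-type acceptor residue at which the acceptor-derived suffix
    begins. Retained/truncated domains get their mapped fusion-protein
    coordinates. Domains outside the supplied wild-type protein lengths
    are errors.
    """
    if fusion.protein is None:
        raise ValueError("fusion has no ORF/protein; run annotate_fusion first")
    dj = donor_protein_junction_aa
    aj = acceptor_protein_junction_aa
    suffix_len = len(fusion.protein) - dj
    report: list[dict] = []
    for dom in donor_domains:
        if donor_protein_len is not None and dom.aa_end > donor_protein_len:
            raise ValueError(f"domain {dom.name} outside donor protein "
                             f"(length {donor_protein_len})")
        if dom.aa_end <= dj:
            status, lo, hi = "retained", dom.aa_start, dom.aa_end
        elif dom.aa_start > dj:
            status, lo, hi = "lost", None, None
        else:
            status, lo, hi = "truncated", dom.aa_start, dj
        report.append({"name": dom.name, "source": "donor", "status": status,
                       "wt_start": dom.aa_start, "wt_end": dom.aa_end,
                       "fusion_start": lo, "fusion_end": hi})
    acc_lo, acc_hi = aj, aj + suffix_len - 1  # wild-type residues present
    for dom in acceptor_domains:
        if acceptor_protein_len is not None and dom.aa_end > acceptor_protein_len:
            raise ValueError(f"domain {dom.name} outside acceptor protein "
                             f"(length {acceptor_protein_len})")
        if dom.aa_start >= acc_lo and dom.aa_end <= acc_hi:
            status = "retained"
            lo, hi = dom.aa_start, dom.aa_end
        elif dom.aa_end < acc_lo or dom.aa_start > acc_hi:
            status, lo, hi = "lost", None, None
        else:
            status = "truncated"
            lo, hi = max(dom.aa_start, acc_lo), min(dom.aa_end, acc_hi)
        fus = (lambda wt: dj + (wt - aj) + 1)
        report.append({"name": dom.name, "source": "acceptor", "status": status,
                       "wt_start": dom.aa_start, "wt_end": dom.aa_end,
                       "fusion_start": fus(lo) if lo is not None else None,
                       "fusion_end": fus(hi) if hi is not None else None})
    return report


DOMAIN_COLUMNS = ["name", "source", "aa_start", "aa_end"]


def read_domains(path: PathLike) -> list[DomainRecord]:
    df = pd.read_csv(path, sep="\t")
    return [DomainRecord(name=str(r.name), source=str(r.source),
                         aa_start=int(r.aa_start), aa_end=int(r.aa_end))
            for r in df.itertuples(index=False)]


def write_domains(domains: Iterable[DomainRecord], path: PathLike) -> None:
    pd.DataFrame([vars(d) for d in domains])[DOMAIN_COLUMNS].to_csv(
        path, sep="\t", index=False)


def fusion_to_json(fusion: FusionTranscript,
                   domain_report: Optional[list[dict]] = None) -> dict:
    out = {
        "donor_id": fusion.donor_id, "acceptor_id": fusion.acceptor_id,
        "donor_pos": fusion.donor_pos, "acceptor_pos": fusion.acceptor_pos,
        "length": len(fusion.seq), "junction_offset": fusion.junction_offset,
        "donor_exons": fusion.donor_exons, "acceptor_exons": fusion.acceptor_exons,
        "orf_start": fusion.orf_start, "orf_end": fusion.orf_end,
        "orf_length": fusion.orf_length,
        "protein_length": len(fusion.protein) if fusion.protein else None,
        "protein": fusion.protein, "in_frame": fusion.in_frame,
    }
    if domain_report is not None:
        out["domains"] = domain_report
    return out
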