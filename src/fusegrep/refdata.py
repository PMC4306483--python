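"""Built-in worked-example data: printed sequences and synthetic references.

Two kinds of data live here and they must not be confused:

* **Published sequences** — the 101 bp chimeric KAT6B-KANSL1 read, the
  20-nt exon-3 anchor term, its two BLAST-localised fragments and the
  RT-PCR primers, all printed in the study this pipeline reproduces.
  These are verbatim inputs.

* **Synthetic reference stand-ins** — the real RefSeq mRNAs
  (NM_012330.3 for KAT6B, NM_015443.3 for KANSL1, and a MED12 mRNA)
  cannot be redistributed or fetched offline, so ``synthetic_kat6b`` /
  ``synthetic_kansl1`` / ``synthetic_med12`` build deterministic random
  backbones with every published sequence embedded at its published
  coordinate: the 43-mer at donor nt 1280-1322 (exon 3 ending at 1322),
  the 58-mer at acceptor nt 2715-2772 (exon 11 starting at 2715), all
  primer sites at the positions their names indicate, and lengths/CDS
  phases chosen so the assembled fusion is 3667 bp and the 1322/2715
  junction is in-frame. Coordinates of published features are exact;
  every other base is synthetic.

A consequence the stand-ins inherit from the published read itself: the
58-mer carries a stop codon in all three frames within 47 nt of the
junction, so the fusion's longest ORF terminates 18 nt past the junction
(engineered donor ATG at nt 21 -> 1320 bp ORF, 440 aa), shorter than the
published 1398 bp / 466 aa. No choice of stand-in can reproduce those
published sizes while embedding the published read context verbatim; see
docs/methods.md.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np

from .anchors import reverse_complement
from .fusionmodel import (DomainRecord, FusionTranscript, annotate_fusion,
                          assemble_fusion)
from .insilico_pcr import PrimerPair
from .seqio import SequenceRecord, TranscriptModel

# ---------------------------------------------------------------------------
# Published sequences (verbatim)
# ---------------------------------------------------------------------------

#: Last 20 nt of KAT6B exon 3 (donor nt 1303-1322): the search term.
ANCHOR_TERM = "TACCCCATGAGAAAGACCAG"

#: Read prefix localised to KAT6B, donor nt 1280-1322.
DONOR_FRAGMENT = "CTCGCTCCCACCTGTCAGCCTTCTACCCCATGAGAAAGACCAG"

#: Read suffix localised to KANSL1, acceptor nt 2715-2772.
ACCEPTOR_FRAGMENT = "CAGCAGCCAGTAAGGAGGTGAAGGGGAGAGAGCTCATTCGATATTAACAACATTGTCA"

#: The unique 101 bp chimeric read the anchor term extracts.
CHIMERIC_READ = DONOR_FRAGMENT + ACCEPTOR_FRAGMENT

DONOR_BREAKPOINT = 1322    # last donor (KAT6B exon 3) base in the fusion
ACCEPTOR_BREAKPOINT = 2715  # first acceptor (KANSL1 exon 11) base
FUSION_LENGTH = 3667

PRIMERS = {
    "MORF-1234F": "GCTTAGATGGCAAAGGGGCACCTC",
    "MORF-1261F": "ATCCCAGTGCATTCCCATCCTCG",
    "KANSL1-2969R1": "GTGGCACACTCGTGGTCCACAGC",
    "KANSL1-2900R1": "AGGCTGCGTCGGATAGGTCCTCA",
    "KANSL1-2341F1": "GGCACAAATTGGTCAGCTCCTTCCT",
    "MORF-1591R1": "GAAAGTGGTGGGTCACAGCATTCCA",
    "KANSL1-2407F1": "GGACCCACAGGCAGCACTTAGACG",
    "MORF-1483R1": "CATTCGATGCACTGCCACCTTAAGG",
    "MED12-Ex1-F": "TTACCCTCAGGACCCCAAACAG",
    "MED12-Ex3-R": "TGCAATAATGCTGCTGAAGTTGG",
}


def fusion_primer_pairs() -> list[PrimerPair]:
    """The four donor-forward / acceptor-reverse combinations."""
    return [
        PrimerPair("MORF-1234F/KANSL1-2969R1", PRIMERS["MORF-1234F"], PRIMERS["KANSL1-2969R1"]),
        PrimerPair("MORF-1234F/KANSL1-2900R1", PRIMERS["MORF-1234F"], PRIMERS["KANSL1-2900R1"]),
        PrimerPair("MORF-1261F/KANSL1-2969R1", PRIMERS["MORF-1261F"], PRIMERS["KANSL1-2969R1"]),
        PrimerPair("MORF-1261F/KANSL1-2900R1", PRIMERS["MORF-1261F"], PRIMERS["KANSL1-2900R1"]),
    ]


def reciprocal_primer_pair() -> PrimerPair:
    """First-round primers for the (absent) reciprocal KANSL1-KAT6B transcript."""
    return PrimerPair("KANSL1-2341F1/MORF-1591R1",
                      PRIMERS["KANSL1-2341F1"], PRIMERS["MORF-1591R1"])


def nested_reciprocal_pair() -> PrimerPair:
    return PrimerPair("KANSL1-2407F1/MORF-1483R1",
                      PRIMERS["KANSL1-2407F1"], PRIMERS["MORF-1483R1"])


def med12_pair() -> PrimerPair:
    """MED12 expression check primers; 163 bp product spanning exon 2."""
    return PrimerPair("MED12-Ex1-F/MED12-Ex3-R",
                      PRIMERS["MED12-Ex1-F"], PRIMERS["MED12-Ex3-R"])


# ---------------------------------------------------------------------------
# Synthetic reference construction
# ---------------------------------------------------------------------------

_BUILD_SEED = 20150117  # fixed: the stand-ins are definitions, not samples
_STOPS = ("TAA", "TAG", "TGA")


def _random_seq(rng: np.random.Generator, n: int) -> list[str]:
    return list(rng.choice(list("ACGT"), size=n))


def _embed(seq: list[str], protected: np.ndarray, pos1: int, sub: str) -> None:
    """Place ``sub`` at 1-based ``pos1``; protected overlaps must agree."""
    for j, base in enumerate(sub):
        i = pos1 - 1 + j
        if protected[i] and seq[i] != base:
            raise AssertionError(
                f"embedding conflict at position {i + 1}: {seq[i]} vs {base}")
        seq[i] = base
        protected[i] = True


def _purge_stops(seq: list[str], protected: np.ndarray,
                 cds_start: int, cds_end: int) -> list[int]:
    """Remove in-frame stops from the CDS interior; returns skipped (all-
    protected) stop codon start positions, which are left intact."""
    skipped = []
    for c1 in range(cds_start, cds_end - 4, 3):
        codon = "".join(seq[c1 - 1:c1 + 2])
        if codon in _STOPS:
            free = [j for j in (2, 0, 1) if not protected[c1 - 1 + j]]
            if not free:
                skipped.append(c1)
                continue
            seq[c1 - 1 + free[0]] = "C"  # de-stops in any codon position
    return skipped


def _purge_upstream_atg(seq: list[str], protected: np.ndarray,
                        cds_start: int) -> None:
    """Ensure no in-frame ATG upstream of the annotated start codon."""
    for c1 in range(cds_start - 3, 0, -3):
        if "".join(seq[c1 - 1:c1 + 2]) == "ATG" and not protected[c1 - 1]:
            seq[c1 - 1] = "C"


def _count(hay: str, needle: str) -> int:
    n, i = 0, hay.find(needle)
    while i != -1:
        n, i = n + 1, hay.find(needle, i + 1)
    return n


@lru_cache(maxsize=1)
def synthetic_kat6b() -> TranscriptModel:
    """Synthetic KAT6B mRNA stand-in (coordinates modelled on NM_012330.3).

    2000 nt, 5 exons with exon 2 ending at nt 443 and exon 3 at nt 1322
    (published exon-3 interval 444-1322); the published 43-mer sits at nt
    1280-1322 (anchor term at 1303-1322), MORF primer sites at the
    positions in their names; CDS 21..1922 (ATG at 21, internal frame
    purged of stops, TAA at 1920-1922); nt 1323 is fixed to 'A' so exact
    extension of the chimeric read stops at the published breakpoint.
    """
    rng = np.random.default_rng(_BUILD_SEED)
    n = 2000
    seq = _random_seq(rng, n)
    protected = np.zeros(n, dtype=bool)
    _embed(seq, protected, 1280, DONOR_FRAGMENT)
    _embed(seq, protected, 1234, PRIMERS["MORF-1234F"])
    _embed(seq, protected, 1261, PRIMERS["MORF-1261F"])
    _embed(seq, protected, 1459, reverse_complement(PRIMERS["MORF-1483R1"]))
    _embed(seq, protected, 1567, reverse_complement(PRIMERS["MORF-1591R1"]))
    _embed(seq, protected, 21, "ATG")
    _embed(seq, protected, 1920, "TAA")
    _embed(seq, protected, 1323, "A")  # mismatch vs read base 44 ('C')
    skipped = _purge_stops(seq, protected, 21, 1922)
    assert not skipped, f"unexpected protected stop codons in donor: {skipped}"
    _purge_upstream_atg(seq, protected, 21)
    model = TranscriptModel(
        transcript_id="KAT6B_synthetic", gene="KAT6B", seq="".join(seq),
        exon_ends=[200, 443, 1322, 1700, 2000], cds_start=21, cds_end=1922,
    )
    s = model.seq
    assert s[1302:1322] == ANCHOR_TERM
    assert _count(s, ANCHOR_TERM) == 1 and _count(s, reverse_complement(ANCHOR_TERM)) == 0
    for name in ("MORF-1234F", "MORF-1261F"):
        assert _count(s, PRIMERS[name]) == 1, name
    for name in ("MORF-1483R1", "MORF-1591R1"):
        assert _count(s, reverse_complement(PRIMERS[name])) == 1, name
    return model


@lru_cache(maxsize=1)
def synthetic_kansl1() -> TranscriptModel:
    """Synthetic KANSL1 mRNA stand-in (coordinates modelled on NM_015443.3).

    5059 nt (so that the 1322/2715 fusion is 3667 bp), 15 exons with exon
    11 starting at nt 2715; the published 58-mer sits at nt 2715-2772 and
    the KANSL1 primer sites at the positions in their names; CDS 591..3833
    with the phase that makes the published junction in-frame. The
    published 58-mer leaves one in-frame stop (TGA at 2733-2735) inside
    the CDS — an inconsistency inherited from the published read, kept
    verbatim. nt 2714 is fixed to 'T' so the read's acceptor match starts
    exactly at the published breakpoint (blunt transcript-level junction).
    """
    rng = np.random.default_rng(_BUILD_SEED + 1)
    n = 5059
    seq = _random_seq(rng, n)
    protected = np.zeros(n, dtype=bool)
    _embed(seq, protected, 2715, ACCEPTOR_FRAGMENT)
    _embed(seq, protected, 2341, PRIMERS["KANSL1-2341F1"])
    _embed(seq, protected, 2407, PRIMERS["KANSL1-2407F1"])
    _embed(seq, protected, 2878, reverse_complement(PRIMERS["KANSL1-2900R1"]))
    _embed(seq, protected, 2947, reverse_complement(PRIMERS["KANSL1-2969R1"]))
    _embed(seq, protected, 591, "ATG")
    _embed(seq, protected, 3831, "TAA")
    _embed(seq, protected, 2714, "T")  # mismatch vs read base 43 ('G')
    skipped = _purge_stops(seq, protected, 591, 3833)
    assert skipped == [2733], f"unexpected protected stops in acceptor: {skipped}"
    model = TranscriptModel(
        transcript_id="KANSL1_synthetic", gene="KANSL1", seq="".join(seq),
        exon_ends=[300, 600, 900, 1300, 1700, 2000, 2300, 2500, 2600, 2714,
                   3100, 3600, 4100, 4600, 5059],
        cds_start=591, cds_end=3833,
    )
    s = model.seq
    assert s[2714:2772] == ACCEPTOR_FRAGMENT
    assert _count(s, ANCHOR_TERM) == 0 and _count(s, reverse_complement(ANCHOR_TERM)) == 0
    for name in ("KANSL1-2341F1", "KANSL1-2407F1"):
        assert _count(s, PRIMERS[name]) == 1, name
    for name in ("KANSL1-2900R1", "KANSL1-2969R1"):
        assert _count(s, reverse_complement(PRIMERS[name])) == 1, name
    return model


@lru_cache(maxsize=1)
def synthetic_med12() -> TranscriptModel:
    """Synthetic MED12 mRNA stand-in: 300 nt, 3 exons (ends 100/180/300),
    with the published primer sites placed so MED12-Ex1-F sits in exon 1,
    the reverse site in exon 3, and the product is the published 163 bp
    spanning all of exon 2."""
    rng = np.random.default_rng(_BUILD_SEED + 2)
    n = 300
    seq = _random_seq(rng, n)
    protected = np.zeros(n, dtype=bool)
    _embed(seq, protected, 61, PRIMERS["MED12-Ex1-F"])
    _embed(seq, protected, 201, reverse_complement(PRIMERS["MED12-Ex3-R"]))
    model = TranscriptModel(transcript_id="MED12_synthetic", gene="MED12",
                            seq="".join(seq), exon_ends=[100, 180, 300])
    assert _count(model.seq, PRIMERS["MED12-Ex1-F"]) == 1
    assert _count(model.seq, reverse_complement(PRIMERS["MED12-Ex3-R"])) == 1
    return model


def synthetic_domains() -> tuple[list[DomainRecord], list[DomainRecord]]:
    """Domain tables for the synthetic proteins (stand-in coordinates).

    Donor: NEMM region with its H15 (linker histone H1/H5 globular) domain
    in the N-terminal part of the synthetic KAT6B protein (633 aa).
    Acceptor: PEHE domain in the C-terminal part of the synthetic KANSL1
    protein (1080 aa). Positions are synthetic; only the topology
    (N-terminal donor domain, C-terminal acceptor domain) mirrors the
    wild-type proteins.
    """
    donor = [DomainRecord("NEMM", "donor", 1, 200),
             DomainRecord("H15", "donor", 25, 90)]
    acceptor = [DomainRecord("PEHE", "acceptor", 800, 950)]
    return donor, acceptor


def synthetic_fusion() -> FusionTranscript:
    """The KAT6B-KANSL1 fusion assembled from the synthetic references."""
    fusion = assemble_fusion(synthetic_kat6b(), DONOR_BREAKPOINT,
                             synthetic_kansl1(), ACCEPTOR_BREAKPOINT)
    return annotate_fusion(fusion, synthetic_kat6b(), synthetic_kansl1())


# ---------------------------------------------------------------------------
# Worked-example fixtures
# ---------------------------------------------------------------------------

def chimeric_read_record(read_id: str = "chimeric_101bp") -> SequenceRecord:
    return SequenceRecord(id=read_id, seq=CHIMERIC_READ,
                          qual="I" * len(CHIMERIC_READ))


def decoy_reads(n: int, length: int = 101, seed: int = 0) -> list[SequenceRecord]:
    """Random reads guaranteed not to contain the anchor term (either
    orientation); background for the worked-example FASTQ fixture."""
    rng = np.random.default_rng(seed)
    rc = reverse_complement(ANCHOR_TERM)
    out: list[SequenceRecord] = []
    while len(out) < n:
        seq = "".join(rng.choice(list("ACGT"), size=length))
        if ANCHOR_TERM in seq or rc in seq:
            continue
        out.append(SequenceRecord(id=f"decoy{len(out) + 1}", seq=seq,
                                  qual="I" * length))
    return out


_MINI_FLANK_L = "GTGTGTGTGTGTGTGTGTGT"
_MINI_FLANK_R = "GAGAGAGAGAGAGAGAGAGA"


def mini_references() -> tuple[TranscriptModel, SequenceRecord]:
    """Desk-scale references built from the two published read fragments.

    The donor embeds the 43-mer with non-extending flanks and an exon
    boundary at the fragment's last base (so the k=20 exon-end anchor is
    the published search term); the acceptor embeds read bases 41-101 —
    the chromosome-17-matching portion, whose first three bases duplicate
    donor bases 41-43 — giving the published 3-base junction microhomology.
    """
    donor_seq = _MINI_FLANK_L + DONOR_FRAGMENT + _MINI_FLANK_R
    assert donor_seq[63] != CHIMERIC_READ[43]  # no extension past the junction
    donor = TranscriptModel(transcript_id="donor_mini", gene="KAT6B",
                            seq=donor_seq, exon_ends=[63, 83])
    acc_segment = CHIMERIC_READ[40:]  # read bases 41-101
    assert _MINI_FLANK_L[-1] != CHIMERIC_READ[39]  # no left extension
    acceptor = SequenceRecord(id="acceptor_mini",
                              seq=_MINI_FLANK_L + acc_segment + _MINI_FLANK_R)
    return donor, acceptor
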