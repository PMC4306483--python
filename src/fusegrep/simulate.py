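"""Synthetic RNA-seq read simulation with planted fusion junctions.

Generates the ground truth every pipeline stage is tested against: a
pair of random multi-exon transcript models, a fusion junction planted
at an exon_end/exon_start boundary pair (optionally with engineered
microhomology), and single-end reads drawn uniformly from the wild-type
and fusion transcripts with per-base substitution errors. Substitutions
only — the detection method is exact-match based and indel tolerance is
out of scope. Qualities are written as a uniform 'I' run and never
consumed.

One integer seed drives all randomness; the draw order (gene
construction, then per-read start positions, then per-base errors) is
fixed, so outputs are byte-identical across runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .fusionmodel import assemble_fusion
from .seqio import PathLike, SequenceRecord, TranscriptModel, write_fastq

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class PlantedJunction:
    """Ground truth for a simulated fusion."""

    donor_id: str
    donor_pos: int       # exon-end transcript coordinate on the donor
    acceptor_id: str
    acceptor_pos: int    # exon-start transcript coordinate on the acceptor
    microhomology_len: int
    in_frame: Optional[bool] = None


@dataclass
class SimConfig:
    """Read-simulation parameters.

    ``read_len`` should be at least twice the caller's ``min_flank`` for
    junction-spanning reads to be callable; ``fusion_fraction`` is the
    proportion of reads drawn from the fusion transcript, the rest being
    split between the two wild-type transcripts.
    """

    read_len: int = 100
    n_reads: int = 2000
    error_rate: float = 0.0
    fusion_fraction: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.fusion_fraction <= 1:
            raise ValueError("fusion_fraction must be in [0, 1]")
        if not 0 <= self.error_rate < 1:
            raise ValueError("error_rate must be in [0, 1)")
        if self.read_len < 2 or self.n_reads < 0:
            raise ValueError("bad read_len / n_reads")


def _clean_cds(rng: np.random.Generator, seq: list[str], cds_start: int,
               cds_end: int) -> None:
    """Engineer ATG..stop with a stop-free interior and no upstream
    in-frame ATG, mutating bases in place."""
    seq[cds_start - 1:cds_start + 2] = list("ATG")
    seq[cds_end - 3:cds_end] = list("TAA")
    for c in range(cds_start + 3, cds_end - 3, 3):
        while "".join(seq[c - 1:c + 2]) in ("TAA", "TAG", "TGA"):
            seq[c + 1] = str(rng.choice(_BASES))
    for c in range(cds_start - 3, 0, -3):
        if "".join(seq[c - 1:c + 2]) == "ATG":
            seq[c - 1] = "C"


def make_toy_genes(seed: int, n_exons: tuple[int, int] = (4, 5),
                   exon_len_range: tuple[int, int] = (150, 350),
                   donor_junction_exon: int = 3,
                   acceptor_junction_exon: int = 3,
                   microhomology_len: int = 0,
                   in_frame: bool = True,
                   ) -> tuple[TranscriptModel, TranscriptModel, PlantedJunction]:
    """Two random multi-exon transcripts with an engineered junction.

    The junction is placed at the end of ``donor_junction_exon`` on the
    donor and the start of ``acceptor_junction_exon`` on the acceptor.
    Both transcripts get clean engineered CDSs whose phases make the
    junction in-frame (or deliberately out of frame). With
    ``microhomology_len = m > 0`` the m acceptor bases 5' of the acceptor
    breakpoint are overwritten with the m donor bases preceding the
    junction, so the planted breakpoint is ambiguous within that window
    exactly as at a real microhomologous junction.
    """
    rng = np.random.default_rng(seed)

    def build(tag: str, k_exons: int) -> tuple[list[str], list[int]]:
        lens = rng.integers(exon_len_range[0], exon_len_range[1] + 1,
                            size=k_exons)
        ends = np.cumsum(lens).astype(int).tolist()
        seq = list(rng.choice(_BASES, size=ends[-1]))
        return seq, ends

    donor_seq, donor_ends = build("donor", n_exons[0])
    acceptor_seq, acceptor_ends = build("acceptor", n_exons[1])
    donor_pos = donor_ends[donor_junction_exon - 1]
    acceptor_pos = (acceptor_ends[acceptor_junction_exon - 2] + 1
                    if acceptor_junction_exon > 1 else 1)

    # CDS phases: pick donor start, then set the acceptor start so that
    # (donor_pos - cds_d + 1) == (acceptor_pos - cds_a)  (mod 3), shifted
    # by one for an out-of-frame junction.
    cds_d = int(rng.integers(5, 31))
    target = (donor_pos - cds_d + 1) % 3 if in_frame \
        else (donor_pos - cds_d + 2) % 3
    cds_a = int(rng.integers(5, 31))
    cds_a += (acceptor_pos - cds_a - target) % 3
    cds_d_end = cds_d + 3 * ((len(donor_seq) - 10 - cds_d + 1) // 3) - 1
    cds_a_end = cds_a + 3 * ((len(acceptor_seq) - 10 - cds_a + 1) // 3) - 1
    _clean_cds(rng, donor_seq, cds_d, cds_d_end)
    _clean_cds(rng, acceptor_seq, cds_a, cds_a_end)
    if microhomology_len:
        m = microhomology_len
        if m >= acceptor_pos or m > donor_pos:
            raise ValueError("microhomology window outside a transcript")
        acceptor_seq[acceptor_pos - 1 - m:acceptor_pos - 1] = \
            donor_seq[donor_pos - m:donor_pos]
    donor = TranscriptModel("toy_donor", "TOYD", "".join(donor_seq),
                            donor_ends, cds_d, cds_d_end)
    acceptor = TranscriptModel("toy_acceptor", "TOYA", "".join(acceptor_seq),
                               acceptor_ends, cds_a, cds_a_end)
    junction = PlantedJunction(
        donor_id=donor.transcript_id, donor_pos=donor_pos,
        acceptor_id=acceptor.transcript_id, acceptor_pos=acceptor_pos,
        microhomology_len=microhomology_len, in_frame=in_frame)
    return donor, acceptor, junction


def canonical_planted(donor: TranscriptModel, acceptor: TranscriptModel,
                      junction: PlantedJunction) -> tuple[int, int]:
    """Donor-maximal canonical form of the planted breakpoint.

    Shifts the breakpoint rightwards while the next acceptor base equals
    the next donor base — the same homology-resolution rule the caller
    applies — so planted truth and calls are compared on equal footing.
    """
    d, a = junction.donor_pos, junction.acceptor_pos
    while d < len(donor.seq) and a <= len(acceptor.seq) \
            and acceptor.seq[a - 1] == donor.seq[d]:
        d, a = d + 1, a + 1
    return d, a


def fusion_sequence(donor: TranscriptModel, acceptor: TranscriptModel,
                    junction: PlantedJunction) -> str:
    return assemble_fusion(donor, junction.donor_pos,
                           acceptor, junction.acceptor_pos).seq


def spanning_margin(junction_offset: int, start: int, read_len: int) -> int:
    """Bases on the scarcer side of the junction for a fusion read, or 0."""
    left = junction_offset - start + 1
    right = start + read_len - 1 - junction_offset
    return max(0, min(left, right))


def expected_spanning_reads(n_fusion: int, read_len: int, fusion_len: int,
                            min_flank: int = 20) -> float:
    """Closed form: reads overlapping the junction with >= min_flank bases
    on both sides, for uniform start positions."""
    positions = read_len - (2 * min_flank - 1)
    return n_fusion * max(0, positions) / (fusion_len - read_len + 1)


def simulate_reads(donor: TranscriptModel, acceptor: TranscriptModel,
                   junction: PlantedJunction, cfg: SimConfig,
                   out: Optional[PathLike] = None,
                   ) -> tuple[list[SequenceRecord], dict]:
    """Draw reads from the fusion and wild-type transcripts.

    Returns (records, truth manifest); when ``out`` is given the records
    are also written as FASTQ (gzip if the suffix is .gz). The manifest
    records, per read, the source transcript, the 1-based start, the
    number of substitution errors, and for fusion reads the junction-
    spanning margin (min flank on either side, 0 if not spanning).
    """
    rng = np.random.default_rng(cfg.seed)
    fusion = fusion_sequence(donor, acceptor, junction)
    sources = {"fusion": fusion, donor.transcript_id: donor.seq,
               acceptor.transcript_id: acceptor.seq}
    for name, seq in sources.items():
        if cfg.read_len > len(seq):
            raise ValueError(f"read_len {cfg.read_len} exceeds {name} "
                             f"length {len(seq)}")
    n_fusion = round(cfg.n_reads * cfg.fusion_fraction)
    n_wt = cfg.n_reads - n_fusion
    plan = (["fusion"] * n_fusion
            + [donor.transcript_id] * (n_wt // 2 + n_wt % 2)
            + [acceptor.transcript_id] * (n_wt // 2))
    records: list[SequenceRecord] = []
    manifest_reads: list[dict] = []
    for i, src in enumerate(plan):
        template = sources[src]
        start = int(rng.integers(1, len(template) - cfg.read_len + 2))
        bases = list(template[start - 1:start - 1 + cfg.read_len])
        n_err = 0
        if cfg.error_rate > 0:
            hits = np.flatnonzero(rng.random(cfg.read_len) < cfg.error_rate)
            for j in hits:
                alts = [b for b in "ACGT" if b != bases[j]]
                bases[j] = alts[int(rng.integers(0, 3))]
            n_err = len(hits)
        read_id = f"sim{i + 1}|{src}|{start}"
        records.append(SequenceRecord(id=read_id, seq="".join(bases),
                                      qual="I" * cfg.read_len))
        entry = {"id": read_id, "source": src, "start": start, "errors": n_err}
        if src == "fusion":
            entry["spanning_margin"] = spanning_margin(
                junction.donor_pos, start, cfg.read_len)
        manifest_reads.append(entry)
    manifest = {
        "config": {"read_len": cfg.read_len, "n_reads": cfg.n_reads,
                   "error_rate": cfg.error_rate,
                   "fusion_fraction": cfg.fusion_fraction, "seed": cfg.seed},
        "junction": {
            "donor_id": junction.donor_id, "donor_pos": junction.donor_pos,
            "acceptor_id": junction.acceptor_id,
            "acceptor_pos": junction.acceptor_pos,
            "microhomology_len": junction.microhomology_len,
            "canonical": list(canonical_planted(donor, acceptor, junction)),
        },
        "fusion_length": len(fusion),
        "reads": manifest_reads,
    }
    if out is not None:
        write_fastq(records, out)
    return records, manifest
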