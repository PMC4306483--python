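"""End-to-end orchestration: anchors -> scan -> split/call -> model -> PCR.

The pipeline chains the discovery stages exactly as one would run them
by hand and writes a report bundle (TSVs, FASTAs, JSON) into an output
directory. Defaults mirror the worked example's choices: k = 20,
min_flank = 20, min_support = 1, partner seed length 16. Outputs are
deterministic for identical inputs; timestamps only ever appear in logs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

from . import anchors as anchors_mod
from . import fusionmodel, insilico_pcr, junction, scan, seqio

logger = logging.getLogger(__name__)

EXIT_OK = 0
EXIT_NO_CALL = 3

REPORT_SCHEMA_VERSION = 1


class StageError(RuntimeError):
    """A pipeline stage failed; the stage name prefixes the message."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    """Paths and parameters for a full run; see the module docstring."""

    fastq: Sequence[str]
    donor_fasta: str
    donor_exons: str
    partners_fasta: str
    out_dir: str
    donor_id: Optional[str] = None
    acceptor_exons: Optional[str] = None   # enables the fusion-model stage
    domains: Optional[str] = None          # TSV: name/source/aa_start/aa_end
    primers: Optional[str] = None          # TSV: name/fwd/rev
    k: int = anchors_mod.DEFAULT_K
    exons: Optional[Sequence[int]] = None
    sides: Sequence[str] = anchors_mod.SIDES
    min_flank: int = junction.DEFAULT_MIN_FLANK
    min_support: int = 1
    seed_len: int = junction.DEFAULT_SEED_LEN
    max_len: int = insilico_pcr.DEFAULT_MAX_LEN
    log_level: str = "INFO"

    def validate_paths(self) -> None:
        for p in [*self.fastq, self.donor_fasta, self.donor_exons,
                  self.partners_fasta, self.acceptor_exons, self.domains,
                  self.primers]:
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(p)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage; returns the report dict (also written as JSON).

    The report's ``status`` is "call" when at least one junction was
    called and "no_call" otherwise; stage failures raise
    :class:`StageError` and leave already-written outputs with a
    ``.partial`` suffix alongside them.
    """
    logging.getLogger("fusegrep").setLevel(config.log_level)
    config.validate_paths()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def fail(stage: str, exc: Exception) -> StageError:
        for p in written:
            if p.exists():
                p.rename(p.with_suffix(p.suffix + ".partial"))
        return StageError(stage, exc)

    report: dict = {"schema_version": REPORT_SCHEMA_VERSION,
                    "parameters": {
                        "k": config.k, "min_flank": config.min_flank,
                        "min_support": config.min_support,
                        "seed_len": config.seed_len, "max_len": config.max_len,
                    }}

    try:
        donor = seqio.load_transcript_model(config.donor_fasta,
                                            config.donor_exons,
                                            transcript_id=config.donor_id)
        partners = seqio.read_fasta(config.partners_fasta)
    except Exception as exc:
        raise fail("load", exc)

    try:
        anchor_list = anchors_mod.design_anchors(
            donor, k=config.k, exons=config.exons, sides=config.sides)
        path = out / "anchors.tsv"
        anchors_mod.write_anchors(anchor_list, path)
        written.append(path)
        report["anchors"] = [
            {"seq": a.seq, "exon": a.exon_index, "side": a.side,
             "orientation": a.orientation} for a in anchor_list]
    except Exception as exc:
        raise fail("anchors", exc)

    try:
        hits: list[scan.ReadHit] = []
        for fq in config.fastq:
            hits.extend(scan.scan_reads(seqio.read_fastq(fq), anchor_list))
        path = out / "hits.tsv"
        scan.write_hits(hits, path)
        written.append(path)
        report["n_hits"] = len(hits)
    except Exception as exc:
        raise fail("scan", exc)

    try:
        index = junction.PartnerIndex(partners, seed_len=config.seed_len)
        splits = [junction.split_align(h, donor, index,
                                       min_flank=config.min_flank)
                  for h in hits]
        no_calls = [s for s in splits if isinstance(s, junction.NoCall)]
        calls = junction.call_junctions(splits, min_support=config.min_support)
        path = out / "junctions.tsv"
        junction.write_junctions(calls, path)
        written.append(path)
        report["n_no_calls"] = len(no_calls)
        report["no_call_reasons"] = sorted({n.reason for n in no_calls})
    except Exception as exc:
        raise fail("call", exc)

    acceptor: Optional[seqio.TranscriptModel] = None
    if calls and config.acceptor_exons is not None:
        try:
            top = calls[0]
            acceptor = seqio.load_transcript_model(
                config.partners_fasta, config.acceptor_exons,
                transcript_id=top.acceptor_id)
            fusion = fusionmodel.assemble_fusion(
                donor, top.donor_pos, acceptor, top.acceptor_pos)
            fusionmodel.annotate_fusion(fusion, donor, acceptor)
            top.in_frame = fusion.in_frame
            domain_report = None
            if config.domains is not None and fusion.protein is not None:
                doms = fusionmodel.read_domains(config.domains)
                dj = fusion.donor_protein_junction_aa
                if dj is not None and acceptor.cds_start is not None:
                    aj = (top.acceptor_pos - acceptor.cds_start) // 3 + 1
                    domain_report = fusionmodel.map_domains(
                        fusion, [d for d in doms if d.source == "donor"],
                        [d for d in doms if d.source == "acceptor"],
                        donor_protein_junction_aa=dj,
                        acceptor_protein_junction_aa=aj)
            seqio.write_fasta(
                [seqio.SequenceRecord(id=f"{fusion.donor_id}-{fusion.acceptor_id}",
                                      seq=fusion.seq)],
                out / "fusion.fa")
            written.append(out / "fusion.fa")
            if fusion.protein:
                with open(out / "protein.fa", "w") as fh:
                    fh.write(f">{fusion.donor_id}-{fusion.acceptor_id}_protein\n"
                             f"{fusion.protein}\n")
                written.append(out / "protein.fa")
            fusion_json = fusionmodel.fusion_to_json(fusion, domain_report)
            (out / "fusion.json").write_text(json.dumps(fusion_json, indent=2))
            written.append(out / "fusion.json")
            report["fusion"] = fusion_json
        except Exception as exc:
            raise fail("model", exc)

    if config.primers is not None and calls and "fusion" in report:
        try:
            pairs = insilico_pcr.read_primers(config.primers)
            template = seqio.read_fasta(out / "fusion.fa")[0]
            rows = []
            pcr_report = []
            for pair in pairs:
                amps = insilico_pcr.predict_amplicons(template, pair,
                                                      max_len=config.max_len)
                rows.extend((pair, a) for a in amps)
                pcr_report.append({"pair": pair.name,
                                   "products": [a.length for a in amps]})
            insilico_pcr.write_amplicons(rows, out / "amplicons.tsv")
            written.append(out / "amplicons.tsv")
            report["pcr"] = pcr_report
        except Exception as exc:
            raise fail("pcr", exc)

    report["junctions"] = junction.junctions_to_json(calls)
    report["status"] = "call" if calls else "no_call"
    (out / "report.json").write_text(json.dumps(report, indent=2))
    logger.info("pipeline finished: %d junction call(s)", len(calls))
    return report
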