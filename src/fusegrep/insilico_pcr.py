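"""In-silico RT-PCR: exact primer-site amplicon prediction.

Verifies primer design logic, not hybridisation thermodynamics: a
product is predicted wherever the forward primer matches the template
exactly and the reverse primer's reverse complement matches exactly
downstream, within ``max_len``. An empty product list is the expected
result for a negative control — e.g. a donor-forward / acceptor-reverse
pair on either wild-type transcript, or reciprocal-orientation primers
on the fusion.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import pandas as pd

from .anchors import reverse_complement
from .scan import _occurrences
from .seqio import PathLike, SequenceRecord

DEFAULT_MAX_LEN = 5000
MIN_PRIMER_LEN = 10


@dataclass(frozen=True)
class PrimerPair:
    """Forward and reverse primers, both written 5'->3' as synthesised."""

    name: str
    fwd: str
    rev: str

    def __post_init__(self) -> None:
        for label, p in (("fwd", self.fwd), ("rev", self.rev)):
            if len(p) < MIN_PRIMER_LEN:
                raise ValueError(f"{self.name}: {label} primer shorter than "
                                 f"{MIN_PRIMER_LEN} nt")
            if set(p) - set("ACGT"):
                raise ValueError(f"{self.name}: {label} primer has non-ACGT symbols")


@dataclass
class AmpliconPrediction:
    """A predicted PCR product on one template."""

    template_id: str
    start: int  # 1-based: 5' end of the forward site
    end: int    # 1-based: 3' end of the reverse site
    length: int
    product_seq: str

    def __post_init__(self) -> None:
        if self.length != self.end - self.start + 1 or \
                self.length != len(self.product_seq):
            raise ValueError("inconsistent amplicon coordinates")


def predict_amplicons(template: SequenceRecord, pair: PrimerPair,
                      max_len: int = DEFAULT_MAX_LEN) -> list[AmpliconPrediction]:
    """All exact-match products of one primer pair on one template.

    Every (forward site, reverse site) combination with the forward site
    ending strictly before the reverse site starts and a product length
    of at most ``max_len`` is reported, sorted by start then length.
    """
    if max_len <= len(pair.fwd) + len(pair.rev):
        raise ValueError("max_len must exceed the combined primer lengths")
    seq = template.seq
    rev_site = reverse_complement(pair.rev)
    fwd_starts = [i + 1 for i in _occurrences(seq, pair.fwd)]
    rev_ends = [i + len(rev_site) for i in _occurrences(seq, rev_site)]
    out = []
    for fs in fwd_starts:
        fwd_end = fs + len(pair.fwd) - 1
        for re_ in rev_ends:
            rev_start = re_ - len(pair.rev) + 1
            if fwd_end < rev_start and re_ - fs + 1 <= max_len:
                out.append(AmpliconPrediction(
                    template_id=template.id, start=fs, end=re_,
                    length=re_ - fs + 1, product_seq=seq[fs - 1:re_]))
    out.sort(key=lambda a: (a.start, a.length))
    return out


PRIMER_COLUMNS = ["name", "fwd", "rev"]
AMPLICON_COLUMNS = ["template_id", "primer_pair", "start", "end", "length",
                    "product_seq"]


def read_primers(path: PathLike) -> list[PrimerPair]:
    df = pd.read_csv(path, sep="\t")
    return [PrimerPair(name=str(r.name), fwd=str(r.fwd), rev=str(r.rev))
            for r in df.itertuples(index=False)]


def write_amplicons(rows: Iterable[tuple[PrimerPair, AmpliconPrediction]],
                    path: PathLike) -> None:
    records = [{"template_id": a.template_id, "primer_pair": p.name,
                "start": a.start, "end": a.end, "length": a.length,
                "product_seq": a.product_seq} for p, a in rows]
    pd.DataFrame(records, columns=AMPLICON_COLUMNS).to_csv(
        path, sep="\t", index=False)
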