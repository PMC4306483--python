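# fusegrep

Targeted discovery of gene-fusion transcripts in raw RNA-seq reads, built
around the simplest possible recruitment step: an **exact `grep`-style
search for exon-boundary anchor k-mers**.

## The problem

When cytogenetics points at a specific candidate gene — say a tumour with a
balanced translocation t(10;17)(q22;q21) disrupting *KAT6B* — genome-wide
fusion callers can miss the event entirely, while the evidence sits in the
raw FASTQ as a handful of chimeric reads. Because fusion junctions created
by a rearrangement plus splicing fall at exon boundaries, a k-mer taken
flush against an exon boundary of the candidate transcript is a
high-specificity bait: any read that contains it *and then continues into
foreign sequence* spans the fusion junction. For k = 20 the expected number
of chance hits per 100 bp read is about 81·4⁻²⁰ ≈ 7·10⁻¹¹, so exact
matching over tens of millions of reads stays essentially noise-free.

`fusegrep` packages that idea as a pipeline for transcriptomics users who
have a candidate gene and raw reads:

1. **anchors** — derive exon-boundary k-mers (both boundary sides, both
   orientations) from the candidate transcript model.
2. **scan** — stream FASTQ (plain or gzipped) and extract every read
   containing an anchor exactly, in either orientation (`grep` semantics;
   zero mismatches; headers and quality lines can never match because
   records are parsed).
3. **call** — split-align each recruited read by exact maximal extension:
   the anchor placement is extended mismatch-free along the candidate, and
   the unexplained remainder is seeded (16-mers) into a k-mer index of a
   partner search set and extended likewise. Each flank must reach
   `min_flank` (default 20) matched bases. Junction microhomology — bases
   shared by both partners — is resolved **donor-maximally**: the canonical
   call assigns every shared base to the 5' partner, and calls are
   aggregated by canonical breakpoint with read support counts.
4. **model** — assemble the predicted fusion mRNA
   (`donor[1..d] + acceptor[a..end]`), report retained exons, the longest
   ATG-initiated ORF (length excludes the stop codon, so protein length =
   ORF/3), a reading-frame check from the wild-type CDS phases
   (`(d − cds_d + 1) ≡ (a − cds_a) (mod 3)`), and retained / truncated /
   lost protein domains.
5. **pcr** — in-silico RT-PCR: exact primer-site matching predicts products
   for verification primer pairs, including the negative controls
   (wild-type templates, reciprocal-orientation primers).
6. **simulate** — generate toy transcript pairs with planted junctions
   (optionally microhomologous), error-bearing reads, and a truth manifest,
   so the whole chain is testable without external data.

## Worked example

The package ships the published worked example: a 101 bp chimeric
KAT6B–KANSL1 read, the 20-nt search term from the end of KAT6B exon 3, and
the RT-PCR primer panel, together with deterministic synthetic stand-ins
for the reference mRNAs (the real RefSeq records cannot be redistributed;
the stand-ins embed every published sequence at its published coordinate —
see `fusegrep.refdata` and `docs/methods.md`).

```bash
fusegrep worked-example --out-dir demo --n-decoys 100 --seed 1
```

prints

```
anchor term: TACCCCATGAGAAAGACCAG
reads scanned: 101; anchor hits: 1 (read length 101 bp)
junction: KAT6B_synthetic nt 1322 -> KANSL1_synthetic nt 2715 (support 1, microhomology 0, in_frame True)
fusion transcript: 3667 bp; retained exons [1, 2, 3] + [11, 12, 13, 14, 15]
ORF: 1320 bp; protein: 440 aa
in-silico PCR MORF-1234F/KANSL1-2969R1: [344]
in-silico PCR MORF-1234F/KANSL1-2900R1: [275]
in-silico PCR MORF-1261F/KANSL1-2969R1: [317]
in-silico PCR MORF-1261F/KANSL1-2900R1: [248]
in-silico PCR KANSL1-2341F1/MORF-1591R1: no product
in-silico PCR KANSL1-2407F1/MORF-1483R1: no product
MED12 control: 163 bp
```

Reading the output: the anchor term recruits exactly one read out of 101 —
the 101 bp chimeric read — whose first 43 bases extend along KAT6B to
nt 1322 (the end of exon 3) and whose remainder matches KANSL1 from
nt 2715 (the start of exon 11), a blunt in-frame junction at transcript
level. The assembled fusion is 3667 bp and retains KAT6B exons 1–3 plus
KANSL1 exons 11–15. All four fusion primer combinations amplify a single
product on the fusion and nothing on the wild-type templates; the
reciprocal-orientation primers amplify nothing on the fusion; the MED12
control primers give their 163 bp product. The ORF/protein sizes (1320 bp
/ 440 aa) are a property of the published junction context embedded in
the stand-ins; `docs/methods.md` explains why they are shorter than the
published 1398 bp / 466 aa.

The same run can be driven stage by stage (`fusegrep anchors / scan /
call / model / pcr`) or through `fusegrep run --config ...` on your own
FASTQ and references; `fusegrep simulate` generates truth-tracked
synthetic data.

## Scope

Single-candidate, targeted discovery only: no genome-wide fusion scanning,
no scored or gapped alignment, no quality trimming, no paired-end
bookkeeping (each read is searched independently), and no primer
thermodynamics — the in-silico PCR verifies design logic, not
hybridisation.
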