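"""Toy reference bundle: genome, transcript annotation, canonical proteome.

A single contig carries a few dozen non-overlapping transcripts on both
strands.  Protein-coding transcripts have an ATG-initiated CDS with an
in-frame terminal stop (included in the annotated CDS) and clean GT..AG
introns; non-coding transcripts (lncRNA / pseudogene) are random exonic
sequence.  The proteome is exactly the translation of every coding CDS.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..config import CohortConfig
from ..genome import STOP_CODONS, TranscriptModel, revcomp, translate_cds, write_fasta, write_gtf

NUCS = np.array(list("ACGT"))

# sense codons only (no stops), used to build internal CDS codons
_ALL_CODONS = [a + b + c for a in "ACGT" for b in "ACGT" for c in "ACGT"]
SENSE_CODONS = [c for c in _ALL_CODONS if c not in STOP_CODONS and c != "ATG"]


@dataclass
class ReferenceBundle:
    genome: dict[str, str]
    transcripts: list[TranscriptModel]
    proteome: dict[str, str]
    contig: str = "chr1"

    def transcript(self, tid: str) -> TranscriptModel:
        return next(t for t in self.transcripts if t.id == tid)

    def write(self, outdir) -> None:
        from pathlib import Path

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_fasta(outdir / "genome.fa", self.genome)
        write_gtf(outdir / "transcripts.gtf", self.transcripts)
        write_fasta(outdir / "proteome.fa", self.proteome)


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(NUCS[rng.integers(0, 4, size=n)])


def _random_cds(rng: np.random.Generator, n_codons: int) -> str:
    """ATG + sense codons + one stop; no internal stops or internal ATG-frame starts."""
    body = "".join(SENSE_CODONS[i] for i in rng.integers(0, len(SENSE_CODONS), size=n_codons - 2))
    stop = STOP_CODONS[rng.integers(0, 3)]
    return "ATG" + body + stop


def generate_reference(config: CohortConfig) -> ReferenceBundle:
    """Build the toy reference deterministically from the config seed."""
    if config.n_transcripts < 1:
        raise ValueError("need at least one transcript")
    rng = np.random.default_rng(config.seed)
    n_coding = int(round(config.n_transcripts * config.coding_fraction))

    contig_parts: list[str] = []
    offset = 0
    transcripts: list[TranscriptModel] = []
    proteome: dict[str, str] = {}

    for i in range(config.n_transcripts):
        coding = i < n_coding
        tid = f"T{i:04d}"
        gene = f"G{i:04d}"
        strand = "+" if rng.random() < 0.5 else "-"
        if coding:
            utr5 = _random_seq(rng, int(rng.integers(15, 61)))
            n_codons = int(rng.integers(60, 201))
            cds = _random_cds(rng, n_codons)
            utr3 = _random_seq(rng, int(rng.integers(30, 91)))
            spliced = utr5 + cds + utr3
            cds_start, cds_end = len(utr5), len(utr5) + len(cds)
            biotype = "protein_coding"
        else:
            spliced = _random_seq(rng, int(rng.integers(300, 901)))
            cds_start = cds_end = None
            biotype = "lncRNA" if rng.random() < 0.5 else "pseudogene"

        # split the spliced sequence into exons and insert GT..AG introns
        n_exons = int(rng.integers(1, 5))
        cut_grid = np.arange(60, len(spliced) - 60, 50)  # 50 nt spacing keeps exons sizeable
        n_exons = min(n_exons, len(cut_grid) + 1)
        cuts = sorted(rng.choice(cut_grid, size=n_exons - 1, replace=False)) if n_exons > 1 else []
        bounds = [0, *map(int, cuts), len(spliced)]
        exon_seqs = [spliced[a:b] for a, b in zip(bounds, bounds[1:])]
        intron_seqs = ["GT" + _random_seq(rng, int(rng.integers(76, 196))) + "AG" for _ in exon_seqs[:-1]]

        pre_mrna = exon_seqs[0] + "".join(i + e for i, e in zip(intron_seqs, exon_seqs[1:]))
        locus_seq = pre_mrna if strand == "+" else revcomp(pre_mrna)

        spacer = _random_seq(rng, int(rng.integers(200, 601)))
        contig_parts.extend([spacer, locus_seq])
        locus_start = offset + len(spacer)
        offset = locus_start + len(locus_seq)

        # exon genomic intervals: walk the pre-mRNA layout
        ivs_premrna = []
        p = 0
        for k, e in enumerate(exon_seqs):
            ivs_premrna.append((p, p + len(e)))
            p += len(e) + (len(intron_seqs[k]) if k < len(intron_seqs) else 0)
        if strand == "+":
            exons = [(locus_start + a, locus_start + b) for a, b in ivs_premrna]
        else:
            L = len(pre_mrna)
            exons = sorted((locus_start + L - b, locus_start + L - a) for a, b in ivs_premrna)

        t = TranscriptModel(
            id=tid, gene=gene, contig="chr1", strand=strand, biotype=biotype,
            exons=exons, cds_start=cds_start, cds_end=cds_end,
        )
        transcripts.append(t)
        if coding:
            aa = translate_cds(cds)
            proteome[f"PROT_{tid}"] = aa[:-1]

    genome = {"chr1": "".join(contig_parts) + _random_seq(rng, 300)}
    return ReferenceBundle(genome=genome, transcripts=transcripts, proteome=proteome)
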