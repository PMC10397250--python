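"""Transcript models and reference sequence access.

Genomic intervals are 0-based half-open internally; VCF positions (1-based)
are converted on ingest.  Transcript coordinates are 0-based offsets into the
spliced (exon-concatenated) sequence read 5'->3' on the transcribed strand.
The annotated CDS of a coding transcript includes its stop codon.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import pyranges as pr
from Bio import SeqIO
from Bio.Seq import Seq

COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")
STOP_CODONS = ("TAA", "TAG", "TGA")


def revcomp(seq: str) -> str:
    return seq.translate(COMPLEMENT)[::-1]


def translate_cds(seq: str) -> str:
    """Translate a nucleotide sequence with the standard code, trimming to codons."""
    usable = len(seq) - len(seq) % 3
    return str(Seq(seq[:usable]).translate())


@dataclass
class TranscriptModel:
    """One transcript: exon structure, strand, biotype, optional CDS.

    ``exons`` are genomic (start, end) intervals sorted by genomic position;
    for minus-strand transcripts the 5'-most exon is therefore the last one.
    ``cds_start``/``cds_end`` are transcript coordinates (stop codon included).
    """

    id: str
    gene: str
    contig: str
    strand: str
    biotype: str
    exons: list[tuple[int, int]] = field(default_factory=list)
    cds_start: int | None = None
    cds_end: int | None = None

    def __post_init__(self) -> None:
        self.exons = sorted(self.exons)
        for (s1, e1), (s2, e2) in zip(self.exons, self.exons[1:]):
            if e1 > s2:
                raise ValueError(f"{self.id}: overlapping exons")
        if self.strand not in "+-":
            raise ValueError(f"{self.id}: bad strand {self.strand!r}")

    # -- basic geometry -------------------------------------------------
    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def length(self) -> int:
        return sum(e - s for s, e in self.exons)

    @property
    def is_coding(self) -> bool:
        return self.cds_start is not None

    def introns(self) -> list[tuple[int, int]]:
        """Genomic intervals between consecutive exons (genomic order)."""
        return [
            (e1, s2) for (_, e1), (s2, _) in zip(self.exons, self.exons[1:])
        ]

    # -- sequence -------------------------------------------------------
    def spliced_seq(self, genome: Mapping[str, str]) -> str:
        chrom = genome[self.contig]
        s = "".join(chrom[a:b] for a, b in self.exons)
        return revcomp(s) if self.strand == "-" else s

    def cds_seq(self, genome: Mapping[str, str]) -> str:
        if not self.is_coding:
            raise ValueError(f"{self.id} is non-coding")
        return self.spliced_seq(genome)[self.cds_start : self.cds_end]

    def protein(self, genome: Mapping[str, str]) -> str:
        """Translation of the CDS, stop codon excluded."""
        aa = translate_cds(self.cds_seq(genome))
        return aa[:-1] if aa.endswith("*") else aa

    # -- coordinate projection -----------------------------------------
    def genomic_to_transcript(self, gpos: int) -> int | None:
        """Map a 0-based genomic position to a transcript offset (None if intronic/outside)."""
        off = 0
        if self.strand == "+":
            for a, b in self.exons:
                if a <= gpos < b:
                    return off + (gpos - a)
                off += b - a
            return None
        for a, b in reversed(self.exons):
            if a <= gpos < b:
                return off + (b - 1 - gpos)
            off += b - a
        return None

    def splice_site_intron(self, gpos: int) -> int | None:
        """Index (transcript order, 0-based) of the intron whose 2-bp donor or
        acceptor dinucleotide contains ``gpos``; None otherwise."""
        intr = self.introns()
        for gi, (a, b) in enumerate(intr):
            if a <= gpos < a + 2 or b - 2 <= gpos < b:
                return gi if self.strand == "+" else len(intr) - 1 - gi
        return None

    def contains(self, gpos: int) -> bool:
        return self.start <= gpos < self.end


# ---------------------------------------------------------------------------
# FASTA / GTF io
# ---------------------------------------------------------------------------

def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(path, records: Mapping[str, str] | list[tuple[str, str]], width: int = 60) -> None:
    items = records.items() if isinstance(records, Mapping) else records
    with open(path, "w") as fh:
        for name, seq in items:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_gtf(path, transcripts: list[TranscriptModel], genome: Mapping[str, str] | None = None) -> None:
    """Write transcript/exon/CDS features with gene_id, transcript_id, transcript_biotype."""

    def attrs(t: TranscriptModel) -> str:
        return (
            f'gene_id "{t.gene}"; transcript_id "{t.id}"; '
            f'transcript_biotype "{t.biotype}";'
        )

    with open(path, "w") as fh:
        for t in sorted(transcripts, key=lambda t: (t.contig, t.start, t.id)):
            row = [t.contig, "neoseek", "transcript", str(t.start + 1), str(t.end), ".", t.strand, ".", attrs(t)]
            fh.write("\t".join(row) + "\n")
            for a, b in t.exons:
                fh.write("\t".join([t.contig, "neoseek", "exon", str(a + 1), str(b), ".", t.strand, ".", attrs(t)]) + "\n")
            if t.is_coding:
                for a, b in _cds_genomic_intervals(t):
                    fh.write("\t".join([t.contig, "neoseek", "CDS", str(a + 1), str(b), ".", t.strand, ".", attrs(t)]) + "\n")


def _cds_genomic_intervals(t: TranscriptModel) -> list[tuple[int, int]]:
    """Genomic intervals covered by the transcript-coordinate CDS span."""
    out = []
    exons = t.exons if t.strand == "+" else list(reversed(t.exons))
    off = 0
    for a, b in exons:
        ln = b - a
        lo, hi = max(t.cds_start, off), min(t.cds_end, off + ln)
        if lo < hi:
            if t.strand == "+":
                out.append((a + (lo - off), a + (hi - off)))
            else:
                out.append((b - (hi - off), b - (lo - off)))
        off += ln
    return sorted(out)


def read_gtf(path) -> list[TranscriptModel]:
    """Load transcript models from a GTF file (exon + CDS features)."""
    df = pr.read_gtf(str(path)).df
    models: dict[str, TranscriptModel] = {}
    cds_rows: dict[str, list[tuple[int, int]]] = {}
    for _, row in df.iterrows():
        tid = row["transcript_id"]
        if row["Feature"] == "exon":
            m = models.get(tid)
            if m is None:
                biotype = row.get("transcript_biotype") or row.get("gene_biotype") or "protein_coding"
                models[tid] = m = TranscriptModel(
                    id=tid,
                    gene=row["gene_id"],
                    contig=str(row["Chromosome"]),
                    strand=str(row["Strand"]),
                    biotype=str(biotype),
                    exons=[],
                )
            m.exons.append((int(row["Start"]), int(row["End"])))
        elif row["Feature"] == "CDS":
            cds_rows.setdefault(tid, []).append((int(row["Start"]), int(row["End"])))
    for tid, m in models.items():
        m.exons = sorted(m.exons)
        ivs = cds_rows.get(tid)
        if ivs:
            ivs = sorted(ivs)
            gpos_first = ivs[0][0] if m.strand == "+" else ivs[-1][1] - 1
            tpos = m.genomic_to_transcript(gpos_first)
            ln = sum(b - a for a, b in ivs)
            m.cds_start, m.cds_end = tpos, tpos + ln
    return sorted(models.values(), key=lambda t: (t.contig, t.start, t.id))
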