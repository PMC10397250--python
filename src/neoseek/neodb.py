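"""Mutated-peptide database construction.

Each variant is applied independently to the wild-type spliced transcript
sequence (no multi-variant phasing); open reading frames enclosing the
variant site are determined and translated, and mutant proteins that differ
from the canonical translation are emitted as database entries.

ORF semantics
-------------
For missense/in-frame events on protein-coding transcripts, the annotated
CDS frame is used; a substitution destroying the stop codon extends the CDS
into the 3'UTR to the next in-frame stop, and a start-loss falls back to a
frame scan.  For everything else (non-coding transcripts, frameshifts,
splice-site retention, stop/start events) each of the three reading frames
is scanned for the minimal ORF enclosing the variant anchor: the nearest
upstream ATG with no intervening in-frame stop, paired with the nearest
downstream in-frame stop.  At most one ORF per frame, hence at most three
per (variant, transcript).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .genome import COMPLEMENT, STOP_CODONS, TranscriptModel, revcomp, translate_cds
from .variants import Variant

log = logging.getLogger(__name__)

MAX_ORFS_PER_TRANSCRIPT = 3


# ---------------------------------------------------------------------------
# coordinate projection
# ---------------------------------------------------------------------------

@dataclass
class ProjectedVariant:
    """A variant expressed in transcript coordinates.

    ``kind`` is "exonic", "splice_site" (with the affected intron index in
    transcript order), or "intronic" (deep intronic; not processed further).
    For exonic projections ``tpos``/``ref``/``alt`` are strand-oriented.
    """

    kind: str
    tpos: int | None = None
    ref: str | None = None
    alt: str | None = None
    intron_index: int | None = None


def project_variant(variant: Variant, transcript: TranscriptModel) -> ProjectedVariant:
    """Project a genomic variant onto a transcript (strand-aware)."""
    if not (transcript.start <= variant.start < transcript.end or
            transcript.start < variant.end <= transcript.end):
        raise ValueError(f"{variant.key} outside span of {transcript.id}")
    span = range(variant.start, max(variant.end, variant.start + 1))
    for g in span:
        idx = transcript.splice_site_intron(g)
        if idx is not None:
            return ProjectedVariant(kind="splice_site", intron_index=idx)
    ref, alt = variant.ref, variant.alt
    if variant.vclass in ("SNV", "MNV"):
        anchor_g = variant.start if transcript.strand == "+" else variant.end - 1
        tpos = transcript.genomic_to_transcript(anchor_g)
        if tpos is None or transcript.genomic_to_transcript(variant.start) is None \
                or transcript.genomic_to_transcript(variant.end - 1) is None:
            return ProjectedVariant(kind="intronic")
        if transcript.strand == "-":
            ref, alt = revcomp(ref), revcomp(alt)
        return ProjectedVariant(kind="exonic", tpos=tpos, ref=ref, alt=alt)
    # anchored indel: the anchor base sits at pos-1 (0-based pos0)
    g_anchor = variant.pos - 1
    if variant.vclass == "deletion":
        deleted = range(variant.start, variant.end)
        if any(transcript.genomic_to_transcript(g) is None for g in deleted):
            return ProjectedVariant(kind="intronic")
    if transcript.genomic_to_transcript(g_anchor) is None:
        return ProjectedVariant(kind="intronic")
    if transcript.strand == "+":
        tpos = transcript.genomic_to_transcript(g_anchor)
        return ProjectedVariant(kind="exonic", tpos=tpos, ref=ref, alt=alt)
    # minus strand: re-anchor on the transcribed strand.  The reverse
    # complement of an anchored event "R -> A" at pos0 is an anchored event
    # whose anchor is the base downstream in genome coordinates; the anchor
    # base itself is resolved against the spliced sequence at application.
    rc_ref, rc_alt = revcomp(ref), revcomp(alt)
    g_last = variant.pos - 1 + len(variant.ref) - 1
    g_new_anchor = g_last + 1  # next genomic base = preceding transcript base
    tpos = transcript.genomic_to_transcript(g_new_anchor)
    if tpos is None:
        return ProjectedVariant(kind="intronic")
    return ProjectedVariant(kind="exonic", tpos=tpos, ref=rc_ref[:-1], alt=rc_alt[:-1])


# ---------------------------------------------------------------------------
# variant application
# ---------------------------------------------------------------------------

@dataclass
class MutatedSequence:
    """Spliced transcript sequence after applying one variant."""

    transcript_id: str
    seq: str
    anchor_start: int         # transcript coordinate where the change begins
    anchor_end: int           # end of the changed/novel region (half-open)
    variant_key: str
    kind: str                 # exonic | splice_site
    length_delta: int = 0
    retained_intron: tuple[int, int] | None = None  # span within seq
    cds_start: int | None = None
    cds_end: int | None = None


def apply_variant(
    transcript: TranscriptModel,
    variant: Variant,
    genome: Mapping[str, str],
) -> MutatedSequence | None:
    """Apply a variant to the spliced transcript sequence.

    Splice-site variants instead retain the affected intron in the mature
    sequence.  Returns None for deep-intronic variants.  Raises ValueError on
    reference-allele mismatch (corrupt inputs).
    """
    proj = project_variant(variant, transcript)
    spliced = transcript.spliced_seq(genome)
    if proj.kind == "intronic":
        return None
    if proj.kind == "splice_site":
        return _retain_intron(transcript, variant, genome, proj.intron_index, spliced)

    tpos = proj.tpos
    ref_t, alt_t = proj.ref, proj.alt
    if variant.vclass in ("SNV", "MNV"):
        if transcript.strand == "-":
            tpos = tpos  # already anchored at 5'-most changed base
        found = spliced[tpos : tpos + len(ref_t)]
        if found != ref_t:
            raise ValueError(
                f"ref mismatch for {variant.key} on {transcript.id}: expected {ref_t}, found {found}"
            )
        seq = spliced[:tpos] + alt_t + spliced[tpos + len(ref_t):]
        return MutatedSequence(
            transcript_id=transcript.id, seq=seq,
            anchor_start=tpos, anchor_end=tpos + len(alt_t),
            variant_key=variant.key, kind="exonic",
            cds_start=transcript.cds_start, cds_end=transcript.cds_end,
        )
    # anchored indel, strand-oriented minimal form: ref/alt share first base
    if transcript.strand == "-":
        # re-derive the strand-oriented alleles with the real anchor base
        rc_ref, rc_alt = revcomp(variant.ref), revcomp(variant.alt)
        anchor_base = spliced[tpos]
        ref_t = anchor_base + rc_ref[:-1]
        alt_t = anchor_base + rc_alt[:-1]
    found = spliced[tpos : tpos + len(ref_t)]
    if found != ref_t:
        raise ValueError(
            f"ref mismatch for {variant.key} on {transcript.id}: expected {ref_t}, found {found}"
        )
    seq = spliced[:tpos] + alt_t + spliced[tpos + len(ref_t):]
    delta = len(alt_t) - len(ref_t)
    return MutatedSequence(
        transcript_id=transcript.id, seq=seq,
        anchor_start=tpos, anchor_end=tpos + len(alt_t),
        variant_key=variant.key, kind="exonic", length_delta=delta,
        cds_start=transcript.cds_start, cds_end=transcript.cds_end,
    )


def _retain_intron(
    t: TranscriptModel,
    variant: Variant,
    genome: Mapping[str, str],
    intron_index: int,
    spliced: str,
) -> MutatedSequence:
    """Wild-type exon sequence with the affected intron retained in place."""
    introns = t.introns()  # genomic order
    gi = intron_index if t.strand == "+" else len(introns) - 1 - intron_index
    a, b = introns[gi]
    intron_seq = genome[t.contig][a:b]
    if t.strand == "-":
        intron_seq = revcomp(intron_seq)
    # transcript offset of the end of the exon 5' of this intron
    exons_t = t.exons if t.strand == "+" else list(reversed(t.exons))
    off = sum(e - s for s, e in exons_t[: intron_index + 1])
    seq = spliced[:off] + intron_seq + spliced[off:]
    # the mutation site is the exon/intron junction: an ORF qualifies when it
    # encloses the junction, reading into the retained intron until a stop
    return MutatedSequence(
        transcript_id=t.id, seq=seq,
        anchor_start=off, anchor_end=off + 1,
        variant_key=variant.key, kind="splice_site",
        length_delta=len(intron_seq),
        retained_intron=(off, off + len(intron_seq)),
        cds_start=t.cds_start, cds_end=t.cds_end,
    )


# ---------------------------------------------------------------------------
# ORF scanning
# ---------------------------------------------------------------------------

@dataclass
class OrfRecord:
    start: int   # transcript coordinate of the ATG (or annotated CDS start)
    end: int     # half-open end, past the stop codon
    frame: int   # start % 3
    mode: str    # canonical_cds | scan


def scan_orfs(
    mutated: MutatedSequence,
    mode: str,
    annotated_cds: tuple[int, int] | None = None,
) -> list[OrfRecord]:
    """Find up to three ORFs enclosing the variant anchor.

    ``mode='canonical_cds'`` uses the annotated frame (with stop-loss
    extension into the 3'UTR when the annotated stop is destroyed);
    ``mode='scan'`` searches all three frames for the minimal enclosing
    ATG..stop pair.
    """
    seq = mutated.seq
    a0, a1 = mutated.anchor_start, mutated.anchor_end
    if mode == "canonical_cds":
        if annotated_cds is None:
            raise ValueError("canonical_cds mode needs annotated CDS bounds")
        cs, _ = annotated_cds
        # walk the annotated frame from the start codon to the first stop;
        # this realizes the stop-loss extension into the 3'UTR automatically
        end = _first_inframe_stop(seq, cs)
        if end is None:
            return []
        return [OrfRecord(start=cs, end=end, frame=cs % 3, mode="canonical_cds")]
    orfs: list[OrfRecord] = []
    for frame in range(3):
        rec = _minimal_enclosing_orf(seq, frame, a0, a1)
        if rec is not None:
            orfs.append(rec)
    return orfs


def _first_inframe_stop(seq: str, start: int) -> int | None:
    """Half-open end of the ORF starting at ``start`` (past its stop codon)."""
    for p in range(start, len(seq) - 2, 3):
        if seq[p : p + 3] in STOP_CODONS:
            return p + 3
    return None


def _minimal_enclosing_orf(seq: str, frame: int, a0: int, a1: int) -> OrfRecord | None:
    """Nearest upstream ATG (no intervening in-frame stop) paired with the
    nearest downstream in-frame stop, enclosing [a0, a1)."""
    start = None
    for p in range(frame, min(a0, len(seq) - 3) + 1, 3):
        codon = seq[p : p + 3]
        if codon == "ATG":
            start = p
        elif codon in STOP_CODONS and p + 3 < a1:
            start = None  # this stop terminates any upstream ORF before the anchor
    if start is None:
        return None
    end = _first_inframe_stop(seq, start)
    if end is None or end < a1:
        return None
    return OrfRecord(start=start, end=end, frame=frame, mode="scan")


# ---------------------------------------------------------------------------
# translation and database emission
# ---------------------------------------------------------------------------

@dataclass
class MutPeptideEntry:
    """A translated mutant ORF destined for the search database."""

    protein: str
    transcript_id: str
    variant_key: str
    frame: int
    orf_start: int
    orf_end: int
    effect: str
    mutated_aa_start: int   # first protein residue touched by the change
    mutated_aa_end: int     # half-open; runs to the end for frame-altering events

    @property
    def header(self) -> str:
        return f"NEO|{self.transcript_id}|{self.variant_key}|F{self.frame}|{self.effect}"


#: effect classes whose novelty extends from the change point to the protein end
FRAME_ALTERING = frozenset({"frameshift", "splice_site", "stop_loss", "start_loss"})


def translate_and_emit(
    mutated: MutatedSequence,
    orfs: Sequence[OrfRecord],
    effect: str,
    canonical_proteins: Iterable[str],
) -> list[MutPeptideEntry]:
    """Translate ORFs and keep entries whose protein differs from every
    canonical translation of the transcript (amino-acid-change rule)."""
    canon = set(canonical_proteins)
    out: list[MutPeptideEntry] = []
    for orf in orfs:
        cds = mutated.seq[orf.start : orf.end]
        aa = translate_cds(cds)
        if "*" in aa[:-1]:
            raise AssertionError(f"internal stop in claimed ORF of {mutated.variant_key}")
        protein = aa[:-1] if aa.endswith("*") else aa
        if not protein or protein in canon:
            continue
        res0 = max(0, (mutated.anchor_start - orf.start) // 3)
        if effect in FRAME_ALTERING:
            res1 = len(protein)
        else:
            res1 = min(len(protein), (mutated.anchor_end - 1 - orf.start) // 3 + 1)
        if res0 >= len(protein):
            continue  # change lies past the translated region (e.g. in the stop)
        out.append(
            MutPeptideEntry(
                protein=protein,
                transcript_id=mutated.transcript_id,
                variant_key=mutated.variant_key,
                frame=orf.start % 3,
                orf_start=orf.start,
                orf_end=orf.end,
                effect=effect,
                mutated_aa_start=res0,
                mutated_aa_end=max(res1, res0 + 1),
            )
        )
    return out


def entries_for_variant(
    variant: Variant,
    transcript: TranscriptModel,
    genome: Mapping[str, str],
    effect: str | None = None,
) -> list[MutPeptideEntry]:
    """End-to-end: project, apply, scan, translate for one (variant, transcript)."""
    mutated = apply_variant(transcript, variant, genome)
    if mutated is None:
        return []
    canonical = [transcript.protein(genome)] if transcript.is_coding else []
    if effect is None:
        effect = _infer_effect(variant, transcript, mutated)
    if transcript.is_coding and mutated.kind == "exonic" and effect == "synonymous":
        return []
    if (
        transcript.is_coding
        and mutated.kind == "exonic"
        and effect in ("missense", "inframe_indel", "stop_loss", "synonymous")
        and transcript.cds_start <= mutated.anchor_start < transcript.cds_end + mutated.length_delta
    ):
        orfs = scan_orfs(mutated, "canonical_cds", (transcript.cds_start, transcript.cds_end))
    else:
        orfs = scan_orfs(mutated, "scan")
    entries = translate_and_emit(mutated, orfs, effect, canonical)
    return entries[:MAX_ORFS_PER_TRANSCRIPT]


def _infer_effect(variant: Variant, t: TranscriptModel, mutated: MutatedSequence) -> str:
    if mutated.kind == "splice_site":
        return "splice_site"
    if variant.vclass in ("insertion", "deletion"):
        return "frameshift" if variant.indel_len % 3 else "inframe_indel"
    if not t.is_coding:
        return "noncoding_exon"
    a = mutated.anchor_start
    if a < t.cds_start or a >= t.cds_end:
        return "UTR"
    # substitution in the CDS: compare the wild-type and mutant codon spans
    wt_cds_len = t.cds_end - t.cds_start
    cs = t.cds_start
    ci = (mutated.anchor_start - cs) // 3
    cj = (mutated.anchor_end - 1 - cs) // 3 + 1
    aa_mut = translate_cds(mutated.seq[cs : cs + wt_cds_len])
    aa_wt = translate_cds(_wildtype_cds(mutated, cs, wt_cds_len))
    wt_span, mut_span = aa_wt[ci:cj], aa_mut[ci:cj]
    if ci == 0 and aa_mut[:1] != "M":
        return "start_loss"
    if aa_mut == aa_wt:
        return "synonymous"
    if "*" in wt_span and "*" not in mut_span:
        return "stop_loss"
    if "*" in mut_span and "*" not in wt_span:
        return "stop_gain"
    return "missense"


def _wildtype_cds(mutated: MutatedSequence, cds_start: int, cds_len: int) -> str:
    """Undo the substitution held in ``mutated`` to recover the wild-type CDS."""
    a0, a1 = mutated.anchor_start, mutated.anchor_end
    # substitutions only (length-preserving); the ref allele in transcript
    # orientation is not stored, so rebuild via the variant key
    _, _, ref, alt = mutated.variant_key.split(":")
    seq = mutated.seq
    applied = seq[a0:a1]
    if applied == alt:
        wt = seq[:a0] + ref + seq[a1:]
    else:  # minus strand: applied alleles were reverse-complemented
        wt = seq[:a0] + revcomp(ref) + seq[a1:]
    return wt[cds_start : cds_start + cds_len]


# ---------------------------------------------------------------------------
# database building
# ---------------------------------------------------------------------------

def build_database(entries: Sequence[MutPeptideEntry], fasta_path, provenance_path) -> int:
    """Write the mutated-protein FASTA and a provenance TSV.

    Entries are ordered by (transcript, variant, frame); identical proteins
    arising from the same variant are collapsed into one FASTA record whose
    provenance rows are all preserved.  Returns the number of FASTA records.
    """
    if not entries:
        log.warning("empty mutated-peptide database")
    ordered = sorted(entries, key=lambda e: (e.transcript_id, e.variant_key, e.frame))
    groups: dict[tuple[str, str], list[MutPeptideEntry]] = {}
    for e in ordered:
        groups.setdefault((e.variant_key, e.protein), []).append(e)
    with open(fasta_path, "w") as fa, open(provenance_path, "w") as tsv:
        tsv.write("header\ttranscript\tvariant\tframe\teffect\tmut_aa_start\tmut_aa_end\tprotein\n")
        for (variant_key, protein), group in sorted(groups.items(), key=lambda kv: (kv[1][0].transcript_id, kv[0][0], kv[1][0].frame)):
            rep = group[0]
            fa.write(f">{rep.header}\n{protein}\n")
            for e in group:
                tsv.write(
                    f"{e.header}\t{e.transcript_id}\t{e.variant_key}\t{e.frame}\t{e.effect}\t"
                    f"{e.mutated_aa_start}\t{e.mutated_aa_end}\t{e.protein}\n"
                )
    return len(groups)


def read_provenance(provenance_path) -> list[MutPeptideEntry]:
    """Inverse of :func:`build_database` for the provenance table."""
    import csv

    out = []
    with open(provenance_path) as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            out.append(
                MutPeptideEntry(
                    protein=row["protein"],
                    transcript_id=row["transcript"],
                    variant_key=row["variant"],
                    frame=int(row["frame"]),
                    orf_start=0,
                    orf_end=0,
                    effect=row["effect"],
                    mutated_aa_start=int(row["mut_aa_start"]),
                    mutated_aa_end=int(row["mut_aa_end"]),
                )
            )
    return out
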