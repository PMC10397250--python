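"""DNA/RNA variant ingestion, population-SNP filtering, source reconciliation,
exchange/effect classification, TMB, and cross-patient sharing analysis.

Variants are stored in minimal representation: shared prefix/suffix bases are
trimmed (a one-base anchor is kept for pure insertions/deletions, matching the
VCF convention) so identical events called with different padding compare equal.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import pysam

from .genome import COMPLEMENT, TranscriptModel, translate_cds

log = logging.getLogger(__name__)

MAX_INDEL_LEN = 10  # indels longer than this are not annotated

GNOMAD_AF_MAX = 0.01  # population SNP if gnomAD AF > 1%
DBSNP_AF_MAX = 0.05   # population SNP if dbSNP AF > 5%

NUCS = "ACGT"
EXCHANGE_CLASSES = tuple(f"{a}>{b}" for a in NUCS for b in NUCS if a != b)

#: effect classes ordered most to least severe (reporting precedence)
EFFECT_SEVERITY = (
    "splice_site",
    "frameshift",
    "stop_gain",
    "stop_loss",
    "start_loss",
    "inframe_indel",
    "missense",
    "synonymous",
    "noncoding_exon",
    "UTR",
    "intron",
    "intergenic",
)

CODING_EFFECTS = frozenset(
    {"missense", "stop_gain", "stop_loss", "start_loss", "frameshift", "inframe_indel", "splice_site"}
)


def _trim(pos: int, ref: str, alt: str) -> tuple[int, str, str]:
    """Minimal representation of a (1-based pos, ref, alt) allele pair."""
    while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    return pos, ref, alt


def _vclass(ref: str, alt: str) -> str:
    if len(ref) == len(alt):
        return "SNV" if len(ref) == 1 else "MNV"
    return "insertion" if len(alt) > len(ref) else "deletion"


@dataclass
class Variant:
    """One called nucleotide change with source and annotation payload."""

    contig: str
    pos: int            # 1-based, VCF convention
    ref: str
    alt: str
    patient: str = ""
    source: str = "DNA_only"     # DNA_only | RNA_only | both
    af_gnomad: float | None = None
    af_dbsnp: float | None = None
    dna_ref_reads: int | None = None
    tumor_vaf: float | None = None

    def __post_init__(self) -> None:
        if self.ref == self.alt:
            raise ValueError(f"{self.key}: ref == alt")
        if self.indel_len > MAX_INDEL_LEN:
            raise ValueError(f"{self.key}: indel longer than {MAX_INDEL_LEN} bp")

    @property
    def vclass(self) -> str:
        return _vclass(self.ref, self.alt)

    @property
    def indel_len(self) -> int:
        return abs(len(self.alt) - len(self.ref))

    @property
    def key(self) -> str:
        return f"{self.contig}:{self.pos}:{self.ref}:{self.alt}"

    @property
    def start(self) -> int:
        """0-based genomic start of the changed bases (minimal representation)."""
        pos0 = self.pos - 1
        if self.vclass in ("SNV", "MNV"):
            return pos0
        return pos0 + 1  # anchored indel: change begins after the anchor base

    @property
    def end(self) -> int:
        """0-based half-open genomic end of the affected reference span."""
        if self.vclass == "insertion":
            return self.start  # zero-length reference footprint
        return self.pos - 1 + len(self.ref)


@dataclass
class EffectAnnotation:
    effect: str
    biotype: str = "other"
    transcript: str | None = None
    strand_oriented_exchange: str | None = None


@dataclass
class ProbeRegion:
    contig: str
    start: int  # 0-based half-open
    end: int
    mean_coverage: float = 0.0

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("probe region end must exceed start")


# ---------------------------------------------------------------------------
# ingestion
# ---------------------------------------------------------------------------

def parse_and_normalize(vcf_path, source_label: str, patient: str = "") -> list[Variant]:
    """Read a VCF, split multi-allelic records, trim to minimal representation,
    and drop indels longer than 10 bp (with a logged count)."""
    out: list[Variant] = []
    dropped = 0
    with pysam.VariantFile(str(vcf_path)) as vf:
        for rec in vf:
            info = rec.info
            ad = info.get("AD")
            dp = info.get("DP")
            for i, alt in enumerate(rec.alts or ()):
                pos, ref, a = _trim(rec.pos, rec.ref, str(alt))
                if abs(len(a) - len(ref)) > MAX_INDEL_LEN:
                    dropped += 1
                    continue
                vaf = None
                if ad is not None and dp:
                    try:
                        vaf = float(ad[i + 1]) / float(dp)
                    except (IndexError, TypeError, ZeroDivisionError):
                        vaf = None
                out.append(
                    Variant(
                        contig=rec.contig,
                        pos=pos,
                        ref=ref,
                        alt=a,
                        patient=patient,
                        source=source_label,
                        af_gnomad=_maybe_float(info.get("AF_GNOMAD")),
                        af_dbsnp=_maybe_float(info.get("AF_DBSNP")),
                        tumor_vaf=vaf,
                    )
                )
    if dropped:
        log.info("%s: dropped %d indel(s) longer than %d bp", vcf_path, dropped, MAX_INDEL_LEN)
    return out


def _maybe_float(x) -> float | None:
    return None if x is None else float(x)


# ---------------------------------------------------------------------------
# population-SNP filter
# ---------------------------------------------------------------------------

def filter_population_snps(
    variants: Sequence[Variant],
    gnomad_max: float = GNOMAD_AF_MAX,
    dbsnp_max: float = DBSNP_AF_MAX,
    strict_dbsnp: bool = False,
) -> tuple[list[Variant], list[Variant]]:
    """Split variants into (kept, excluded) by population allele frequency.

    Excluded iff gnomAD AF > 1% or dbSNP AF > 5%; variants without AF records
    are kept.  ``strict_dbsnp`` additionally excludes any variant carrying a
    dbSNP AF record at all (dbSNP-membership semantics).
    """
    kept, excluded = [], []
    for v in variants:
        is_pop = (v.af_gnomad is not None and v.af_gnomad > gnomad_max) or (
            v.af_dbsnp is not None and (strict_dbsnp or v.af_dbsnp > dbsnp_max)
        )
        (excluded if is_pop else kept).append(v)
    return kept, excluded


# ---------------------------------------------------------------------------
# source reconciliation
# ---------------------------------------------------------------------------

@dataclass
class RescueParams:
    """Cross-source rescue: a variant called by one caller is accepted in the
    other data layer if that layer shows at least ``min_alt_reads`` supporting
    reads at the site, without requiring an independent call."""

    min_alt_reads: int = 2


def merge_sources(
    dna_variants: Sequence[Variant],
    rna_variants: Sequence[Variant],
    dna_alt_reads: Mapping[tuple[str, int, str, str], int] | None = None,
    rna_alt_reads: Mapping[tuple[str, int, str, str], int] | None = None,
    rescue: RescueParams | None = None,
) -> list[Variant]:
    """Reconcile DNA and RNA calls of one patient into variants with source set.

    ``*_alt_reads`` map (contig, pos, ref, alt) to supporting-read counts in
    the respective layer, used for the rescue rule.
    """
    rescue = rescue or RescueParams()
    dna = {(v.contig, v.pos, v.ref, v.alt): v for v in dna_variants}
    rna = {(v.contig, v.pos, v.ref, v.alt): v for v in rna_variants}
    out: list[Variant] = []
    for k, v in dna.items():
        if k in rna:
            r = rna[k]
            out.append(replace(v, source="both", tumor_vaf=r.tumor_vaf if r.tumor_vaf is not None else v.tumor_vaf))
        elif rna_alt_reads and rna_alt_reads.get(k, 0) >= rescue.min_alt_reads:
            out.append(replace(v, source="both"))
        else:
            out.append(replace(v, source="DNA_only"))
    for k, v in rna.items():
        if k in dna:
            continue
        if dna_alt_reads and dna_alt_reads.get(k, 0) >= rescue.min_alt_reads:
            out.append(replace(v, source="both"))
        else:
            out.append(replace(v, source="RNA_only"))
    return out


def classify_dna_support(
    rna_only_variants: Sequence[Variant],
    dna_pileup: Mapping[tuple[str, int], int],
    min_reads: int = 3,
) -> dict[str, str]:
    """Per RNA-only variant: ``canonical_covered`` if the DNA data show at
    least ``min_reads`` reference-allele reads at the locus, else ``not_covered``.
    """
    out = {}
    for v in rna_only_variants:
        n = dna_pileup.get((v.contig, v.pos), 0)
        out[v.key] = "canonical_covered" if n >= min_reads else "not_covered"
    return out


# ---------------------------------------------------------------------------
# exchange classification
# ---------------------------------------------------------------------------

def classify_exchange(variant: Variant, transcripts: Sequence[TranscriptModel]) -> str:
    """Strand-oriented substitution class of an SNV (one of 12, e.g. "A>G").

    If all annotated transcripts overlapping the variant agree in strand, the
    exchange is reported on the transcribed strand (complemented for minus-
    strand genes); otherwise it is reported as called.
    """
    if variant.vclass != "SNV":
        return "non_SNV"
    g0 = variant.pos - 1
    strands = {t.strand for t in transcripts if t.contig == variant.contig and t.contains(g0)}
    ref, alt = variant.ref, variant.alt
    if strands == {"-"}:
        ref, alt = ref.translate(COMPLEMENT), alt.translate(COMPLEMENT)
    return f"{ref}>{alt}"


# ---------------------------------------------------------------------------
# TMB
# ---------------------------------------------------------------------------

def merge_intervals(ivs: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    out: list[tuple[int, int]] = []
    for s, e in sorted(ivs):
        if out and s <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


def compute_tmb(
    variants: Sequence[Variant],
    probe_regions: Sequence[ProbeRegion],
    effects: Mapping[str, str] | None = None,
) -> float:
    """Mutations per megabase over the qualifying probe territory.

    ``probe_regions`` must already be coverage-filtered and ±300 bp extended;
    overlapping regions are merged before the length computation.  The
    numerator counts variants with a coding (non-synonymous) effect — supplied
    via ``effects`` (variant key -> effect class), or all variants if no effect
    map is given — that overlap any qualifying region.
    """
    merged: dict[str, list[tuple[int, int]]] = {}
    for r in probe_regions:
        merged.setdefault(r.contig, []).append((r.start, r.end))
    merged = {c: merge_intervals(v) for c, v in merged.items()}
    total = sum(e - s for ivs in merged.values() for s, e in ivs)
    if total == 0:
        raise ValueError("no qualifying probe territory (zero total length)")

    def overlaps(v: Variant) -> bool:
        ivs = merged.get(v.contig, ())
        s, e = v.start, max(v.end, v.start + 1)
        return any(a < e and s < b for a, b in ivs)

    n = 0
    for v in variants:
        if effects is not None and effects.get(v.key) not in CODING_EFFECTS:
            continue
        if overlaps(v):
            n += 1
    return n / (total / 1e6)


# ---------------------------------------------------------------------------
# shared-variant analysis
# ---------------------------------------------------------------------------

@dataclass
class SharingSummary:
    per_variant_patients: dict[str, int]
    unique_fraction: float
    sharing_histogram: dict[int, int]
    cooccurrence: dict[frozenset, list[str]] = field(default_factory=dict)


def shared_variant_analysis(
    cohort_variants: Mapping[str, Iterable[Variant]],
    cooccurrence_min_patients: int = 10,
    cooccurrence_min_variants: int = 2,
) -> SharingSummary:
    """Cross-patient sharing of identical (contig, pos, ref, alt) variants.

    ``cohort_variants`` maps patient id -> variants; duplicate rows within a
    patient count once.  Co-occurrence sets are restricted to variants shared
    by at least ``cooccurrence_min_patients`` patients and reported for patient
    sets carrying at least ``cooccurrence_min_variants`` such variants.
    """
    if len(cohort_variants) < 2:
        raise ValueError("sharing analysis needs at least 2 patients")
    carriers: dict[str, set[str]] = {}
    for patient, vs in cohort_variants.items():
        for v in vs:
            carriers.setdefault(v.key, set()).add(patient)
    counts = {k: len(ps) for k, ps in carriers.items()}
    hist = Counter(counts.values())
    unique = hist.get(1, 0)
    co: dict[frozenset, list[str]] = {}
    for k, ps in carriers.items():
        if len(ps) >= cooccurrence_min_patients:
            co.setdefault(frozenset(ps), []).append(k)
    co = {ps: sorted(ks) for ps, ks in co.items() if len(ks) >= cooccurrence_min_variants}
    return SharingSummary(
        per_variant_patients=counts,
        unique_fraction=unique / len(counts) if counts else 1.0,
        sharing_histogram=dict(sorted(hist.items())),
        cooccurrence=co,
    )


# ---------------------------------------------------------------------------
# effect annotation
# ---------------------------------------------------------------------------

def _effect_in_transcript(v: Variant, t: TranscriptModel, genome: Mapping[str, str]) -> str | None:
    """Effect of a variant within one transcript, applying the precedence
    splice_site > frameshift/inframe_indel > stop/start classes >
    missense/synonymous > UTR > intron."""
    g0 = v.pos - 1
    if not t.contains(v.start) and not t.contains(max(v.start, v.end - 1)):
        return None
    for g in range(v.start, max(v.end, v.start + 1)):
        if t.splice_site_intron(g) is not None:
            return "splice_site"
    tpos = t.genomic_to_transcript(v.start if v.vclass != "insertion" else g0)
    if tpos is None:
        return "intron"
    if not t.is_coding:
        return "noncoding_exon"
    in_cds = t.cds_start <= tpos < t.cds_end
    if not in_cds:
        return "UTR"
    if v.vclass in ("insertion", "deletion"):
        return "frameshift" if v.indel_len % 3 else "inframe_indel"
    # substitution inside the CDS: translate the affected codon(s)
    spliced = t.spliced_seq(genome)
    ref_t, alt_t = v.ref, v.alt
    anchor = tpos
    if t.strand == "-":
        ref_t = ref_t.translate(COMPLEMENT)[::-1]
        alt_t = alt_t.translate(COMPLEMENT)[::-1]
        anchor = tpos - (len(v.ref) - 1)
    mutated = spliced[:anchor] + alt_t + spliced[anchor + len(ref_t):]
    cds_wt = spliced[t.cds_start : t.cds_end]
    cds_mut = mutated[t.cds_start : t.cds_end]
    aa_wt, aa_mut = translate_cds(cds_wt), translate_cds(cds_mut)
    if aa_mut == aa_wt:
        return "synonymous"
    ci = (anchor - t.cds_start) // 3
    cj = (anchor + len(ref_t) - 1 - t.cds_start) // 3 + 1  # codon range [ci, cj)
    wt_span, mut_span = aa_wt[ci:cj], aa_mut[ci:cj]
    if ci == 0 and aa_mut[:1] != "M":
        return "start_loss"
    if "*" in wt_span and "*" not in mut_span:
        return "stop_loss"
    if "*" in mut_span and "*" not in wt_span:
        return "stop_gain"
    return "missense"


def annotate_effect(
    variant: Variant,
    transcripts: Sequence[TranscriptModel],
    genome: Mapping[str, str],
) -> EffectAnnotation:
    """Most severe effect of the variant across overlapping transcripts."""
    best: tuple[int, str, TranscriptModel] | None = None
    for t in transcripts:
        if t.contig != variant.contig:
            continue
        eff = _effect_in_transcript(variant, t, genome)
        if eff is None:
            continue
        rank = EFFECT_SEVERITY.index(eff)
        if best is None or rank < best[0]:
            best = (rank, eff, t)
    if best is None:
        return EffectAnnotation(effect="intergenic", biotype="other",
                                strand_oriented_exchange=classify_exchange(variant, transcripts)
                                if variant.vclass == "SNV" else None)
    _, eff, t = best
    return EffectAnnotation(
        effect=eff,
        biotype=t.biotype,
        transcript=t.id,
        strand_oriented_exchange=classify_exchange(variant, transcripts)
        if variant.vclass == "SNV" else None,
    )
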