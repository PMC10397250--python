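"""Per-patient DNA/RNA variant call generation with planted ground truth.

The generator plants, per patient: population SNPs (present in both layers,
with gnomAD/dbSNP allele frequencies drawn from a mixture so both exclusion
rules fire), somatic DNA variants (re-detected at the RNA level with high
probability), RNA-only variants dominated by A>G exchanges on the
transcribed strand (the A-to-I editing signature), a cohort-shared RNA
variant pool, and special events (splice-site, frameshift, stop-loss).
VCFs are written on the forward genomic strand.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..config import CohortConfig
from ..genome import COMPLEMENT, STOP_CODONS, TranscriptModel
from .reference import ReferenceBundle

NUCS = "ACGT"
EXCHANGES_NON_AG = [f"{a}>{b}" for a in NUCS for b in NUCS if a != b and (a, b) != ("A", "G")]


@dataclass
class PlantedVariant:
    contig: str
    pos: int          # 1-based
    ref: str
    alt: str
    label: str        # population_snp | somatic_dna | rna_edit | rna_other | rna_shared | special:<kind>
    af_gnomad: float | None = None
    af_dbsnp: float | None = None
    in_dna: bool = False
    in_rna: bool = False
    vaf: float = 0.5
    transcript_id: str | None = None

    @property
    def key(self) -> str:
        return f"{self.contig}:{self.pos}:{self.ref}:{self.alt}"


@dataclass
class PatientVariants:
    patient: str
    variants: list[PlantedVariant]

    def by_label(self, prefix: str) -> list[PlantedVariant]:
        return [v for v in self.variants if v.label.startswith(prefix)]


@dataclass
class VariantGroundTruth:
    patients: dict[str, PatientVariants]
    shared_pool: list[PlantedVariant]
    dna_pileup: dict[str, dict[tuple[str, int], int]]  # patient -> locus -> ref reads

    def editing_fraction_planted(self, patient: str) -> float:
        pv = self.patients[patient]
        rna_only = [v for v in pv.variants if v.in_rna and not v.in_dna]
        if not rna_only:
            return 0.0
        return sum(1 for v in rna_only if v.label in ("rna_edit",) or
                   (v.label == "rna_shared" and _is_ag(v))) / len(rna_only)


def _is_ag(v: PlantedVariant) -> bool:
    return v.label in ("rna_edit",) or getattr(v, "_edited", False)


def _nb_count(rng: np.random.Generator, mean: float, size_param: float) -> int:
    if mean <= 0:
        return 0
    p = size_param / (size_param + mean)
    return int(rng.negative_binomial(size_param, p))


class _SiteIndex:
    """Exonic genomic positions indexed by the base on the transcribed strand."""

    def __init__(self, ref: ReferenceBundle):
        self.by_base: dict[str, list[tuple[int, TranscriptModel]]] = {b: [] for b in NUCS}
        chrom = ref.genome[ref.contig]
        for t in ref.transcripts:
            for a, b in t.exons:
                for g in range(a, b):
                    base = chrom[g]
                    tbase = base if t.strand == "+" else base.translate(COMPLEMENT)
                    if tbase in self.by_base:
                        self.by_base[tbase].append((g, t))

    def sample(self, rng: np.random.Generator, tbase: str, used: set[int]) -> tuple[int, TranscriptModel] | None:
        sites = self.by_base[tbase]
        for _ in range(200):
            g, t = sites[int(rng.integers(0, len(sites)))]
            if g not in used:
                return g, t
        return None


def _genomic_alt(t_strand: str, talt: str) -> str:
    return talt if t_strand == "+" else talt.translate(COMPLEMENT)


def generate_patient_variants(ref: ReferenceBundle, config: CohortConfig) -> VariantGroundTruth:
    """Plant the cohort's variant structure; deterministic in (config, seed)."""
    rng = np.random.default_rng(config.seed + 1)
    chrom = ref.genome[ref.contig]
    glen = len(chrom)
    index = _SiteIndex(ref)

    # ---- cohort-level population SNP panel -------------------------------
    n_snp = int(round(config.population_snp_rate * glen))
    snp_positions = sorted(int(p) for p in rng.choice(glen, size=n_snp, replace=False))
    panel: list[PlantedVariant] = []
    af_kinds = ["gnomad_common", "dbsnp_common", "rare", "no_af"]
    for i, g in enumerate(snp_positions):
        refb = chrom[g]
        if refb not in NUCS:
            continue
        altb = NUCS[(NUCS.index(refb) + 1 + int(rng.integers(0, 3))) % 4]
        kind = af_kinds[i % 4]
        if kind == "gnomad_common":
            af_g, af_d = float(rng.uniform(0.02, 0.5)), float(rng.uniform(0.01, 0.5))
        elif kind == "dbsnp_common":
            af_g, af_d = float(rng.uniform(0.0001, 0.009)), float(rng.uniform(0.06, 0.5))
        elif kind == "rare":
            af_g, af_d = float(rng.uniform(0.0001, 0.009)), float(rng.uniform(0.001, 0.04))
        else:
            af_g = af_d = None
        panel.append(
            PlantedVariant(ref.contig, g + 1, refb, altb, "population_snp",
                           af_gnomad=af_g, af_dbsnp=af_d, in_dna=True, in_rna=True)
        )

    # ---- cohort-shared RNA-only pool -------------------------------------
    used: set[int] = {v.pos - 1 for v in panel}
    pool: list[PlantedVariant] = []
    for i in range(config.shared_pool_size):
        edited = rng.random() < config.editing_fraction
        if edited:
            hit = index.sample(rng, "A", used)
            if hit is None:
                continue
            g, t = hit
            talt = "G"
        else:
            cls = EXCHANGES_NON_AG[int(rng.integers(0, len(EXCHANGES_NON_AG)))]
            tref, talt = cls.split(">")
            hit = index.sample(rng, tref, used)
            if hit is None:
                continue
            g, t = hit
        used.add(g)
        v = PlantedVariant(
            ref.contig, g + 1, chrom[g], _genomic_alt(t.strand, talt),
            "rna_shared", in_rna=True, transcript_id=t.id,
        )
        v._edited = edited  # noqa: SLF001 — transcribed-strand A>G marker
        pool.append(v)

    # ---- per-patient variants --------------------------------------------
    patients: dict[str, PatientVariants] = {}
    pileups: dict[str, dict[tuple[str, int], int]] = {}
    for pi in range(config.n_patients):
        name = f"P{pi + 1:02d}"
        prng = np.random.default_rng(config.seed + 100 + pi)
        taken = used  # cohort-global: private variants never recur across patients
        out: list[PlantedVariant] = []

        for v in panel:  # population SNPs: each patient carries a subset
            if prng.random() < 0.6:
                out.append(v)

        n_som = _nb_count(prng, config.n_somatic_dna, config.nb_dispersion)
        for _ in range(n_som):
            g, t = _sample_any_exonic(prng, index, taken)
            taken.add(g)
            refb = chrom[g]
            altb = NUCS[(NUCS.index(refb) + 1 + int(prng.integers(0, 3))) % 4]
            out.append(
                PlantedVariant(ref.contig, g + 1, refb, altb, "somatic_dna",
                               in_dna=True, in_rna=prng.random() < config.rna_detection_prob,
                               vaf=float(prng.uniform(0.15, 0.7)), transcript_id=t.id)
            )

        n_rna = _nb_count(prng, config.n_rna_only, config.nb_dispersion)
        n_shared = min(int(round(config.shared_fraction * n_rna)), len(pool))
        shared_idx = prng.choice(len(pool), size=n_shared, replace=False) if n_shared else []
        for si in sorted(int(x) for x in shared_idx):
            out.append(pool[si])
        for _ in range(n_rna - n_shared):
            edited = prng.random() < config.editing_fraction
            if edited:
                hit = index.sample(prng, "A", taken)
                if hit is None:
                    continue
                g, t = hit
                talt, label = "G", "rna_edit"
            else:
                cls = EXCHANGES_NON_AG[int(prng.integers(0, len(EXCHANGES_NON_AG)))]
                tref, talt = cls.split(">")
                hit = index.sample(prng, tref, taken)
                if hit is None:
                    continue
                g, t = hit
                label = "rna_other"
            taken.add(g)
            out.append(
                PlantedVariant(ref.contig, g + 1, chrom[g], _genomic_alt(t.strand, talt),
                               label, in_rna=True, vaf=float(prng.uniform(0.1, 0.9)),
                               transcript_id=t.id)
            )

        out.extend(_plant_special_events(prng, ref, config, taken))
        out.sort(key=lambda v: (v.pos, v.alt))
        patients[name] = PatientVariants(patient=name, variants=out)

        # DNA pileup at RNA-only loci: most are canonically covered (>= 3 reads)
        pile: dict[tuple[str, int], int] = {}
        for v in out:
            if v.in_rna and not v.in_dna:
                covered = prng.random() >= 0.25
                pile[(v.contig, v.pos)] = int(prng.poisson(20) + 3) if covered else int(prng.integers(0, 3))
        pileups[name] = pile

    return VariantGroundTruth(patients=patients, shared_pool=pool, dna_pileup=pileups)


def _sample_any_exonic(rng, index: _SiteIndex, used: set[int]):
    base = NUCS[int(rng.integers(0, 4))]
    hit = index.sample(rng, base, used)
    if hit is None:  # fall back to any base
        for b in NUCS:
            hit = index.sample(rng, b, used)
            if hit is not None:
                break
    if hit is None:
        raise RuntimeError("toy genome exhausted while planting variants")
    return hit


def _productive(v: PlantedVariant, t: TranscriptModel, ref: ReferenceBundle) -> bool:
    """True if the event yields at least one mutant database entry (events
    without representable novelty, e.g. a stop-loss with no in-frame stop
    anywhere in the 3'UTR, are not planted as ground truth)."""
    from ..neodb import entries_for_variant
    from ..variants import Variant

    try:
        var = Variant(contig=v.contig, pos=v.pos, ref=v.ref, alt=v.alt)
        return bool(entries_for_variant(var, t, ref.genome))
    except (ValueError, AssertionError):
        return False


def _plant_special_events(
    rng: np.random.Generator,
    ref: ReferenceBundle,
    config: CohortConfig,
    taken: set[int],
) -> list[PlantedVariant]:
    chrom = ref.genome[ref.contig]
    out: list[PlantedVariant] = []
    coding = [t for t in ref.transcripts if t.is_coding]

    # splice-site: hit the donor dinucleotide of an intron of a coding transcript
    want = config.special_event_counts.get("splice_site", 0)
    donor_sites = []
    for t in coding:
        for a, b in t.introns():
            g = a if t.strand == "+" else b - 1
            if g not in taken:
                donor_sites.append((g, t))
    planted = 0
    for g, t in _pick(rng, donor_sites, len(donor_sites)):
        if planted >= want:
            break
        refb = chrom[g]
        altb = "A" if refb != "A" else "C"
        v = PlantedVariant(ref.contig, g + 1, refb, altb, "special:splice_site",
                           in_rna=True, transcript_id=t.id)
        if not _productive(v, t, ref):
            continue
        taken.add(g)
        out.append(v)
        planted += 1
    if planted < want:
        raise ValueError(
            f"requested {want} splice-site events but only {planted} productive donor sites available"
        )

    # frameshift: 1- or 2-bp deletion inside the CDS, clear of exon boundaries
    want = config.special_event_counts.get("frameshift", 0)
    fs_sites = []
    for t in coding:
        sp = t.spliced_seq(ref.genome)
        mid = (t.cds_start + t.cds_end) // 2
        g = _transcript_to_genomic(t, mid)
        if g is not None and _well_inside_exon(t, g, margin=6) and g not in taken and (g - 1) not in taken:
            fs_sites.append((g, t))
    planted = 0
    for g, t in _pick(rng, fs_sites, len(fs_sites)):
        if planted >= want:
            break
        dellen = int(rng.integers(1, 3))
        anchor = g - 1  # VCF-style anchor base preceding the deleted span
        refseq = chrom[anchor : anchor + dellen + 1]
        v = PlantedVariant(ref.contig, anchor + 1, refseq, refseq[0], "special:frameshift",
                           in_rna=True, transcript_id=t.id)
        if not _productive(v, t, ref):
            continue
        taken.update(range(anchor, anchor + dellen + 1))
        out.append(v)
        planted += 1
    if planted < want:
        raise ValueError(f"requested {want} frameshift events but only {planted} productive CDS sites available")

    # stop-loss: substitution in the annotated stop codon producing a sense codon
    want = config.special_event_counts.get("stop_loss", 0)
    sl_sites = []
    for t in coding:
        sp = t.spliced_seq(ref.genome)
        stop = sp[t.cds_end - 3 : t.cds_end]
        for off in range(3):
            tpos = t.cds_end - 3 + off
            g = _transcript_to_genomic(t, tpos)
            if g is None or g in taken or not _well_inside_exon(t, g, margin=0):
                continue
            for talt in NUCS:
                if talt == stop[off]:
                    continue
                if stop[:off] + talt + stop[off + 1:] not in STOP_CODONS:
                    sl_sites.append((g, t, stop[off], talt))
                    break
            if sl_sites and sl_sites[-1][1] is t:
                break
    planted = 0
    for g, t, tref, talt in _pick(rng, sl_sites, len(sl_sites)):
        if planted >= want:
            break
        v = PlantedVariant(ref.contig, g + 1, chrom[g], _genomic_alt(t.strand, talt),
                           "special:stop_loss", in_rna=True, transcript_id=t.id)
        if not _productive(v, t, ref):
            continue
        taken.add(g)
        out.append(v)
        planted += 1
    if planted < want:
        raise ValueError(f"requested {want} stop-loss events but only {planted} productive stop codons available")
    return out


def _pick(rng: np.random.Generator, items: list, k: int) -> list:
    if k == 0 or not items:
        return []
    idx = rng.choice(len(items), size=min(k, len(items)), replace=False)
    return [items[int(i)] for i in np.sort(idx)]


def _transcript_to_genomic(t: TranscriptModel, tpos: int) -> int | None:
    off = 0
    exons = t.exons if t.strand == "+" else list(reversed(t.exons))
    for a, b in exons:
        ln = b - a
        if tpos < off + ln:
            return a + (tpos - off) if t.strand == "+" else b - 1 - (tpos - off)
        off += ln
    return None


def _well_inside_exon(t: TranscriptModel, g: int, margin: int = 3) -> bool:
    return any(a + margin <= g < b - margin for a, b in t.exons)


# ---------------------------------------------------------------------------
# VCF writing
# ---------------------------------------------------------------------------

VCF_HEADER = """##fileformat=VCFv4.2
##contig=<ID={contig},length={length}>
##INFO=<ID=AF_GNOMAD,Number=1,Type=Float,Description="gnomAD population allele frequency">
##INFO=<ID=AF_DBSNP,Number=1,Type=Float,Description="dbSNP population allele frequency">
##INFO=<ID=DP,Number=1,Type=Integer,Description="read depth">
##INFO=<ID=AD,Number=R,Type=Integer,Description="allelic depths">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO
"""


def write_vcf(path, variants: list[PlantedVariant], contig: str, contig_len: int,
              rng: np.random.Generator) -> None:
    with open(path, "w") as fh:
        fh.write(VCF_HEADER.format(contig=contig, length=contig_len))
        for v in sorted(variants, key=lambda v: (v.pos, v.alt)):
            dp = int(rng.poisson(50) + 10)
            alt_reads = max(1, int(round(dp * v.vaf)))
            info = [f"DP={dp}", f"AD={dp - alt_reads},{alt_reads}"]
            if v.af_gnomad is not None:
                info.insert(0, f"AF_GNOMAD={v.af_gnomad:.6f}")
            if v.af_dbsnp is not None:
                info.insert(1 if v.af_gnomad is not None else 0, f"AF_DBSNP={v.af_dbsnp:.6f}")
            fh.write(f"{v.contig}\t{v.pos}\t.\t{v.ref}\t{v.alt}\t.\tPASS\t{';'.join(info)}\n")


def write_patient_vcfs(outdir, gt: VariantGroundTruth, ref: ReferenceBundle, seed: int) -> None:
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    clen = len(ref.genome[ref.contig])
    for idx, (name, pv) in enumerate(sorted(gt.patients.items())):
        rng = np.random.default_rng(seed + 1000 + idx)
        write_vcf(outdir / f"{name}.dna.vcf", [v for v in pv.variants if v.in_dna], ref.contig, clen, rng)
        write_vcf(outdir / f"{name}.rna.vcf", [v for v in pv.variants if v.in_rna], ref.contig, clen, rng)
        with open(outdir / f"{name}.dna_pileup.tsv", "w") as fh:
            fh.write("contig\tpos\tref_reads\talt_reads\n")
            for (c, p), n in sorted(gt.dna_pileup[name].items()):
                fh.write(f"{c}\t{p}\t{n}\t0\n")
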