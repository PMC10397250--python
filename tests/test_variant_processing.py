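"""Variant ingestion, population-SNP filtering, source reconciliation,
exchange/effect classification, TMB, and sharing analysis."""

import numpy as np
import pytest

from neoseek.genome import TranscriptModel
from neoseek.variants import (
    ProbeRegion,
    Variant,
    annotate_effect,
    classify_dna_support,
    classify_exchange,
    compute_tmb,
    filter_population_snps,
    merge_sources,
    parse_and_normalize,
    shared_variant_analysis,
)

VCF_TEMPLATE = """##fileformat=VCFv4.2
##contig=<ID=chr1,length=100000>
##INFO=<ID=AF_GNOMAD,Number=1,Type=Float,Description="x">
##INFO=<ID=AF_DBSNP,Number=1,Type=Float,Description="x">
##INFO=<ID=DP,Number=1,Type=Integer,Description="x">
##INFO=<ID=AD,Number=R,Type=Integer,Description="x">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO
{rows}"""


def _write_vcf(tmp_path, rows):
    path = tmp_path / "t.vcf"
    path.write_text(VCF_TEMPLATE.format(rows="".join(r + "\n" for r in rows)))
    return path


class TestParseAndNormalize:
    def test_multiallelic_split(self, tmp_path):
        path = _write_vcf(tmp_path, ["chr1\t100\t.\tA\tG,T\t.\tPASS\tDP=30;AD=20,8,2"])
        vs = parse_and_normalize(path, "RNA_only")
        assert [(v.pos, v.ref, v.alt) for v in vs] == [(100, "A", "G"), (100, "A", "T")]

    def test_long_indel_dropped(self, tmp_path):
        path = _write_vcf(tmp_path, [
            "chr1\t200\t.\tA\tAGGGGGGGGGGG\t.\tPASS\tDP=10",   # 11 bp insertion
            "chr1\t300\t.\tA\tAGGG\t.\tPASS\tDP=10",            # 3 bp, kept
        ])
        vs = parse_and_normalize(path, "DNA_only")
        assert len(vs) == 1 and vs[0].pos == 300

    def test_empty_vcf(self, tmp_path):
        path = _write_vcf(tmp_path, [])
        assert parse_and_normalize(path, "DNA_only") == []

    def test_padding_trimmed_to_minimal(self, tmp_path):
        path = _write_vcf(tmp_path, ["chr1\t100\t.\tCAT\tCGT\t.\tPASS\tDP=9"])
        (v,) = parse_and_normalize(path, "DNA_only")
        assert (v.pos, v.ref, v.alt) == (101, "A", "G")


class TestPopulationSnpFilter:
    @pytest.mark.parametrize(
        "af_g, af_d, excluded",
        [
            (0.02, None, True),       # gnomAD > 1%
            (0.005, 0.02, False),     # below both thresholds
            (None, 0.06, True),       # dbSNP > 5%
            (None, None, False),      # no AF record: kept
            (0.01, 0.05, False),      # exactly at thresholds: kept (strict >)
        ],
    )
    def test_threshold_rules(self, af_g, af_d, excluded):
        v = Variant("chr1", 10, "A", "G", af_gnomad=af_g, af_dbsnp=af_d)
        kept, excl = filter_population_snps([v])
        assert (len(excl) == 1) is excluded

    def test_conservation(self):
        rng = np.random.default_rng(0)
        vs = [
            Variant("chr1", int(i) + 1, "A", "G",
                    af_gnomad=float(rng.uniform(0, 0.05)) if rng.random() < 0.7 else None,
                    af_dbsnp=float(rng.uniform(0, 0.2)) if rng.random() < 0.5 else None)
            for i in range(200)
        ]
        kept, excl = filter_population_snps(vs)
        assert len(kept) + len(excl) == len(vs)
        assert {v.key for v in kept} | {v.key for v in excl} == {v.key for v in vs}

    def test_strict_dbsnp_mode(self):
        v = Variant("chr1", 10, "A", "G", af_dbsnp=0.001)
        kept, excl = filter_population_snps([v], strict_dbsnp=True)
        assert excl and not kept


class TestMergeSources:
    def test_called_in_both(self):
        d = [Variant("chr1", 10, "A", "G", source="DNA_only")]
        r = [Variant("chr1", 10, "A", "G", source="RNA_only")]
        (m,) = merge_sources(d, r)
        assert m.source == "both"

    def test_rescue_with_two_alt_reads(self):
        r = [Variant("chr1", 10, "A", "G")]
        (m,) = merge_sources([], r, dna_alt_reads={("chr1", 10, "A", "G"): 2})
        assert m.source == "both"

    def test_no_rescue_without_support(self):
        r = [Variant("chr1", 10, "A", "G")]
        (m,) = merge_sources([], r, dna_alt_reads={("chr1", 10, "A", "G"): 0})
        assert m.source == "RNA_only"

    def test_symmetry_up_to_label(self):
        d = [Variant("chr1", 10, "A", "G"), Variant("chr1", 20, "C", "T")]
        r = [Variant("chr1", 10, "A", "G"), Variant("chr1", 30, "G", "A")]
        fwd = {v.key: v.source for v in merge_sources(d, r)}
        rev = {v.key: v.source for v in merge_sources(r, d)}
        swap = {"DNA_only": "RNA_only", "RNA_only": "DNA_only", "both": "both"}
        assert rev == {k: swap[s] for k, s in fwd.items()}


class TestDnaSupport:
    @pytest.mark.parametrize("reads, expected", [(10, "canonical_covered"), (3, "canonical_covered"), (2, "not_covered")])
    def test_read_threshold(self, reads, expected):
        v = Variant("chr1", 50, "A", "G")
        assert classify_dna_support([v], {("chr1", 50): reads})[v.key] == expected

    def test_missing_locus_not_covered(self):
        v = Variant("chr1", 50, "A", "G")
        assert classify_dna_support([v], {})[v.key] == "not_covered"


class TestClassifyExchange:
    def _tx(self, strand):
        return TranscriptModel(id="t", gene="g", contig="chr1", strand=strand,
                               biotype="protein_coding", exons=[(0, 100)])

    def test_plus_strand_as_called(self):
        assert classify_exchange(Variant("chr1", 10, "A", "G"), [self._tx("+")]) == "A>G"

    def test_minus_strand_complemented(self):
        assert classify_exchange(Variant("chr1", 10, "T", "C"), [self._tx("-")]) == "A>G"

    def test_intergenic_reported_as_called(self):
        assert classify_exchange(Variant("chr1", 500, "A", "G"), [self._tx("+")]) == "A>G"

    def test_non_snv_marker(self):
        assert classify_exchange(Variant("chr1", 10, "AT", "A"), [self._tx("+")]) == "non_SNV"


class TestTmb:
    def test_simple_density(self):
        regions = [ProbeRegion("chr1", 0, 40_000_000, 30)]
        vs = [Variant("chr1", int(i) * 1000 + 1, "A", "G") for i in range(80)]
        assert compute_tmb(vs, regions) == pytest.approx(80 / 40)

    def test_zero_mutations(self):
        assert compute_tmb([], [ProbeRegion("chr1", 0, 1_000_000, 30)]) == 0.0

    def test_overlapping_regions_merged(self):
        regions = [ProbeRegion("chr1", 0, 1_000_000, 30), ProbeRegion("chr1", 500_000, 1_500_000, 30)]
        vs = [Variant("chr1", p, "A", "G") for p in (100, 600_000, 1_200_000)]
        assert compute_tmb(vs, regions) == pytest.approx(3 / 1.5)

    def test_split_invariance(self):
        vs = [Variant("chr1", p, "A", "G") for p in (10, 500, 900)]
        whole = compute_tmb(vs, [ProbeRegion("chr1", 0, 1000, 30)])
        parts = compute_tmb(vs, [ProbeRegion("chr1", 0, 400, 30), ProbeRegion("chr1", 400, 1000, 30)])
        assert whole == pytest.approx(parts)

    def test_zero_territory_is_error(self):
        with pytest.raises(ValueError):
            compute_tmb([], [])

    def test_noncoding_effects_excluded(self):
        vs = [Variant("chr1", 100, "A", "G"), Variant("chr1", 200, "C", "T")]
        effects = {vs[0].key: "missense", vs[1].key: "intron"}
        tmb = compute_tmb(vs, [ProbeRegion("chr1", 0, 1_000_000, 30)], effects=effects)
        assert tmb == pytest.approx(1.0)


class TestSharing:
    def test_enumeration(self):
        v1, v2, v3 = (Variant("chr1", p, "A", "G") for p in (10, 20, 30))
        s = shared_variant_analysis({"P1": [v1, v2], "P2": [v1, v3], "P3": [v1]},
                                    cooccurrence_min_patients=2)
        assert s.per_variant_patients[v1.key] == 3
        assert s.unique_fraction == pytest.approx(2 / 3)

    def test_disjoint_sets_all_unique(self):
        s = shared_variant_analysis({
            "P1": [Variant("chr1", 10, "A", "G")],
            "P2": [Variant("chr1", 20, "A", "G")],
        })
        assert s.unique_fraction == 1.0

    def test_within_patient_dedup(self):
        v = Variant("chr1", 10, "A", "G")
        s = shared_variant_analysis({"P1": [v, v], "P2": []})
        assert s.per_variant_patients[v.key] == 1

    def test_needs_two_patients(self):
        with pytest.raises(ValueError):
            shared_variant_analysis({"P1": []})


class TestAnnotateEffect:
    def test_missense_codon_change(self, reference):
        t = next(t for t in reference.transcripts if t.is_coding and t.strand == "+")
        # substitute the middle base of the 2nd CDS codon (AAA->AGA style check
        # is realised on whatever codon is present; assert missense/synonymous family)
        tpos = t.cds_start + 4
        g = [gg for gg in range(t.start, t.end) if t.genomic_to_transcript(gg) == tpos][0]
        ref_base = reference.genome["chr1"][g]
        alt = {"A": "G", "C": "T", "G": "A", "T": "C"}[ref_base]
        ann = annotate_effect(Variant("chr1", g + 1, ref_base, alt), [t], reference.genome)
        assert ann.effect in {"missense", "synonymous"}
        assert ann.transcript == t.id

    def test_splice_donor_base(self, reference):
        t = next(t for t in reference.transcripts if len(t.exons) > 1 and t.strand == "+")
        a, _ = t.introns()[0]
        ref_base = reference.genome["chr1"][a]  # the G of GT
        ann = annotate_effect(Variant("chr1", a + 1, ref_base, "A" if ref_base != "A" else "C"),
                              [t], reference.genome)
        assert ann.effect == "splice_site"

    def test_noncoding_exon_biotype(self, reference):
        t = next(t for t in reference.transcripts if not t.is_coding)
        g = t.exons[0][0] + 5
        ref_base = reference.genome["chr1"][g]
        ann = annotate_effect(Variant("chr1", g + 1, ref_base, "A" if ref_base != "A" else "C"),
                              [t], reference.genome)
        assert ann.effect == "noncoding_exon"
        assert ann.biotype in {"lncRNA", "pseudogene"}

    def test_unknown_contig_is_intergenic(self, reference):
        ann = annotate_effect(Variant("chrZ", 10, "A", "G"), reference.transcripts, reference.genome)
        assert ann.effect == "intergenic"
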