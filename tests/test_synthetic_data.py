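"""Generator contracts: determinism, planted statistical structure, and
traceability of ground truth through the generated files."""

import dataclasses
import filecmp
import json

import numpy as np
import pytest

from neoseek.config import CohortConfig
from neoseek.genome import STOP_CODONS, revcomp
from neoseek.synthetic import generate_cohort, generate_reference
from neoseek.synthetic.normals import generate_normal_cohort
from neoseek.synthetic.variants import generate_patient_variants


class TestConfig:
    def test_fraction_bounds_enforced(self):
        with pytest.raises(ValueError, match="editing_fraction"):
            CohortConfig(editing_fraction=1.5)

    def test_negative_count_rejected(self):
        with pytest.raises(ValueError):
            CohortConfig(n_patients=-1)

    def test_yaml_round_trip(self, tmp_path):
        cfg = CohortConfig(seed=9, n_patients=2)
        cfg.to_yaml(tmp_path / "c.yaml")
        assert CohortConfig.from_yaml(tmp_path / "c.yaml") == cfg


class TestReference:
    def test_coding_count_forced_by_config(self):
        cfg = CohortConfig(n_transcripts=10, coding_fraction=0.8, seed=1)
        ref = generate_reference(cfg)
        assert sum(t.is_coding for t in ref.transcripts) == 8
        assert len(ref.transcripts) == 10

    def test_proteome_is_cds_translation(self, reference):
        for t in reference.transcripts:
            if t.is_coding:
                assert reference.proteome[f"PROT_{t.id}"] == t.protein(reference.genome)

    def test_cds_structure(self, reference):
        for t in reference.transcripts:
            if not t.is_coding:
                continue
            cds = t.cds_seq(reference.genome)
            assert cds.startswith("ATG") and cds[-3:] in STOP_CODONS and len(cds) % 3 == 0

    def test_introns_canonical(self, reference):
        for t in reference.transcripts:
            for a, b in t.introns():
                intron = reference.genome["chr1"][a:b]
                if t.strand == "-":
                    intron = revcomp(intron)
                assert intron[:2] == "GT" and intron[-2:] == "AG"

    def test_both_strands_represented(self, reference):
        assert {t.strand for t in reference.transcripts} == {"+", "-"}

    def test_zero_transcripts_is_error(self):
        with pytest.raises(ValueError):
            generate_reference(CohortConfig(n_transcripts=0))

    def test_determinism_byte_identical(self, tmp_path):
        cfg = CohortConfig(n_transcripts=8, seed=5)
        for d in ("a", "b"):
            generate_reference(cfg).write(tmp_path / d)
        for f in ("genome.fa", "transcripts.gtf", "proteome.fa"):
            assert filecmp.cmp(tmp_path / "a" / f, tmp_path / "b" / f, shallow=False)


class TestPatientVariants:
    def test_editing_fraction_within_three_sd(self):
        cfg = CohortConfig(seed=7, n_patients=1, n_transcripts=25,
                           editing_fraction=0.6, n_rna_only=500, shared_fraction=0.0,
                           special_event_counts={})
        ref = generate_reference(cfg)
        gt = generate_patient_variants(ref, cfg)
        pv = gt.patients["P01"]
        rna_only = [v for v in pv.variants if v.in_rna and not v.in_dna]
        n_ag = sum(1 for v in rna_only if v.label == "rna_edit")
        n = len(rna_only)
        sd = np.sqrt(0.6 * 0.4 / n)
        assert abs(n_ag / n - 0.6) <= 3 * sd

    def test_no_sharing_when_fraction_zero(self):
        cfg = CohortConfig(seed=3, n_patients=3, shared_fraction=0.0, n_rna_only=100,
                           special_event_counts={})
        ref = generate_reference(cfg)
        gt = generate_patient_variants(ref, cfg)
        seen: dict[str, set] = {}
        for p, pv in gt.patients.items():
            for v in pv.variants:
                if v.in_rna and not v.in_dna:
                    seen.setdefault(v.key, set()).add(p)
        assert all(len(ps) == 1 for ps in seen.values())

    def test_stop_loss_sits_on_stop_codon(self, cohort):
        ref = cohort.reference
        tx = {t.id: t for t in ref.transcripts}
        for p in cohort.patients:
            for v in cohort.variant_truth.patients[p].variants:
                if v.label != "special:stop_loss":
                    continue
                t = tx[v.transcript_id]
                tpos = t.genomic_to_transcript(v.pos - 1)
                assert t.cds_end - 3 <= tpos < t.cds_end

    def test_splice_events_on_donor_dinucleotide(self, cohort):
        tx = {t.id: t for t in cohort.reference.transcripts}
        for p in cohort.patients:
            for v in cohort.variant_truth.patients[p].variants:
                if v.label == "special:splice_site":
                    assert tx[v.transcript_id].splice_site_intron(v.pos - 1) is not None

    def test_frameshift_length_not_multiple_of_three(self, cohort):
        for p in cohort.patients:
            for v in cohort.variant_truth.patients[p].variants:
                if v.label == "special:frameshift":
                    assert (len(v.ref) - len(v.alt)) % 3 != 0

    def test_population_snps_in_both_layers(self, cohort):
        for p in cohort.patients:
            for v in cohort.variant_truth.patients[p].variants:
                if v.label == "population_snp":
                    assert v.in_dna and v.in_rna

    def test_excess_special_events_error_names_shortfall(self):
        cfg = CohortConfig(seed=1, n_patients=1, n_transcripts=5,
                           special_event_counts={"splice_site": 500})
        ref = generate_reference(cfg)
        with pytest.raises(ValueError, match="splice-site"):
            generate_patient_variants(ref, cfg)

    def test_vcf_round_trip_traceability(self, cohort, tmp_path):
        """Every planted variant is recoverable from the written VCFs."""
        from neoseek.synthetic.variants import write_patient_vcfs
        from neoseek.variants import parse_and_normalize

        write_patient_vcfs(tmp_path, cohort.variant_truth, cohort.reference, cohort.config.seed)
        p = cohort.patients[0]
        rna = parse_and_normalize(tmp_path / f"{p}.rna.vcf", "RNA_only", p)
        planted = {v.key for v in cohort.variant_truth.patients[p].variants if v.in_rna}
        assert {v.key for v in rna} == planted


class TestNormalCohort:
    def test_absent_level_has_zero_hits(self, cohort):
        absents = [v for v, l in cohort.prevalence_levels.items() if l == "absent"]
        t = cohort.normal_table
        for v in absents:
            assert (t.loc[t["variant_id"] == v, "alt_reads"] >= 1).sum() == 0

    def test_high_level_exceeds_five_percent(self, cohort):
        t = cohort.normal_table
        n = t["sample_id"].nunique()
        for v, lvl in cohort.prevalence_levels.items():
            if lvl == "high":
                hits = int((t.loc[t["variant_id"] == v, "alt_reads"] >= 1).sum())
                assert hits > 0.05 * n

    def test_low_coverage_locus_mostly_uncovered(self, cohort):
        t = cohort.normal_table
        for v, lvl in cohort.prevalence_levels.items():
            if lvl == "not_available":
                sub = t[t["variant_id"] == v]
                assert (sub["total_reads"] >= 3).mean() < 0.05

    def test_too_small_cohort_is_error(self):
        cfg = CohortConfig(seed=1, normal_cohort_size=10)
        with pytest.raises(ValueError, match="cohort"):
            generate_normal_cohort(["v1"], cfg)


class TestCohortDeterminism:
    def test_full_cohort_byte_identical(self, tmp_path, small_config):
        cfg = dataclasses.replace(small_config, n_patients=2, n_rna_only=60,
                                  normal_cohort_size=200)
        for d in ("a", "b"):
            generate_cohort(cfg).write(tmp_path / d)
        a_files = sorted(f.relative_to(tmp_path / "a") for f in (tmp_path / "a").rglob("*") if f.is_file())
        for f in a_files:
            assert filecmp.cmp(tmp_path / "a" / f, tmp_path / "b" / f, shallow=False), f

    def test_ground_truth_traceable_identifiers(self, cohort, tmp_path):
        cohort.write(tmp_path / "c")
        gt = json.loads((tmp_path / "c" / "ground_truth.json").read_text())
        for p in cohort.patients:
            keys = {v["key"] for v in gt["patients"][p]["variants"]}
            assert {v.key for v in cohort.variant_truth.patients[p].variants} == keys
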