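"""Mutated-sequence construction, ORF scanning (with a brute-force oracle),
translation, and database emission."""

import itertools

import numpy as np
import pytest

from neoseek.genome import STOP_CODONS, TranscriptModel
from neoseek.neodb import (
    MutatedSequence,
    apply_variant,
    build_database,
    entries_for_variant,
    project_variant,
    read_provenance,
    scan_orfs,
)
from neoseek.variants import Variant


def _tx(genome_seq, exons, cds=None, strand="+", tid="tx"):
    t = TranscriptModel(id=tid, gene="g", contig="chr1", strand=strand,
                        biotype="protein_coding" if cds else "lncRNA",
                        exons=exons,
                        cds_start=cds[0] if cds else None,
                        cds_end=cds[1] if cds else None)
    return t, {"chr1": genome_seq}


# ---------------------------------------------------------------------------
# projection and application
# ---------------------------------------------------------------------------

class TestProjection:
    def test_plus_strand_exonic_offset(self):
        t, g = _tx("AAACCCGGGTTT", [(0, 6), (9, 12)], cds=(0, 9))
        p = project_variant(Variant("chr1", 11, "T", "C"), t)
        assert p.kind == "exonic" and p.tpos == 7  # 6 exon1 bases + offset 1

    def test_minus_strand_snv_complemented(self):
        t, g = _tx("AAACCCGGGTTT", [(0, 12)], cds=(0, 12), strand="-")
        p = project_variant(Variant("chr1", 5, "T", "C"), t)  # genomic T>C
        assert (p.ref, p.alt) == ("A", "G")

    def test_donor_site_flagged(self):
        t, g = _tx("ATGAAAGTTTAGGGCTAA", [(0, 6), (12, 18)], cds=(0, 12))
        p = project_variant(Variant("chr1", 7, "G", "A"), t)
        assert p.kind == "splice_site" and p.intron_index == 0

    def test_outside_span_is_error(self):
        t, g = _tx("ATGAAATAA", [(0, 9)], cds=(0, 9))
        with pytest.raises(ValueError):
            project_variant(Variant("chr1", 100, "A", "G"), t)


class TestApplyVariant:
    def test_substitution(self):
        t, g = _tx("ATGGCCTAA", [(0, 9)], cds=(0, 9))
        m = apply_variant(t, Variant("chr1", 5, "C", "T"), g)
        assert m.seq == "ATGGTCTAA"

    def test_intron_retention(self):
        t, g = _tx("ATGAAAGTTTAGGGCTAA", [(0, 6), (12, 18)], cds=(0, 12))
        m = apply_variant(t, Variant("chr1", 7, "G", "A"), g)
        assert m.seq == "ATGAAAGTTTAGGGCTAA"
        assert m.retained_intron == (6, 12)

    def test_deletion(self):
        t, g = _tx("ATGAAACCCGGGTAA", [(0, 15)], cds=(0, 15))
        m = apply_variant(t, Variant("chr1", 6, "AC", "A"), g)  # drop base 7
        assert m.seq == "ATGAAACCGGGTAA"

    def test_ref_mismatch_is_error(self):
        t, g = _tx("ATGGCCTAA", [(0, 9)], cds=(0, 9))
        with pytest.raises(ValueError, match="ref mismatch"):
            apply_variant(t, Variant("chr1", 5, "G", "T"), g)

    def test_length_invariant(self):
        t, g = _tx("ATGAAACCCGGGTAA", [(0, 15)], cds=(0, 15))
        wt_len = 15
        m = apply_variant(t, Variant("chr1", 6, "A", "AGG"), g)
        assert len(m.seq) == wt_len + 2


# ---------------------------------------------------------------------------
# ORF scanning vs brute-force oracle
# ---------------------------------------------------------------------------

def enumerate_enclosing_orfs(seq, a0, a1):
    """Independent oracle: all (start, end) ATG..stop pairs, in frame, with no
    internal stop, enclosing [a0, a1); minimal (closest start) per frame."""
    best = {}
    for s in range(len(seq) - 2):
        if seq[s:s + 3] != "ATG" or s > a0:
            continue
        for e in range(s + 3, len(seq) + 1, 3):
            codon = seq[e - 3:e]
            if codon in STOP_CODONS:
                if e >= a1:
                    f = s % 3
                    if f not in best or s > best[f][0]:
                        best[f] = (s, e)
                break
    return {f: se for f, se in best.items()}


def _mut(seq, a0, a1):
    return MutatedSequence(transcript_id="t", seq=seq, anchor_start=a0, anchor_end=a1,
                           variant_key="chr1:1:A:G", kind="exonic")


class TestScanOrfs:
    def test_single_enclosing_orf(self):
        seq = "GGATGCATTAACC"
        orfs = scan_orfs(_mut(seq, 5, 8), "scan")
        assert len(orfs) == 1
        o = orfs[0]
        assert seq[o.start:o.end] == "ATGCATTAA"

    def test_no_upstream_atg(self):
        orfs = scan_orfs(_mut("CCCCATTAACC", 4, 7), "scan")
        assert orfs == []

    def test_overlapping_orfs_two_frames(self):
        # frame 0: ATG at 3 .. stop at 39; frame 2: ATG at 14 .. stop at 29
        seq = "TCGATGCACGAAAAATGCCCTGTTCTTAAGCCACCATGAT"
        orfs = scan_orfs(_mut(seq, 20, 22), "scan")
        assert len(orfs) == 2
        oracle = enumerate_enclosing_orfs(seq, 20, 22)
        assert {(o.start, o.end) for o in orfs} == set(oracle.values())

    def test_oracle_equivalence_random(self):
        rng = np.random.default_rng(42)
        bases = np.array(list("ACGT"))
        for _ in range(1000):
            n = int(rng.integers(30, 121))
            seq = "".join(bases[rng.integers(0, 4, n)])
            a0 = int(rng.integers(0, n - 3))
            a1 = a0 + int(rng.integers(1, 4))
            got = {(o.start, o.end) for o in scan_orfs(_mut(seq, a0, a1), "scan")}
            want = set(enumerate_enclosing_orfs(seq, a0, a1).values())
            assert got == want, (seq, a0, a1)

    def test_at_most_three(self):
        rng = np.random.default_rng(7)
        bases = np.array(list("ACGT"))
        for _ in range(200):
            seq = "".join(bases[rng.integers(0, 4, 90)])
            orfs = scan_orfs(_mut(seq, 40, 41), "scan")
            assert len(orfs) <= 3


# ---------------------------------------------------------------------------
# worked end-to-end translations
# ---------------------------------------------------------------------------

class TestWorkedExamples:
    def test_stop_loss_extends_into_utr(self):
        # CDS ATGGCCTAA + 3'UTR CAAGCCTGA; TAA -> TAC destroys the stop
        t, g = _tx("ATGGCCTAACAAGCCTGA", [(0, 18)], cds=(0, 9))
        entries = entries_for_variant(Variant("chr1", 9, "A", "C"), t, g)
        assert [e.protein for e in entries] == ["MAYQA"]
        assert entries[0].effect == "stop_loss"

    def test_frameshift_reads_through(self):
        # delete base 7 of ATGAAACCCGGGTAA (+UTR ATAG): M K P G K stop
        t, g = _tx("ATGAAACCCGGGTAAATAG", [(0, 19)], cds=(0, 15))
        entries = entries_for_variant(Variant("chr1", 6, "AC", "A"), t, g)
        assert [e.protein for e in entries] == ["MKPGK"]
        assert entries[0].effect == "frameshift"

    def test_splice_retention_translates_intron(self):
        # donor G>A retains GTTTAG: ATG AAA GTT TAG -> MKV
        t, g = _tx("ATGAAAGTTTAGGGCTAA", [(0, 6), (12, 18)], cds=(0, 12))
        entries = entries_for_variant(Variant("chr1", 7, "G", "A"), t, g)
        assert [e.protein for e in entries] == ["MKV"]
        assert entries[0].effect == "splice_site"

    def test_missense_single_residue(self):
        t, g = _tx("ATGGCCTAA", [(0, 9)], cds=(0, 9))
        entries = entries_for_variant(Variant("chr1", 5, "C", "T"), t, g)
        assert [e.protein for e in entries] == ["MV"]
        assert entries[0].effect == "missense"
        assert (entries[0].mutated_aa_start, entries[0].mutated_aa_end) == (1, 2)

    def test_synonymous_emits_nothing(self):
        # CCC -> CCA, both Pro
        t, g = _tx("ATGCCCTAA", [(0, 9)], cds=(0, 9))
        assert entries_for_variant(Variant("chr1", 6, "C", "A"), t, g) == []

    def test_minus_strand_missense(self):
        # genome is the revcomp of ATGGCCTAA + upstream spacer
        from neoseek.genome import revcomp

        seq = revcomp("ATGGCCTAA")
        t, g = _tx(seq, [(0, 9)], cds=(0, 9), strand="-")
        assert t.cds_seq(g) == "ATGGCCTAA"
        # transcript C at t-pos 4 is genomic G at genomic pos 4 (0-based)
        entries = entries_for_variant(Variant("chr1", 5, "G", "A"), t, g)
        assert [e.protein for e in entries] == ["MV"]


# ---------------------------------------------------------------------------
# database emission
# ---------------------------------------------------------------------------

class TestBuildDatabase:
    def test_dedup_same_variant_two_transcripts(self, tmp_path):
        t1, g = _tx("ATGGCCTAA", [(0, 9)], cds=(0, 9), tid="tx1")
        e1 = entries_for_variant(Variant("chr1", 5, "C", "T"), t1, g)[0]
        e2 = entries_for_variant(Variant("chr1", 5, "C", "T"), t1, g)[0]
        e2.transcript_id = "tx2"
        n = build_database([e1, e2], tmp_path / "db.fa", tmp_path / "db.tsv")
        assert n == 1
        assert sum(1 for line in open(tmp_path / "db.tsv")) == 3  # header + 2 provenance rows

    def test_empty_database(self, tmp_path):
        n = build_database([], tmp_path / "db.fa", tmp_path / "db.tsv")
        assert n == 0
        assert (tmp_path / "db.fa").read_text() == ""

    def test_provenance_round_trip(self, tmp_path):
        t, g = _tx("ATGGCCTAACAAGCCTGA", [(0, 18)], cds=(0, 9))
        entries = entries_for_variant(Variant("chr1", 9, "A", "C"), t, g)
        build_database(entries, tmp_path / "db.fa", tmp_path / "db.tsv")
        back = read_provenance(tmp_path / "db.tsv")
        assert [(e.protein, e.variant_key, e.frame, e.effect) for e in back] == [
            (e.protein, e.variant_key, e.frame, e.effect) for e in entries
        ]


class TestCohortPlantedEvents:
    def test_special_events_reach_database(self, cohort):
        """Every planted frame-altering event yields at least one database
        entry whose novel region could supply a presented peptide."""
        for p in cohort.patients:
            planted = [v for v in cohort.variant_truth.patients[p].variants
                       if v.label.startswith("special:")]
            have = {e.variant_key for e in cohort.neo_entries[p]}
            missing = [v.key for v in planted if v.key not in have]
            assert not missing, missing
            assert len(cohort.neo_entries[p]) > 0

    def test_at_most_three_per_variant_transcript(self, cohort):
        from collections import Counter

        for p in cohort.patients:
            counts = Counter((e.variant_key, e.transcript_id) for e in cohort.neo_entries[p])
            assert max(counts.values()) <= 3
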