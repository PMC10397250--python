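"""ELISpot immunogenicity calls, binder annotation, validation grouping,
and cohort-level reporting.

A candidate elicits a T-cell response when the mean spot-forming units of
the mutated-peptide wells exceed the control wells by a ratio above 2 AND a
difference above 50 SFU; a single positive measurement in any culture
setting (autologous PBMC, expanded TIL, allogenic-matched PBMC) makes the
candidate immunogenic.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

ELISPOT_RATIO_MIN = 2.0
ELISPOT_DIFF_MIN = 50.0

BINDER_RANK_MAX = 2.0        # percentile rank < 2%
BINDER_AFFINITY_MAX = 500.0  # predicted affinity < 500 nM

CULTURE_TYPES = ("autologous_pbmc", "til", "allogenic_pbmc")
VALIDATION_GROUPS = ("promising", "potentially_promising", "non_validated")


@dataclass
class ElispotMeasurement:
    candidate_id: str
    culture: str
    test_sfu: list[float]
    control_sfu: list[float]
    aliquot: str = "a1"

    def __post_init__(self) -> None:
        if not self.test_sfu or not self.control_sfu:
            raise ValueError("both conditions need at least one replicate")
        if any(x < 0 for x in self.test_sfu + self.control_sfu):
            raise ValueError("spot counts must be >= 0")


@dataclass
class ImmunogenicityCall:
    candidate_id: str
    culture: str
    ratio: float
    difference: float
    positive: bool
    display_difference: float
    zero_control: bool = False
    aliquot: str = "a1"


def elispot_call(m: ElispotMeasurement) -> ImmunogenicityCall:
    """Dual-threshold reactivity call on one measurement (strict inequalities).

    A zero control mean with a positive test mean is treated as infinite
    ratio (positive iff the difference criterion holds) and flagged.
    """
    t = float(np.mean(m.test_sfu))
    c = float(np.mean(m.control_sfu))
    diff = t - c
    zero_control = c == 0.0
    ratio = math.inf if zero_control and t > 0 else (t / c if c > 0 else 0.0)
    positive = ratio > ELISPOT_RATIO_MIN and diff > ELISPOT_DIFF_MIN
    return ImmunogenicityCall(
        candidate_id=m.candidate_id,
        culture=m.culture,
        ratio=ratio,
        difference=diff,
        positive=positive,
        display_difference=max(diff, 0.0),
        zero_control=zero_control,
        aliquot=m.aliquot,
    )


@dataclass
class CandidateImmunogenicity:
    candidate_id: str
    immunogenic: bool
    supporting_cultures: list[str]
    discordant: bool = False


def aggregate_immunogenicity(calls: Sequence[ImmunogenicityCall]) -> CandidateImmunogenicity:
    """Candidate-level call: immunogenic iff any measurement is positive."""
    if not calls:
        raise ValueError("need at least one measurement")
    cid = calls[0].candidate_id
    pos = sorted({c.culture for c in calls if c.positive})
    any_pos = bool(pos)
    discordant = any_pos and any(not c.positive for c in calls)
    return CandidateImmunogenicity(
        candidate_id=cid, immunogenic=any_pos, supporting_cultures=pos, discordant=discordant
    )


# ---------------------------------------------------------------------------
# binder annotation
# ---------------------------------------------------------------------------

@dataclass
class BinderAnnotation:
    candidate_id: str
    best_rank: float | None
    best_affinity: float | None
    binder: bool | None


def annotate_binders(candidate_id: str, peptide: str, prediction_table: pd.DataFrame) -> BinderAnnotation:
    """Best rank/affinity over alleles and algorithms; binder iff percentile
    rank < 2% or predicted affinity < 500 nM; undefined if unpredicted."""
    rows = prediction_table[prediction_table["peptide"] == peptide]
    if rows.empty:
        return BinderAnnotation(candidate_id, None, None, None)
    best_rank = float(rows["rank"].min()) if "rank" in rows else None
    best_aff = float(rows["affinity"].min()) if "affinity" in rows else None
    binder = (best_rank is not None and best_rank < BINDER_RANK_MAX) or (
        best_aff is not None and best_aff < BINDER_AFFINITY_MAX
    )
    return BinderAnnotation(candidate_id, best_rank, best_aff, binder)


# ---------------------------------------------------------------------------
# validation grouping
# ---------------------------------------------------------------------------

@dataclass
class ValidationRules:
    """Configurable rule table for the validation matrix.

    Defaults: a candidate is non-validated if its spectrum could not be
    verified (SA mismatch) or its variant is highly prevalent in normal
    tissue; promising if the spectrum is verified and the variant is absent
    or nearly absent in normal tissue; everything else is potentially
    promising.  RT never excludes on its own but is carried along.
    """

    promising_sa: frozenset = frozenset({"match"})
    promising_prevalence: frozenset = frozenset({"absent", "very_low"})
    exclude_sa: frozenset = frozenset({"mismatch"})
    exclude_prevalence: frozenset = frozenset({"high"})


@dataclass
class ValidationGroup:
    candidate_id: str
    sa_group: str
    rt_group: str
    prevalence: str
    group: str


def assign_validation_group(
    candidate_id: str,
    sa_group: str,
    rt_group: str,
    prevalence: str,
    rules: ValidationRules | None = None,
) -> ValidationGroup:
    rules = rules or ValidationRules()
    if sa_group in rules.exclude_sa or prevalence in rules.exclude_prevalence:
        group = "non_validated"
    elif sa_group in rules.promising_sa and prevalence in rules.promising_prevalence:
        group = "promising"
    else:
        group = "potentially_promising"
    return ValidationGroup(candidate_id, sa_group, rt_group, prevalence, group)


# ---------------------------------------------------------------------------
# cohort report
# ---------------------------------------------------------------------------

@dataclass
class CohortReport:
    peptide_length_histogram: dict[int, int]
    shared_peptide_histogram: dict[int, int]
    unique_peptide_fraction: float
    gene_list_counts: dict[str, int]
    per_patient_counts: pd.DataFrame
    spearman: pd.DataFrame | None = None
    rank_tests: pd.DataFrame | None = None


def cohort_report(
    peptides_by_patient: Mapping[str, Iterable[str]],
    candidate_table: pd.DataFrame | None = None,
    phenotype_table: pd.DataFrame | None = None,
    gene_lists: Mapping[str, set] | None = None,
    peptide_genes: Mapping[str, str] | None = None,
) -> CohortReport:
    """Cohort-level summaries: peptidome length/sharing structure, gene-list
    annotation, per-patient candidate counts, and phenotype correlations
    (Spearman; Mann-Whitney with Benjamini-Hochberg adjustment).

    ``candidate_table`` needs columns patient/peptide (optionally source,
    effect, biotype, exchange); ``phenotype_table`` is indexed by patient with
    free-form numeric columns, aligned one representative sample per patient.
    """
    carriers: dict[str, set[str]] = {}
    for patient, peps in peptides_by_patient.items():
        for p in peps:
            carriers.setdefault(p, set()).add(patient)
    length_hist = Counter(len(p) for p in carriers)
    share_hist = Counter(len(ps) for ps in carriers.values())
    unique_fraction = share_hist.get(1, 0) / len(carriers) if carriers else 1.0

    gene_counts: dict[str, int] = {}
    if gene_lists and peptide_genes:
        for name, genes in gene_lists.items():
            gene_counts[name] = sum(1 for p in carriers if peptide_genes.get(p) in genes)

    if candidate_table is not None and len(candidate_table):
        group_cols = [c for c in ("source", "effect", "biotype", "exchange") if c in candidate_table]
        per_patient = (
            candidate_table.groupby(["patient"] + group_cols, dropna=False)
            .size()
            .rename("n")
            .reset_index()
        )
    else:
        per_patient = pd.DataFrame(columns=["patient", "n"])

    spearman = rank_tests = None
    if phenotype_table is not None and candidate_table is not None and len(candidate_table):
        counts = candidate_table.groupby("patient").size()
        orphans = sorted(set(counts.index) - set(phenotype_table.index))
        if orphans:
            raise ValueError(f"patients missing from phenotype table: {orphans}")
        counts = counts.reindex(phenotype_table.index, fill_value=0)
        rows = []
        for col in phenotype_table.columns:
            rho, p = stats.spearmanr(counts.values, phenotype_table[col].values)
            rows.append({"feature": col, "spearman_rho": rho, "p_value": p})
        spearman = pd.DataFrame(rows)
        if "immunogenic" in candidate_table:
            imm_patients = set(candidate_table.loc[candidate_table["immunogenic"], "patient"])
            grp = phenotype_table.index.isin(imm_patients)
            if grp.any() and (~grp).any():
                rows = []
                for col in phenotype_table.columns:
                    u, p = stats.mannwhitneyu(
                        phenotype_table.loc[grp, col],
                        phenotype_table.loc[~grp, col],
                        alternative="two-sided",
                    )
                    rows.append({"feature": col, "statistic": u, "p_value": p})
                rank_tests = pd.DataFrame(rows)
                rank_tests["p_adj_bh"] = multipletests(rank_tests["p_value"], method="fdr_bh")[1]

    return CohortReport(
        peptide_length_histogram=dict(sorted(length_hist.items())),
        shared_peptide_histogram=dict(sorted(share_hist.items())),
        unique_peptide_fraction=unique_fraction,
        gene_list_counts=gene_counts,
        per_patient_counts=per_patient,
        spearman=spearman,
        rank_tests=rank_tests,
    )
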