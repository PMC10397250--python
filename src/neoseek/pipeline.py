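"""End-to-end pipeline over a (synthetic or file-based) cohort.

Chains the stages: PSM post-processing cascade -> spectral/RT verification
-> normal-tissue prevalence -> ELISpot immunogenicity -> validation
grouping, and computes planted-truth recovery metrics when ground truth is
available.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .candidates import CandidateRecord, CascadeResult, run_cascade
from .immuno import (
    aggregate_immunogenicity,
    assign_validation_group,
    elispot_call,
)
from .prevalence import prevalence_table
from .spectra import best_sa_verdict, classify_rt, fit_rt_alignment
from .synthetic import SyntheticCohort
from .variants import classify_exchange, filter_population_snps, merge_sources


@dataclass
class PipelineResult:
    candidates: list[CandidateRecord]
    cascade: CascadeResult
    table: pd.DataFrame                      # per-candidate verdict matrix
    prevalence: pd.DataFrame
    recovery: dict[str, float] = field(default_factory=dict)


def run_pipeline(cohort: SyntheticCohort, fdr: float = 0.05) -> PipelineResult:
    """Run the candidate identification + validation pipeline on a cohort."""
    proteome = cohort.reference.proteome
    all_candidates: list[CandidateRecord] = []
    cascade_all = CascadeResult(survivors=[])
    rows = []

    for patient in cohort.patients:
        msd = cohort.ms[patient]
        entries = {e.header: e for e in cohort.neo_entries.get(patient, [])}
        cands, cascade = run_cascade(
            msd.psms_primary, msd.psms_rescored, entries, proteome, fdr=fdr
        )
        cascade_all.survivors.extend(cascade.survivors)
        cascade_all.trace.extend(cascade.trace)
        for k, v in cascade.removed.items():
            cascade_all.removed.setdefault(k, []).extend(v)
        all_candidates.extend(cands)

        # per-run RT alignment on the canonical calibration peptides
        rt_model = fit_rt_alignment(msd.calibration_irt, msd.calibration_rt)
        for c in cands:
            pep = c.peptide
            sa = best_sa_verdict(
                msd.endogenous[pep],
                synthetic=msd.synthetic.get(pep),
                predicted=msd.predicted.get(pep),
            ) if pep in msd.endogenous else None
            rt_err = rt_group = None
            if pep in msd.observed_rt and pep in msd.irt:
                pred_rt = float(rt_model.predict(msd.irt[pep]))
                verdict = classify_rt(msd.observed_rt[pep] - pred_rt, msd.observed_rt[pep])
                rt_err, rt_group = verdict.rt_error, verdict.group
            rows.append(
                {
                    "candidate_id": f"{patient}:{pep}",
                    "patient": patient,
                    "peptide": pep,
                    "variant": c.variant_key,
                    "effect": c.entry.effect if c.entry else "",
                    "sa_best": sa.best_sa if sa else np.nan,
                    "sa_group": sa.group if sa else "mismatch",
                    "rt_error": rt_err,
                    "rt_group": rt_group or "mismatch",
                }
            )

    table = pd.DataFrame(rows)

    # prevalence of candidate variants in the normal cohort
    variant_ids = sorted(set(table["variant"])) if len(table) else []
    prev = prevalence_table(variant_ids, cohort.normal_table)
    prev_by_variant = dict(zip(prev["variant_id"], prev["category"])) if len(prev) else {}
    if len(table):
        table["prevalence"] = [prev_by_variant.get(v, "not_available") for v in table["variant"]]

    # ELISpot immunogenicity
    imm_by_candidate: dict[str, bool] = {}
    if cohort.elispot:
        calls: dict[str, list] = {}
        for m in cohort.elispot.measurements:
            calls.setdefault(m.candidate_id, []).append(elispot_call(m))
        for cid, cs in calls.items():
            imm_by_candidate[cid] = aggregate_immunogenicity(cs).immunogenic
    if len(table):
        table["immunogenic"] = [imm_by_candidate.get(cid, False) for cid in table["candidate_id"]]
        table["validation_group"] = [
            assign_validation_group(r.candidate_id, r.sa_group, r.rt_group, r.prevalence).group
            for r in table.itertuples()
        ]

    recovery = _recovery_metrics(cohort, table)
    return PipelineResult(
        candidates=all_candidates,
        cascade=cascade_all,
        table=table,
        prevalence=prev,
        recovery=recovery,
    )


def _recovery_metrics(cohort: SyntheticCohort, table: pd.DataFrame) -> dict[str, float]:
    out: dict[str, float] = {}
    planted = {(p, pep) for p, peps in cohort.planted_presented().items() for pep in peps}
    found = set(zip(table["patient"], table["peptide"])) if len(table) else set()
    tp = len(planted & found)
    out["peptide_precision"] = tp / len(found) if found else 1.0
    out["peptide_recall"] = tp / len(planted) if planted else 1.0

    # prevalence category recovery over planted levels
    if len(table):
        lv = cohort.prevalence_levels
        prev = table.drop_duplicates("variant")
        hits = total = 0
        for r in prev.itertuples():
            if r.variant in lv:
                total += 1
                hits += int(r.prevalence == lv[r.variant])
        out["prevalence_accuracy"] = hits / total if total else 1.0

    # immunogenicity recovery
    if cohort.elispot and len(table):
        planted_pos = cohort.elispot.planted_positive
        called_pos = set(table.loc[table["immunogenic"], "candidate_id"])
        tested = set(table["candidate_id"])
        out["immunogenic_exact"] = float((planted_pos & tested) == called_pos)

    # editing-fraction recovery: A>G share among RNA-only variants
    agree = n_rna_only = n_ag = 0
    for patient, pv in cohort.variant_truth.patients.items():
        dna = [v for v in pv.variants if v.in_dna]
        rna = [v for v in pv.variants if v.in_rna]
        merged = merge_sources(
            [_as_variant(v, patient) for v in dna],
            [_as_variant(v, patient) for v in rna],
        )
        for v in merged:
            if v.source != "RNA_only":
                continue
            if v.vclass != "SNV":
                continue
            n_rna_only += 1
            cls = classify_exchange(v, cohort.reference.transcripts)
            n_ag += int(cls == "A>G")
    out["editing_fraction_observed"] = n_ag / n_rna_only if n_rna_only else 0.0
    out["n_rna_only_snvs"] = float(n_rna_only)
    return out


def _as_variant(v, patient):
    from .variants import Variant

    return Variant(contig=v.contig, pos=v.pos, ref=v.ref, alt=v.alt, patient=patient,
                   af_gnomad=v.af_gnomad, af_dbsnp=v.af_dbsnp, tumor_vaf=v.vaf)
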