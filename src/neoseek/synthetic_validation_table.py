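"""SYNTHETIC stand-in for a per-candidate validation annotation table.

This module fabricates a deterministic, cohort-scale table of per-candidate
raw measurements (best spectral angle, RT error and observed RT, normal-
cohort prevalence and coverage fractions, ELISpot means, variant source)
together with the classification labels those measurements imply.  It is
synthetic data: the values are generated, not measured, and they exist so
the classification rules (SA >= 0.7 verification, the ±8.56 min RT window
with its 9-17 min deviation zone, the prevalence bands with the N/A
coverage rule, and the ELISpot dual threshold) can be exercised end to end
on a table shaped like a study's per-candidate supplementary annotation.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .prevalence import (
    COVERAGE_MIN_FRACTION,
    INTERMEDIATE_MAX,
    LOW_MAX,
    VERY_LOW_MAX,
)
from .spectra import RT_DEVIATION_ZONE, RT_WINDOW_MIN, SA_MATCH_MIN, SA_POTENTIAL_MIN

# cohort-scale marginal structure of the synthetic table
N_CANDIDATES = 90
SA_GROUPS = ["match"] * 41 + ["potential"] * 19 + ["mismatch"] * 30
RT_GROUPS = ["match"] * 45 + ["deviation"] * 17 + ["mismatch"] * 28
PREVALENCE = (
    ["absent"] * 38 + ["very_low"] * 7 + ["low"] * 12
    + ["intermediate"] * 6 + ["high"] * 16 + ["not_available"] * 11
)
SOURCES = ["RNA"] * 79 + ["DNA"] * 3 + ["both"] * 8
N_TESTED_ELISPOT = 78
N_IMMUNOGENIC = 21
N_NORMAL_SAMPLES = 10_269


def _sa_value(rng: np.random.Generator, group: str) -> float:
    if group == "match":
        return float(rng.uniform(SA_MATCH_MIN, 0.99))
    if group == "potential":
        return float(rng.uniform(SA_POTENTIAL_MIN, SA_MATCH_MIN - 1e-6))
    return float(rng.uniform(0.05, SA_POTENTIAL_MIN - 1e-6))


def _rt_values(rng: np.random.Generator, group: str) -> tuple[float, float]:
    """(rt_error, observed_rt) consistent with the group label."""
    if group == "match":
        return float(rng.uniform(-RT_WINDOW_MIN, RT_WINDOW_MIN)), float(rng.uniform(5, 90))
    lo, hi = RT_DEVIATION_ZONE
    err = float(rng.uniform(RT_WINDOW_MIN + 0.5, 25.0)) * (1 if rng.random() < 0.5 else -1)
    if group == "deviation":
        return err, float(rng.uniform(lo, hi))
    return err, float(rng.uniform(hi + 1.0, 90.0))


def _prevalence_values(rng: np.random.Generator, category: str) -> tuple[int, float]:
    """(n_samples_hit, coverage_fraction) consistent with the category."""
    n = N_NORMAL_SAMPLES
    cov = float(rng.uniform(0.2, 0.95))
    if category == "not_available":
        return int(rng.integers(0, 3)), float(rng.uniform(0.0, COVERAGE_MIN_FRACTION - 0.005))
    if category == "absent":
        return 0, cov
    if category == "very_low":
        return int(rng.integers(1, int(n * VERY_LOW_MAX))), cov
    if category == "low":
        return int(rng.integers(int(np.ceil(n * VERY_LOW_MAX)), int(n * LOW_MAX))), cov
    if category == "intermediate":
        return int(rng.integers(int(np.ceil(n * LOW_MAX)), int(n * INTERMEDIATE_MAX) + 1)), cov
    return int(rng.integers(int(n * INTERMEDIATE_MAX) + 1, int(n * 0.4))), cov


def synthetic_candidate_annotations(seed: int = 0) -> pd.DataFrame:
    """Build the synthetic per-candidate annotation table (90 rows).

    Columns hold both the raw measurements and the labels they imply
    (``*_label``); tests and the acceptance recount re-derive the labels
    from the raw values with the package's classification functions.
    """
    rng = np.random.default_rng(seed)
    sa = list(SA_GROUPS)
    rt = list(RT_GROUPS)
    prev = list(PREVALENCE)
    src = list(SOURCES)
    for lst in (sa, rt, prev, src):
        rng.shuffle(lst)

    tested = np.zeros(N_CANDIDATES, dtype=bool)
    tested[rng.choice(N_CANDIDATES, size=N_TESTED_ELISPOT, replace=False)] = True
    imm_idx = rng.choice(np.flatnonzero(tested), size=N_IMMUNOGENIC, replace=False)
    immunogenic = np.zeros(N_CANDIDATES, dtype=bool)
    immunogenic[imm_idx] = True

    rows = []
    for i in range(N_CANDIDATES):
        sa_val = _sa_value(rng, sa[i])
        rt_err, rt_obs = _rt_values(rng, rt[i])
        hits, cov = _prevalence_values(rng, prev[i])
        if tested[i]:
            control = float(rng.uniform(5, 40))
            if immunogenic[i]:
                test = control * float(rng.uniform(2.5, 4.0)) + float(rng.uniform(60, 120))
            else:
                test = (control * float(rng.uniform(0.5, 1.8))
                        if rng.random() < 0.5 else control + float(rng.uniform(0, 45)))
        else:
            control = test = np.nan
        rows.append(
            {
                "candidate_id": f"C{i + 1:03d}",
                "source": src[i],
                "sa_best": sa_val,
                "sa_label": sa[i],
                "rt_error": rt_err,
                "observed_rt": rt_obs,
                "rt_label": rt[i],
                "n_samples_hit": hits,
                "n_samples_total": N_NORMAL_SAMPLES,
                "coverage_fraction": cov,
                "prevalence_label": prev[i],
                "elispot_tested": bool(tested[i]),
                "elispot_test_mean": test,
                "elispot_control_mean": control,
                "immunogenic_label": bool(immunogenic[i]),
            }
        )
    return pd.DataFrame(rows)


def recount(table: pd.DataFrame) -> dict[str, int]:
    """Apply the classification rules to the raw columns and count groups.

    This is the recount a per-candidate supplementary table supports: every
    label is re-derived from raw values through the package's rule
    implementations, never read from the ``*_label`` columns.
    """
    from .immuno import ElispotMeasurement, elispot_call
    from .prevalence import PrevalenceRecord, classify_prevalence
    from .spectra import classify_rt

    sa_groups, rt_groups, prev_cats, imm_calls, groups = [], [], [], [], []
    from .immuno import assign_validation_group

    for r in table.itertuples():
        sa_g = ("match" if r.sa_best >= SA_MATCH_MIN
                else "potential" if r.sa_best >= SA_POTENTIAL_MIN else "mismatch")
        sa_groups.append(sa_g)
        rt_groups.append(classify_rt(r.rt_error, r.observed_rt).group)
        rec = PrevalenceRecord(
            variant_id=r.candidate_id,
            n_samples_hit=int(r.n_samples_hit),
            n_samples_total=int(r.n_samples_total),
            prevalence=r.n_samples_hit / r.n_samples_total,
            coverage_fraction=r.coverage_fraction,
        )
        prev_cats.append(classify_prevalence(rec))
        if r.elispot_tested:
            call = elispot_call(
                ElispotMeasurement(r.candidate_id, "autologous_pbmc",
                                   [r.elispot_test_mean], [r.elispot_control_mean])
            )
            imm_calls.append(call.positive)
        else:
            imm_calls.append(False)
        groups.append(
            assign_validation_group(r.candidate_id, sa_g, rt_groups[-1], prev_cats[-1]).group
        )

    out = {
        "n_candidates": len(table),
        "n_sa_verified": sum(g == "match" for g in sa_groups),
        "n_sa_potential": sum(g == "potential" for g in sa_groups),
        "n_sa_mismatch": sum(g == "mismatch" for g in sa_groups),
        "n_rt_match": sum(g == "match" for g in rt_groups),
        "n_rt_deviation": sum(g == "deviation" for g in rt_groups),
        "n_prev_absent": sum(c == "absent" for c in prev_cats),
        "n_prev_high": sum(c == "high" for c in prev_cats),
        "n_prev_na": sum(c == "not_available" for c in prev_cats),
        "n_rna_only": int((table["source"] == "RNA").sum()),
        "n_elispot_tested": int(table["elispot_tested"].sum()),
        "n_immunogenic": sum(imm_calls),
        "n_validated": sum(g in ("promising", "potentially_promising") for g in groups),
        "n_promising": sum(g == "promising" for g in groups),
        "n_immunogenic_validated": sum(
            i and g in ("promising", "potentially_promising") for i, g in zip(imm_calls, groups)
        ),
    }
    return out
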