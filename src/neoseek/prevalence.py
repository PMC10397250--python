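"""Prevalence of candidate variants in a normal-tissue RNA cohort.

The normal cohort is consumed as a long table (sample_id, tissue,
variant_id, alt_reads, total_reads); a sample "hits" a variant if it shows
at least one alternate read.  Loci whose coverage cannot be assessed (fewer
than 5% of coverage-assessed samples with >= 3 reads) are uninformative and
classified not_available regardless of hits.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

PREVALENCE_CATEGORIES = ("absent", "very_low", "low", "intermediate", "high", "not_available")

VERY_LOW_MAX = 0.001     # < 0.1% of samples
LOW_MAX = 0.01           # < 1%
INTERMEDIATE_MAX = 0.05  # <= 5%; above is high
COVERAGE_MIN_READS = 3
COVERAGE_MIN_FRACTION = 0.05
SAMPLES_PER_TISSUE_CAP = 100  # coverage assessed on up to 100 samples per tissue


@dataclass
class PrevalenceRecord:
    variant_id: str
    n_samples_hit: int
    n_samples_total: int
    prevalence: float
    coverage_fraction: float | None
    category: str = ""


def compute_prevalence(
    variant_id: str,
    normal_table: pd.DataFrame,
    n_samples_total: int | None = None,
    denominator: str = "all",
) -> PrevalenceRecord:
    """Hit counts and coverage fraction for one variant.

    ``denominator='all'`` uses every sample in the cohort (default);
    ``'assessed'`` restricts to samples with a row for this variant.
    Coverage is assessed per tissue on up to the first 100 samples
    (lexicographic sample order).
    """
    rows = normal_table[normal_table["variant_id"] == variant_id]
    if n_samples_total is None:
        n_samples_total = normal_table["sample_id"].nunique()
    if denominator == "assessed":
        n_total = rows["sample_id"].nunique()
    else:
        n_total = n_samples_total
    n_hit = int((rows["alt_reads"] >= 1).sum())
    coverage_fraction = None
    if not rows.empty and "total_reads" in rows:
        capped = (
            rows.sort_values("sample_id")
            .groupby("tissue", sort=True)
            .head(SAMPLES_PER_TISSUE_CAP)
        )
        if len(capped):
            coverage_fraction = float((capped["total_reads"] >= COVERAGE_MIN_READS).mean())
    prevalence = n_hit / n_total if n_total else 0.0
    return PrevalenceRecord(
        variant_id=variant_id,
        n_samples_hit=n_hit,
        n_samples_total=n_total,
        prevalence=prevalence,
        coverage_fraction=coverage_fraction,
    )


def classify_prevalence(record: PrevalenceRecord) -> str:
    """Assign the prevalence category; the N/A rule precedes all others."""
    if record.coverage_fraction is None or record.coverage_fraction < COVERAGE_MIN_FRACTION:
        cat = "not_available"
    elif record.prevalence == 0.0:
        cat = "absent"
    elif record.prevalence < VERY_LOW_MAX:
        cat = "very_low"
    elif record.prevalence < LOW_MAX:
        cat = "low"
    elif record.prevalence <= INTERMEDIATE_MAX:
        cat = "intermediate"
    else:
        cat = "high"
    record.category = cat
    return cat


def prevalence_table(
    variant_ids: list[str],
    normal_table: pd.DataFrame,
    denominator: str = "all",
) -> pd.DataFrame:
    n_total = normal_table["sample_id"].nunique()
    recs = []
    for vid in variant_ids:
        rec = compute_prevalence(vid, normal_table, n_samples_total=n_total, denominator=denominator)
        classify_prevalence(rec)
        recs.append(rec)
    return pd.DataFrame(
        {
            "variant_id": [r.variant_id for r in recs],
            "n_samples_hit": [r.n_samples_hit for r in recs],
            "n_samples_total": [r.n_samples_total for r in recs],
            "prevalence": [r.prevalence for r in recs],
            "coverage_fraction": [r.coverage_fraction for r in recs],
            "category": [r.category for r in recs],
        }
    )


# ---------------------------------------------------------------------------
# tumor-associated over-editing
# ---------------------------------------------------------------------------

MIN_COVERED_FOR_OVEREDITING = 10


@dataclass
class OvereditingRecord:
    variant_id: str
    tumor_vaf: float
    n_covered: int
    normal_vaf_mean: float | None
    normal_vaf_p95: float | None
    flag: bool | None


def overediting_compare(
    variant_id: str,
    tumor_vaf: float,
    normal_table: pd.DataFrame,
    pct: float = 95.0,
) -> OvereditingRecord:
    """Flag a candidate whose tumor VAF exceeds the ``pct`` percentile of the
    normal-sample VAF distribution (covered samples only); undefined with
    fewer than 10 covered samples."""
    rows = normal_table[
        (normal_table["variant_id"] == variant_id)
        & (normal_table["total_reads"] >= COVERAGE_MIN_READS)
    ]
    n = len(rows)
    if n < MIN_COVERED_FOR_OVEREDITING:
        return OvereditingRecord(variant_id, tumor_vaf, n, None, None, None)
    vafs = (rows["alt_reads"] / rows["total_reads"]).to_numpy(dtype=float)
    p95 = float(np.percentile(vafs, pct))
    return OvereditingRecord(
        variant_id=variant_id,
        tumor_vaf=tumor_vaf,
        n_covered=n,
        normal_vaf_mean=float(vafs.mean()),
        normal_vaf_p95=p95,
        flag=bool(tumor_vaf > p95),
    )
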