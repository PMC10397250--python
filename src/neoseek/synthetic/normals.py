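"""Synthetic normal-tissue cohort with planted per-variant prevalence levels.

Each variant is assigned a level (absent / very_low / low / intermediate /
high / not_available); sample hit counts are chosen to land inside the
corresponding prevalence band, and not_available loci are made low-coverage
in more than 95% of samples so the coverage rule fires.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ..config import CohortConfig

PREVALENCE_LEVELS = ("absent", "very_low", "low", "intermediate", "high")

MIN_COHORT = 20


def plant_levels(variant_ids: list[str], config: CohortConfig, rng: np.random.Generator) -> dict[str, str]:
    """Cycle the five prevalence levels over the variants, then convert a
    ``low_coverage_fraction`` tail to not_available loci."""
    levels = {vid: PREVALENCE_LEVELS[i % len(PREVALENCE_LEVELS)] for i, vid in enumerate(sorted(variant_ids))}
    n_na = int(round(config.low_coverage_fraction * len(variant_ids)))
    for vid in sorted(variant_ids)[-n_na:] if n_na else []:
        levels[vid] = "not_available"
    return levels


def _target_hits(level: str, n_samples: int, rng: np.random.Generator) -> int:
    if level in ("absent", "not_available"):
        return 0
    if level == "very_low":      # (0, 0.1%) of samples
        hi = max(1, int(np.ceil(n_samples * 0.001)) - 1)
        return int(rng.integers(1, hi + 1))
    if level == "low":           # [0.1%, 1%)
        lo = max(1, int(np.ceil(n_samples * 0.001)))
        hi = max(lo, int(np.ceil(n_samples * 0.01)) - 1)
        return int(rng.integers(lo, hi + 1))
    if level == "intermediate":  # [1%, 5%]
        lo = int(np.ceil(n_samples * 0.01))
        hi = int(np.floor(n_samples * 0.05))
        return int(rng.integers(lo, hi + 1))
    # high: > 5%
    lo = int(np.floor(n_samples * 0.05)) + 1
    hi = max(lo, int(np.floor(n_samples * 0.15)))
    return int(rng.integers(lo, hi + 1))


def generate_normal_cohort(
    variant_ids: list[str],
    config: CohortConfig,
    levels: dict[str, str] | None = None,
) -> tuple[pd.DataFrame, dict[str, str]]:
    """Long table (sample_id, tissue, variant_id, alt_reads, total_reads)
    plus the planted level per variant."""
    n = config.normal_cohort_size
    if n < MIN_COHORT:
        raise ValueError(f"normal cohort of {n} cannot resolve sub-0.1% prevalence bands (need >= {MIN_COHORT})")
    rng = np.random.default_rng(config.seed + 9000)
    if levels is None:
        levels = plant_levels(variant_ids, config, rng)

    samples = [f"S{i:05d}" for i in range(n)]
    tissues = [f"tissue_{i % config.n_tissues:02d}" for i in range(n)]
    frames = []
    for vid in sorted(variant_ids):
        level = levels[vid]
        hits = _target_hits(level, n, rng)
        hit_idx = set(map(int, rng.choice(n, size=hits, replace=False))) if hits else set()
        if level == "not_available":
            # low coverage in ~98% of samples
            covered = rng.random(n) < 0.02
            total = np.where(covered, rng.poisson(20, n) + 3, rng.integers(0, 3, n))
            alt = np.zeros(n, dtype=int)
        else:
            total = rng.poisson(25, n) + 3
            alt = np.zeros(n, dtype=int)
            for i in hit_idx:
                alt[i] = 1 + rng.poisson(3)
                total[i] = max(total[i], alt[i] + 3)
        frames.append(
            pd.DataFrame(
                {
                    "sample_id": samples,
                    "tissue": tissues,
                    "variant_id": vid,
                    "alt_reads": alt,
                    "total_reads": total,
                }
            )
        )
    table = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
        columns=["sample_id", "tissue", "variant_id", "alt_reads", "total_reads"]
    )
    return table, levels
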