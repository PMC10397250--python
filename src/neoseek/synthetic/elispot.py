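"""Synthetic ELISpot tables with a planted immunogenic candidate subset.

Planted-positive candidates receive test-well means that satisfy both the
ratio (>2) and difference (>50 SFU) criteria against control wells; planted
negatives violate at least one criterion.  Replicates are drawn around the
means with multiplicative dispersion ``elispot_noise`` (at 0 the planted and
called sets coincide exactly).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ..config import CohortConfig
from ..immuno import ElispotMeasurement

CULTURES = ("autologous_pbmc", "til", "allogenic_pbmc")


@dataclass
class ElispotData:
    measurements: list[ElispotMeasurement]
    planted_positive: set[str]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for m in self.measurements:
            rows.append(
                {
                    "candidate_id": m.candidate_id,
                    "culture": m.culture,
                    "aliquot": m.aliquot,
                    "test_sfu": ";".join(f"{x:.1f}" for x in m.test_sfu),
                    "control_sfu": ";".join(f"{x:.1f}" for x in m.control_sfu),
                }
            )
        return pd.DataFrame(rows)


def _replicates(rng: np.random.Generator, mean: float, noise: float, n: int = 2) -> list[float]:
    if noise <= 0:
        return [float(mean)] * n
    return [max(0.0, float(mean * (1.0 + noise * rng.normal()))) for _ in range(n)]


def generate_elispot(candidate_ids: list[str], config: CohortConfig) -> ElispotData:
    """ELISpot measurements for each candidate in 1-2 culture settings."""
    if not candidate_ids:
        raise ValueError("candidate list is empty")
    rng = np.random.default_rng(config.seed + 11_000)
    ordered = sorted(candidate_ids)
    n_pos = int(round(config.immunogenic_fraction * len(ordered)))
    planted = set(ordered[i] for i in map(int, rng.choice(len(ordered), size=n_pos, replace=False)))

    measurements: list[ElispotMeasurement] = []
    first_positive_done = False
    for cid in ordered:
        cultures = ["autologous_pbmc"]
        if rng.random() < 0.4:
            cultures.append("til" if rng.random() < 0.5 else "allogenic_pbmc")
        positive_culture = cultures[0]
        for culture in cultures:
            if cid in planted and culture == positive_culture:
                if not first_positive_done:
                    control_mean = 0.0  # exercises the zero-control convention
                    test_mean = float(rng.uniform(80, 150))
                    first_positive_done = True
                else:
                    control_mean = float(rng.uniform(5, 40))
                    test_mean = control_mean * float(rng.uniform(2.5, 4.0)) + float(rng.uniform(60, 120))
            else:
                control_mean = float(rng.uniform(5, 40))
                if rng.random() < 0.5:
                    # ratio failure (difference may or may not pass)
                    test_mean = control_mean * float(rng.uniform(0.5, 1.8))
                else:
                    # difference failure (ratio may pass on a small control)
                    test_mean = control_mean + float(rng.uniform(0, 45))
            measurements.append(
                ElispotMeasurement(
                    candidate_id=cid,
                    culture=culture,
                    test_sfu=_replicates(rng, test_mean, config.elispot_noise),
                    control_sfu=_replicates(rng, control_mean, config.elispot_noise),
                )
            )
    return ElispotData(measurements=measurements, planted_positive=planted)
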