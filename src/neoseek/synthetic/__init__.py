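"""Self-contained toy cohort generator with planted ground truth.

Everything is deterministic in (config, seed): calling any generator twice
with the same configuration yields byte-identical outputs, and every planted
item is traceable through stable identifiers recorded in the ground truth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from ..config import CohortConfig
from ..neodb import MutPeptideEntry, build_database, entries_for_variant
from ..variants import Variant
from .elispot import ElispotData, generate_elispot
from .msdata import PatientMsData, generate_psms_and_spectra, write_ms_layer
from .normals import generate_normal_cohort, plant_levels
from .reference import ReferenceBundle, generate_reference
from .variants import (
    PlantedVariant,
    VariantGroundTruth,
    generate_patient_variants,
    write_patient_vcfs,
)

__all__ = [
    "CohortConfig",
    "ReferenceBundle",
    "SyntheticCohort",
    "generate_reference",
    "generate_patient_variants",
    "generate_psms_and_spectra",
    "generate_normal_cohort",
    "generate_elispot",
    "generate_cohort",
]


@dataclass
class SyntheticCohort:
    """The complete generated cohort with its ground truth."""

    config: CohortConfig
    reference: ReferenceBundle
    variant_truth: VariantGroundTruth
    neo_entries: dict[str, list[MutPeptideEntry]]       # patient -> db entries
    ms: dict[str, PatientMsData]                        # patient -> MS layer
    normal_table: pd.DataFrame
    prevalence_levels: dict[str, str]                   # variant key -> planted level
    elispot: ElispotData | None

    @property
    def patients(self) -> list[str]:
        return sorted(self.variant_truth.patients)

    def planted_presented(self) -> dict[str, set[str]]:
        return {p: set(self.ms[p].presented) for p in self.patients}

    def ground_truth_json(self) -> dict:
        gt = {
            "patients": {},
            "shared_pool": [v.key for v in self.variant_truth.shared_pool],
            "prevalence_levels": self.prevalence_levels,
            "immunogenic": sorted(self.elispot.planted_positive) if self.elispot else [],
        }
        for p, pv in self.variant_truth.patients.items():
            gt["patients"][p] = {
                "variants": [
                    {"key": v.key, "label": v.label, "in_dna": v.in_dna, "in_rna": v.in_rna}
                    for v in pv.variants
                ],
                "presented_peptides": self.ms[p].presented if p in self.ms else [],
            }
        return gt

    def write(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.reference.write(outdir / "reference")
        write_patient_vcfs(outdir / "variants", self.variant_truth, self.reference, self.config.seed)
        for p in self.patients:
            entries = self.neo_entries.get(p, [])
            build_database(entries, outdir / "variants" / f"{p}.neodb.fa",
                           outdir / "variants" / f"{p}.neodb.tsv")
            if p in self.ms:
                write_ms_layer(outdir / "ms", self.ms[p])
        self.normal_table.to_csv(outdir / "normal_cohort.tsv", sep="\t", index=False)
        if self.elispot:
            self.elispot.to_frame().to_csv(outdir / "elispot.tsv", sep="\t", index=False)
        with open(outdir / "ground_truth.json", "w") as fh:
            json.dump(self.ground_truth_json(), fh, indent=1, sort_keys=True)


def _planted_to_variant(v: PlantedVariant, patient: str, source: str) -> Variant:
    return Variant(contig=v.contig, pos=v.pos, ref=v.ref, alt=v.alt,
                   patient=patient, source=source, af_gnomad=v.af_gnomad,
                   af_dbsnp=v.af_dbsnp, tumor_vaf=v.vaf)


def generate_cohort(config: CohortConfig) -> SyntheticCohort:
    """Generate the full cohort: reference, variants, mutated-peptide
    databases, MS layer, normal cohort, and ELISpot tables."""
    ref = generate_reference(config)
    vt = generate_patient_variants(ref, config)
    tx_by_id = {t.id: t for t in ref.transcripts}

    neo_entries: dict[str, list[MutPeptideEntry]] = {}
    ms: dict[str, PatientMsData] = {}
    for pi, (patient, pv) in enumerate(sorted(vt.patients.items())):
        entries: list[MutPeptideEntry] = []
        for v in pv.variants:
            if not v.in_rna or v.label == "population_snp":
                continue
            t = tx_by_id.get(v.transcript_id) if v.transcript_id else None
            if t is None:
                continue
            var = _planted_to_variant(v, patient, "RNA_only" if not v.in_dna else "both")
            try:
                entries.extend(entries_for_variant(var, t, ref.genome))
            except ValueError:
                continue  # e.g. variant projected outside span after trimming
        neo_entries[patient] = entries
        ms[patient] = generate_psms_and_spectra(ref, patient, entries, config, patient_index=pi)

    # prevalence: every presented-candidate variant plus the shared pool
    candidate_variants = sorted(
        {vk for d in ms.values() for vk in d.presented_variants.values()}
        | {v.key for v in vt.shared_pool}
    )
    import numpy as np

    levels = plant_levels(candidate_variants, config, np.random.default_rng(config.seed + 8000))
    normal_table, levels = generate_normal_cohort(candidate_variants, config, levels=levels)

    all_candidates = sorted({f"{p}:{pep}" for p, d in ms.items() for pep in d.presented})
    elispot = generate_elispot(all_candidates, config) if all_candidates else None

    return SyntheticCohort(
        config=config,
        reference=ref,
        variant_truth=vt,
        neo_entries=neo_entries,
        ms=ms,
        normal_table=normal_table,
        prevalence_levels=levels,
        elispot=elispot,
    )
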