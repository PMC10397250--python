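"""Cohort simulation configuration."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import yaml


@dataclass
class CohortConfig:
    """Parameters of the synthetic cohort generator.

    The defaults describe a desk-scale cohort with the statistical structure
    the analysis assumes: a single ~100 kb contig carrying a few dozen
    transcripts, patients with hundreds of RNA-level variants dominated by
    A>G exchanges on the transcribed strand, a cohort-shared RNA-variant
    pool, and a normal cohort large enough to resolve sub-percent prevalence
    bands.
    """

    n_patients: int = 5
    n_transcripts: int = 30
    coding_fraction: float = 0.8
    genome_size: int = 100_000

    # variant structure (per patient, negative-binomial means)
    n_somatic_dna: int = 30
    n_rna_only: int = 300
    nb_dispersion: float = 5.0          # NB size parameter; larger = tighter
    editing_fraction: float = 0.55      # A>G share of RNA-only variants
    shared_fraction: float = 0.2        # RNA-only variants drawn from shared pool
    shared_pool_size: int = 40
    population_snp_rate: float = 5e-4   # planted SNPs per bp of genome
    rna_detection_prob: float = 0.9     # chance a somatic DNA variant is also RNA-called
    special_event_counts: dict[str, int] = field(
        default_factory=lambda: {"splice_site": 2, "frameshift": 2, "stop_loss": 2}
    )

    # MS layer
    presented_per_patient: int = 6      # planted presented mutant peptides
    corrupt_fraction: float = 0.0       # fraction of endogenous spectra corrupted
    n_calibration_peptides: int = 60    # canonical peptides anchoring RT alignment
    rt_noise_min: float = 0.0           # per-spectrum RT jitter (minutes, s.d.)

    # normal cohort
    normal_cohort_size: int = 2000
    n_tissues: int = 10
    low_coverage_fraction: float = 0.15  # loci made low-coverage to trigger N/A

    # ELISpot
    elispot_noise: float = 0.0          # multiplicative dispersion of spot counts
    immunogenic_fraction: float = 0.3

    seed: int = 0

    def __post_init__(self) -> None:
        fracs = {
            "coding_fraction": self.coding_fraction,
            "editing_fraction": self.editing_fraction,
            "shared_fraction": self.shared_fraction,
            "rna_detection_prob": self.rna_detection_prob,
            "corrupt_fraction": self.corrupt_fraction,
            "low_coverage_fraction": self.low_coverage_fraction,
            "immunogenic_fraction": self.immunogenic_fraction,
        }
        for name, v in fracs.items():
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        counts = {
            "n_patients": self.n_patients,
            "n_transcripts": self.n_transcripts,
            "n_somatic_dna": self.n_somatic_dna,
            "n_rna_only": self.n_rna_only,
            "normal_cohort_size": self.normal_cohort_size,
            "n_tissues": self.n_tissues,
            "genome_size": self.genome_size,
        }
        for name, v in counts.items():
            if v < 0:
                raise ValueError(f"{name} must be >= 0, got {v}")
        if any(v < 0 for v in self.special_event_counts.values()):
            raise ValueError("special_event_counts must be >= 0")

    @classmethod
    def from_yaml(cls, path) -> "CohortConfig":
        with open(path) as fh:
            return cls(**(yaml.safe_load(fh) or {}))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)
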