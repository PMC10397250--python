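"""Generate the synthetic study cohort and summarize what was planted.

Writes the full cohort bundle (reference FASTA/GTF, per-patient VCFs,
mutated-peptide databases, MGF spectra, PSM/normal/ELISpot tables) under
scratch/cohort/ and a per-patient planting summary under results/.
"""

from collections import Counter
from pathlib import Path

import pandas as pd

from neoseek.config import CohortConfig
from neoseek.synthetic import generate_cohort

ROOT = Path(__file__).resolve().parents[1]
SEED = 1


def main() -> None:
    config = CohortConfig(seed=SEED)
    cohort = generate_cohort(config)
    cohort.write(ROOT / "scratch" / "cohort")

    rows = []
    for p in cohort.patients:
        labels = Counter(v.label for v in cohort.variant_truth.patients[p].variants)
        rows.append(
            {
                "patient": p,
                "n_variants": sum(labels.values()),
                **{f"n_{k.replace(':', '_')}": v for k, v in sorted(labels.items())},
                "n_db_entries": len(cohort.neo_entries[p]),
                "n_presented_peptides": len(cohort.ms[p].presented),
            }
        )
    summary = pd.DataFrame(rows).fillna(0)
    out = ROOT / "results"
    out.mkdir(exist_ok=True)
    summary.to_csv(out / "01_cohort_summary.tsv", sep="\t", index=False)

    print(f"cohort of {len(cohort.patients)} patients on a "
          f"{len(cohort.reference.genome['chr1']):,} bp toy contig "
          f"({len(cohort.reference.transcripts)} transcripts)")
    print(summary.to_string(index=False))
    print(f"\nfull bundle -> scratch/cohort/ ; summary -> results/01_cohort_summary.tsv")


if __name__ == "__main__":
    main()
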