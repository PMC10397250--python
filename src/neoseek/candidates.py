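"""PSM post-processing: from two engines' scored peptide-spectrum matches to
a filtered neoantigen candidate list.

The cascade: per-engine 5% FDR with decoy/contaminant removal and union over
engines; peptide property constraints (8-15mers, <= 1500 Da monoisotopic);
mutated-database exclusivity; mutation containment within the peptide span;
canonical near-match and known-peptide exclusion.  Every PSM ends up either
a survivor or attributed to exactly one removing filter (filter_trace).
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd
from pyteomics import mass as _mass

from .neodb import FRAME_ALTERING, MutPeptideEntry

FDR_DEFAULT = 0.05
PEPTIDE_LEN_MIN = 8
PEPTIDE_LEN_MAX = 15
PEPTIDE_MASS_MAX = 1500.0  # Da, monoisotopic

_MOD_RE = re.compile(r"[^A-Z]")  # strips lowercase/bracketed modification syntax


def strip_modifications(peptide: str) -> str:
    """Bare upper-case sequence: variable-modification annotations removed."""
    return _MOD_RE.sub("", peptide.upper().replace("(", "").replace(")", ""))


def peptide_mass(peptide: str) -> float:
    return _mass.fast_mass(peptide)


@dataclass
class PsmRecord:
    peptide: str
    q_value: float
    engine: str                      # primary_search | rescored
    db_hits: frozenset[str]
    spectrum_id: str = ""
    precursor_mass: float | None = None
    patient: str = ""

    def __post_init__(self) -> None:
        self.peptide = strip_modifications(self.peptide)
        if not 0.0 <= self.q_value <= 1.0:
            raise ValueError(f"q_value outside [0,1]: {self.q_value}")

    def hit_kinds(self) -> set[str]:
        kinds = set()
        for h in self.db_hits:
            if h.startswith("NEO|"):
                kinds.add("mutated")
            elif h.startswith("DECOY"):
                kinds.add("decoy")
            elif h.startswith("CONT"):
                kinds.add("contaminant")
            else:
                kinds.add("canonical")
        return kinds


@dataclass
class CandidateRecord:
    peptide: str
    patient: str
    variant_key: str
    entry: MutPeptideEntry | None
    engines_supporting: set[str]
    best_q_value: float
    contains_mutation: str = ""      # direct | noncanonical_frame
    filter_trace: list[tuple[str, str]] = field(default_factory=list)
    flagged: bool = False


@dataclass
class CascadeResult:
    """Survivors plus a complete per-PSM trace of the filter cascade."""

    survivors: list[PsmRecord]
    removed: dict[str, list[PsmRecord]] = field(default_factory=dict)
    trace: list[tuple[PsmRecord, str]] = field(default_factory=list)

    def drop(self, psm: PsmRecord, filt: str) -> None:
        self.removed.setdefault(filt, []).append(psm)
        self.trace.append((psm, filt))

    def keep(self, psm: PsmRecord, filt: str) -> None:
        self.trace.append((psm, f"pass:{filt}"))


# ---------------------------------------------------------------------------
# cascade stages
# ---------------------------------------------------------------------------

def ingest_and_union(
    psms_primary: Sequence[PsmRecord],
    psms_rescored: Sequence[PsmRecord],
    fdr: float = FDR_DEFAULT,
    result: CascadeResult | None = None,
) -> list[PsmRecord]:
    """Per-engine FDR filter, decoy/contaminant removal, union over engines."""
    result = result if result is not None else CascadeResult(survivors=[])
    surviving: list[PsmRecord] = []
    for psm in list(psms_primary) + list(psms_rescored):
        kinds = psm.hit_kinds()
        if "decoy" in kinds and kinds == {"decoy"}:
            result.drop(psm, "decoy")
            continue
        if "contaminant" in kinds:
            result.drop(psm, "contaminant")
            continue
        if psm.q_value > fdr:
            result.drop(psm, "fdr")
            continue
        result.keep(psm, "fdr")
        surviving.append(psm)
    return surviving


def peptide_property_filter(
    psms: Sequence[PsmRecord],
    result: CascadeResult | None = None,
) -> list[PsmRecord]:
    """8-15mers with monoisotopic mass <= 1500 Da."""
    result = result if result is not None else CascadeResult(survivors=[])
    out = []
    for psm in psms:
        n = len(psm.peptide)
        if not PEPTIDE_LEN_MIN <= n <= PEPTIDE_LEN_MAX:
            result.drop(psm, "length")
            continue
        if peptide_mass(psm.peptide) > PEPTIDE_MASS_MAX:
            result.drop(psm, "mass")
            continue
        result.keep(psm, "property")
        out.append(psm)
    return out


def mutated_exclusive_filter(
    psms: Sequence[PsmRecord],
    canonical_proteome: Mapping[str, str] | None = None,
    equate_il: bool = False,
    result: CascadeResult | None = None,
) -> list[PsmRecord]:
    """Keep PSMs hitting the mutated database and nothing canonical; also
    reject peptides occurring verbatim inside any canonical protein."""
    result = result if result is not None else CascadeResult(survivors=[])
    proteome_seqs = list(canonical_proteome.values()) if canonical_proteome else []
    if equate_il:
        proteome_seqs = [s.replace("I", "L") for s in proteome_seqs]
    out = []
    for psm in psms:
        kinds = psm.hit_kinds()
        if "mutated" not in kinds:
            result.drop(psm, "no_mutated_hit")
            continue
        if "canonical" in kinds:
            result.drop(psm, "canonical_hit")
            continue
        pep = psm.peptide.replace("I", "L") if equate_il else psm.peptide
        if any(pep in s for s in proteome_seqs):
            result.drop(psm, "canonical_substring")
            continue
        result.keep(psm, "mutated_exclusive")
        out.append(psm)
    return out


def mutation_containment_check(
    psm: PsmRecord,
    entry: MutPeptideEntry,
) -> str:
    """direct / noncanonical_frame / rejected for one candidate peptide.

    A peptide covering the altered residue(s) is direct evidence; for
    frame-altering events (frameshift, splice retention, stop/start loss) a
    peptide anywhere within the novel downstream region is non-canonical
    evidence; an SNV-derived peptide not covering the altered residue is
    rejected.
    """
    pep = psm.peptide
    start = entry.protein.find(pep)
    if start < 0:
        raise ValueError(f"peptide {pep} not found in linked entry {entry.header}")
    best = "rejected"
    while start >= 0:
        end = start + len(pep)
        overlaps = start < entry.mutated_aa_end and entry.mutated_aa_start < end
        if overlaps:
            verdict = "noncanonical_frame" if entry.effect in FRAME_ALTERING else "direct"
            return verdict
        start = entry.protein.find(pep, start + 1)
    return best


def count_near_matches(
    peptide: str,
    proteome: Mapping[str, str],
    max_substitutions: int = 1,
    equate_il: bool = False,
) -> int:
    """Number of distinct canonical proteins matching the peptide exactly or
    within ``max_substitutions`` substitutions."""
    if equate_il:
        peptide = peptide.replace("I", "L")
    n = 0
    L = len(peptide)
    for name, seq in proteome.items():
        if equate_il:
            seq = seq.replace("I", "L")
        hit = peptide in seq
        if not hit and max_substitutions > 0:
            for i in range(len(seq) - L + 1):
                mism = 0
                for a, b in zip(peptide, seq[i : i + L]):
                    if a != b:
                        mism += 1
                        if mism > max_substitutions:
                            break
                else:
                    hit = True
                    break
        if hit:
            n += 1
    return n


def canonical_and_known_filters(
    psms: Sequence[PsmRecord],
    proteome: Mapping[str, str],
    known_peptides: Iterable[str] = (),
    max_hits_excluded: int = 2,
    near_match_substitutions: int = 1,
    one_two_hit_policy: str = "flag",
    equate_il: bool = False,
    result: CascadeResult | None = None,
) -> tuple[list[PsmRecord], list[PsmRecord]]:
    """Near-match exclusion (> 2 canonical hits removed, 1-2 flagged or
    excluded per policy) and known-peptide list removal.

    Returns (survivors, flagged-for-review).
    """
    result = result if result is not None else CascadeResult(survivors=[])
    known = {strip_modifications(p) for p in known_peptides}
    out, flagged = [], []
    for psm in psms:
        if psm.peptide in known:
            result.drop(psm, "known_peptide")
            continue
        hits = count_near_matches(psm.peptide, proteome, near_match_substitutions, equate_il)
        if hits > max_hits_excluded:
            result.drop(psm, "near_match")
            continue
        if hits >= 1:
            if one_two_hit_policy == "exclude":
                result.drop(psm, "near_match_review")
                continue
            flagged.append(psm)
        result.keep(psm, "canonical_known")
        out.append(psm)
    return out, flagged


# ---------------------------------------------------------------------------
# assembly
# ---------------------------------------------------------------------------

def assemble_candidates(
    psms: Sequence[PsmRecord],
    entries_by_header: Mapping[str, MutPeptideEntry],
    result: CascadeResult | None = None,
) -> list[CandidateRecord]:
    """One CandidateRecord per unique (patient, peptide, variant), with
    engine support, best q-value, and the containment verdict."""
    result = result if result is not None else CascadeResult(survivors=[])
    grouped: dict[tuple[str, str, str], CandidateRecord] = {}
    for psm in psms:
        neo_headers = [h for h in psm.db_hits if h.startswith("NEO|")]
        for header in sorted(neo_headers):
            entry = entries_by_header.get(header)
            if entry is None:
                raise ValueError(f"broken provenance link: {header}")
            verdict = mutation_containment_check(psm, entry)
            if verdict == "rejected":
                result.drop(psm, "mutation_outside_peptide")
                continue
            key = (psm.patient, psm.peptide, entry.variant_key)
            rec = grouped.get(key)
            if rec is None:
                grouped[key] = rec = CandidateRecord(
                    peptide=psm.peptide,
                    patient=psm.patient,
                    variant_key=entry.variant_key,
                    entry=entry,
                    engines_supporting=set(),
                    best_q_value=psm.q_value,
                    contains_mutation=verdict,
                )
            rec.engines_supporting.add(psm.engine)
            rec.best_q_value = min(rec.best_q_value, psm.q_value)
    return sorted(grouped.values(), key=lambda r: (r.patient, r.peptide, r.variant_key))


def engine_partition(candidates: Sequence[CandidateRecord]) -> dict[str, int]:
    """Counts of candidates by supporting engine (primary-only / rescored-only / both)."""
    out = {"primary_only": 0, "rescored_only": 0, "both": 0}
    for c in candidates:
        if c.engines_supporting == {"primary_search"}:
            out["primary_only"] += 1
        elif c.engines_supporting == {"rescored"}:
            out["rescored_only"] += 1
        else:
            out["both"] += 1
    return out


def run_cascade(
    psms_primary: Sequence[PsmRecord],
    psms_rescored: Sequence[PsmRecord],
    entries_by_header: Mapping[str, MutPeptideEntry],
    proteome: Mapping[str, str],
    known_peptides: Iterable[str] = (),
    fdr: float = FDR_DEFAULT,
    equate_il: bool = False,
) -> tuple[list[CandidateRecord], CascadeResult]:
    """The full post-processing cascade over both engines' PSM tables."""
    result = CascadeResult(survivors=[])
    s = ingest_and_union(psms_primary, psms_rescored, fdr=fdr, result=result)
    s = peptide_property_filter(s, result=result)
    s = mutated_exclusive_filter(s, canonical_proteome=proteome, equate_il=equate_il, result=result)
    s, flagged = canonical_and_known_filters(
        s, proteome, known_peptides, equate_il=equate_il, result=result
    )
    flagged_set = {id(p) for p in flagged}
    candidates = assemble_candidates(s, entries_by_header, result=result)
    for c in candidates:
        c.flagged = any(
            id(p) in flagged_set for p in s if p.peptide == c.peptide and p.patient == c.patient
        )
    result.survivors = s
    return candidates, result


# ---------------------------------------------------------------------------
# io
# ---------------------------------------------------------------------------

PSM_COLUMNS = ["peptide", "q_value", "engine", "db_hits", "spectrum_id", "precursor_mass", "patient"]


def read_psm_table(path) -> list[PsmRecord]:
    out = []
    with open(path) as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            out.append(
                PsmRecord(
                    peptide=row["peptide"],
                    q_value=float(row["q_value"]),
                    engine=row["engine"],
                    db_hits=frozenset(row["db_hits"].split(";")) if row["db_hits"] else frozenset(),
                    spectrum_id=row.get("spectrum_id", ""),
                    precursor_mass=float(row["precursor_mass"]) if row.get("precursor_mass") else None,
                    patient=row.get("patient", ""),
                )
            )
    return out


def write_psm_table(path, psms: Sequence[PsmRecord]) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(PSM_COLUMNS) + "\n")
        for p in psms:
            fh.write(
                "\t".join(
                    [
                        p.peptide,
                        f"{p.q_value:.6g}",
                        p.engine,
                        ";".join(sorted(p.db_hits)),
                        p.spectrum_id,
                        "" if p.precursor_mass is None else f"{p.precursor_mass:.4f}",
                        p.patient,
                    ]
                )
                + "\n"
            )


def candidates_to_frame(candidates: Sequence[CandidateRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "patient": [c.patient for c in candidates],
            "peptide": [c.peptide for c in candidates],
            "variant": [c.variant_key for c in candidates],
            "effect": [c.entry.effect if c.entry else "" for c in candidates],
            "engines": ["+".join(sorted(c.engines_supporting)) for c in candidates],
            "best_q": [c.best_q_value for c in candidates],
            "containment": [c.contains_mutation for c in candidates],
            "flagged": [c.flagged for c in candidates],
        }
    )
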