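"""Synthetic immunopeptidomics layer: PSM tables from two search workflows,
endogenous/synthetic/predicted fragment spectra, and retention times.

Fragment spectra carry singly-charged b/y ions computed from monoisotopic
residue masses, lognormal intensities, and optional corruption (peaks moved
to non-matching m/z) to exercise spectral-angle mismatches.  Predicted iRT
maps to simulated observed RT through a known monotone curve.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from pyteomics import mass as _mass

from ..candidates import (
    PEPTIDE_LEN_MAX,
    PEPTIDE_LEN_MIN,
    PEPTIDE_MASS_MAX,
    PsmRecord,
    peptide_mass,
)
from ..config import CohortConfig
from ..neodb import MutPeptideEntry
from ..spectra import Spectrum
from .reference import ReferenceBundle


def fragment_ions(peptide: str) -> tuple[np.ndarray, list[str]]:
    """Singly-charged b/y fragment m/z values (monoisotopic), sorted."""
    mzs, labels = [], []
    for i in range(1, len(peptide)):
        mzs.append(_mass.fast_mass(peptide[:i], ion_type="b", charge=1))
        labels.append(f"b{i}")
        mzs.append(_mass.fast_mass(peptide[i:], ion_type="y", charge=1))
        labels.append(f"y{len(peptide) - i}")
    order = np.argsort(mzs)
    return np.asarray(mzs)[order], [labels[i] for i in order]


def rt_from_irt(irt: np.ndarray | float) -> np.ndarray | float:
    """The run's true (monotone, mildly nonlinear) iRT -> RT map, minutes."""
    irt = np.asarray(irt, dtype=float)
    return 8.0 + 0.85 * irt + 2.0 * np.sin(irt / 25.0)


@dataclass
class PatientMsData:
    patient: str
    psms_primary: list[PsmRecord]
    psms_rescored: list[PsmRecord]
    endogenous: dict[str, Spectrum]       # peptide -> spectrum
    synthetic: dict[str, Spectrum]
    predicted: dict[str, Spectrum]
    irt: dict[str, float]                 # peptide -> predicted iRT
    observed_rt: dict[str, float]         # peptide -> experimental RT (minutes)
    calibration_irt: np.ndarray = field(default_factory=lambda: np.empty(0))
    calibration_rt: np.ndarray = field(default_factory=lambda: np.empty(0))
    presented: list[str] = field(default_factory=list)    # planted mutant peptides
    corrupted: set[str] = field(default_factory=set)
    presented_variants: dict[str, str] = field(default_factory=dict)  # peptide -> variant key


def choose_presented_peptide(
    entry: MutPeptideEntry,
    proteome: dict[str, str],
) -> str | None:
    """A presentable window from a mutant protein: 8-15mer overlapping the
    mutated span, mass <= 1500 Da, absent from the canonical proteome."""
    prot = entry.protein
    # nonamers dominate HLA-I ligands; rotate the preference deterministically
    # so 8-11mers all occur across a cohort
    prefs = [(9, 8, 10, 11), (9, 10, 8, 11), (10, 9, 11, 8), (8, 9, 10, 11)]
    for length in prefs[len(prot) % 4]:
        lo = max(0, entry.mutated_aa_start - length + 1)
        hi = min(len(prot) - length, entry.mutated_aa_end - 1)
        for s in range(lo, hi + 1):
            pep = prot[s : s + length]
            if len(pep) != length:
                continue
            if not (s < entry.mutated_aa_end and entry.mutated_aa_start < s + length):
                continue
            if peptide_mass(pep) > PEPTIDE_MASS_MAX:
                continue
            if any(pep in p for p in proteome.values()):
                continue
            return pep
    return None


def _base_intensities(peptide: str, n: int) -> np.ndarray:
    """Fragmentation pattern as a stable property of the peptide (not the
    acquisition): drawn from a generator seeded by the sequence itself."""
    import zlib

    prng = np.random.default_rng(zlib.crc32(peptide.encode()) & 0x7FFFFFFF)
    return prng.lognormal(mean=10.0, sigma=0.8, size=n)


def _spectrum_for(
    rng: np.random.Generator,
    peptide: str,
    rt_minutes: float,
    source: str,
    corrupt: bool = False,
) -> Spectrum:
    mzs, _ = fragment_ions(peptide)
    inten = _base_intensities(peptide, mzs.size)
    if corrupt:
        # move every peak to a non-matching m/z: SA against the true ions collapses
        mzs = np.sort(rng.uniform(200.0, 1400.0, size=mzs.size))
    jitter = rng.uniform(0.92, 1.08, size=mzs.size)
    prec = peptide_mass(peptide) + 1.00727646688  # singly protonated
    return Spectrum(
        mz=mzs,
        intensity=inten * jitter,
        precursor_mz=prec,
        charge=1,
        rt_minutes=rt_minutes,
        source=source,
        title=f"{source}:{peptide}",
    )


def _canonical_windows(
    rng: np.random.Generator, proteome: dict[str, str], n: int
) -> list[tuple[str, str]]:
    names = sorted(proteome)
    out = []
    for _ in range(n * 3):
        if len(out) >= n:
            break
        name = names[int(rng.integers(0, len(names)))]
        seq = proteome[name]
        L = int(rng.integers(PEPTIDE_LEN_MIN, 12))
        if len(seq) <= L:
            continue
        s = int(rng.integers(0, len(seq) - L))
        pep = seq[s : s + L]
        if peptide_mass(pep) <= PEPTIDE_MASS_MAX:
            out.append((pep, name))
    return out[:n]


def generate_psms_and_spectra(
    ref: ReferenceBundle,
    patient: str,
    entries: list[MutPeptideEntry],
    config: CohortConfig,
    patient_index: int = 0,
) -> PatientMsData:
    """PSM tables for both engines plus endogenous/synthetic/predicted spectra.

    With an empty mutated-peptide database the tables contain canonical rows
    only (a warning-level situation, not an error).
    """
    rng = np.random.default_rng(config.seed + 5000 + patient_index)
    data = PatientMsData(
        patient=patient, psms_primary=[], psms_rescored=[],
        endogenous={}, synthetic={}, predicted={}, irt={}, observed_rt={},
    )

    # presented mutant peptides: one window per distinct variant
    seen_variants: set[str] = set()
    presented: list[tuple[str, MutPeptideEntry]] = []
    for entry in entries:
        if len(presented) >= config.presented_per_patient:
            break
        if entry.variant_key in seen_variants:
            continue
        pep = choose_presented_peptide(entry, ref.proteome)
        if pep is None:
            continue
        seen_variants.add(entry.variant_key)
        presented.append((pep, entry))
    data.presented = [p for p, _ in presented]
    data.presented_variants = {p: e.variant_key for p, e in presented}

    # calibration (canonical) peptides anchor the per-run RT alignment
    calib = _canonical_windows(rng, ref.proteome, config.n_calibration_peptides)
    irts = rng.uniform(0.0, 100.0, size=len(calib))
    rts = rt_from_irt(irts) + rng.normal(0.0, config.rt_noise_min, size=len(calib))
    data.calibration_irt = irts
    data.calibration_rt = np.asarray(rts, dtype=float)

    for (pep, prot_name), irt, rt in zip(calib, irts, rts):
        q = float(rng.uniform(0.0001, 0.02))
        for engine, bucket in (("primary_search", data.psms_primary), ("rescored", data.psms_rescored)):
            bucket.append(
                PsmRecord(peptide=pep, q_value=q, engine=engine,
                          db_hits=frozenset({prot_name}),
                          spectrum_id=f"{patient}:{pep}", patient=patient)
            )
        data.irt[pep] = float(irt)
        data.observed_rt[pep] = float(rt)

    # mutant PSMs: mostly supported by both engines; a few by only one
    for k, (pep, entry) in enumerate(presented):
        q1 = float(rng.uniform(0.001, 0.04))
        q2 = float(rng.uniform(0.001, 0.04))
        hits = frozenset({entry.header})
        rec1 = PsmRecord(peptide=pep, q_value=q1, engine="primary_search", db_hits=hits,
                         spectrum_id=f"{patient}:{pep}", patient=patient)
        rec2 = PsmRecord(peptide=pep, q_value=q2, engine="rescored", db_hits=hits,
                         spectrum_id=f"{patient}:{pep}", patient=patient)
        if k % 5 == 3:
            data.psms_primary.append(rec1)     # primary-only support
        elif k % 5 == 4:
            data.psms_rescored.append(rec2)    # rescored-only support
        else:
            data.psms_primary.append(rec1)
            data.psms_rescored.append(rec2)

        irt = float(rng.uniform(5.0, 95.0))
        rt = float(rt_from_irt(irt) + rng.normal(0.0, config.rt_noise_min))
        data.irt[pep] = irt
        data.observed_rt[pep] = rt
        corrupt = rng.random() < config.corrupt_fraction
        if corrupt:
            data.corrupted.add(pep)
        data.endogenous[pep] = _spectrum_for(rng, pep, rt, "endogenous", corrupt=corrupt)
        data.synthetic[pep] = _spectrum_for(rng, pep, rt + float(rng.normal(0, 0.2)), "synthetic")
        data.predicted[pep] = _spectrum_for(rng, pep, rt_from_irt(irt), "predicted")

    # decoys and contaminants exercise the audit filters
    for i in range(5):
        data.psms_primary.append(
            PsmRecord(peptide="".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=9)),
                      q_value=float(rng.uniform(0.2, 0.9)), engine="primary_search",
                      db_hits=frozenset({f"DECOY_{i}"}), spectrum_id=f"{patient}:decoy{i}",
                      patient=patient)
        )
    data.psms_primary.append(
        PsmRecord(peptide="KAVDAGLKK", q_value=0.002, engine="primary_search",
                  db_hits=frozenset({"CONT_KRT1"}), spectrum_id=f"{patient}:cont0", patient=patient)
    )
    return data


def write_ms_layer(outdir, data: PatientMsData) -> None:
    """Write PSM TSVs, MGFs, and the predicted-spectrum/iRT table."""
    from pathlib import Path

    from ..candidates import write_psm_table
    from ..spectra import write_mgf

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    p = data.patient
    write_psm_table(outdir / f"{p}.psms_primary.tsv", data.psms_primary)
    write_psm_table(outdir / f"{p}.psms_rescored.tsv", data.psms_rescored)
    write_mgf(outdir / f"{p}.endogenous.mgf", list(data.endogenous.values()))
    write_mgf(outdir / f"{p}.synthetic.mgf", list(data.synthetic.values()))
    with open(outdir / f"{p}.predicted.tsv", "w") as fh:
        fh.write("peptide\tirt\tmz\tintensity\n")
        for pep, spec in sorted(data.predicted.items()):
            for mz, inten in zip(spec.mz, spec.intensity):
                fh.write(f"{pep}\t{data.irt[pep]:.4f}\t{mz:.5f}\t{inten:.2f}\n")
    with open(outdir / f"{p}.calibration.tsv", "w") as fh:
        fh.write("irt\trt\n")
        for irt, rt in zip(data.calibration_irt, data.calibration_rt):
            fh.write(f"{irt:.4f}\t{rt:.4f}\n")
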