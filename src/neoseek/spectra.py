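"""Spectrum-level verification of candidate peptides.

Endogenous fragment spectra are compared against synthetic-peptide and
predicted spectra by merging peak lists at 20 ppm and computing the
normalized spectral contrast angle SA = 1 - 2*arccos(<a, b>)/pi on the
L2-normalized paired intensity vectors.  Retention-time concordance is
scored against a per-run LOESS alignment of predicted iRT to observed RT.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from pyteomics import mgf as _mgf
from statsmodels.nonparametric.smoothers_lowess import lowess

SA_MATCH_MIN = 0.7          # verified peptide-spectrum agreement
SA_POTENTIAL_MIN = 0.55     # lower edge of the "potential match" band
RT_WINDOW_MIN = 8.56        # |RT error| window (minutes)
RT_DEVIATION_ZONE = (9.0, 17.0)  # observed-RT range with unreliable predictions


@dataclass
class Spectrum:
    """Centroided peak list with precursor information."""

    mz: np.ndarray
    intensity: np.ndarray
    precursor_mz: float = 0.0
    charge: int = 1
    rt_minutes: float = 0.0
    source: str = "endogenous"   # endogenous | synthetic | predicted
    title: str = ""

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.size == 0:
            raise ValueError("spectrum must have at least one peak")
        if np.any(np.diff(self.mz) <= 0):
            order = np.argsort(self.mz)
            self.mz, self.intensity = self.mz[order], self.intensity[order]
        if np.any(self.intensity < 0):
            raise ValueError("negative intensities")


def read_mgf(path) -> dict[str, Spectrum]:
    """Read an MGF file into spectra keyed by TITLE."""
    out: dict[str, Spectrum] = {}
    with _mgf.MGF(str(path)) as reader:
        for entry in reader:
            params = entry["params"]
            title = params.get("title", "")
            pep = params.get("pepmass", (0.0,))
            charge = params.get("charge", [1])
            out[title] = Spectrum(
                mz=entry["m/z array"],
                intensity=entry["intensity array"],
                precursor_mz=float(pep[0] if isinstance(pep, (tuple, list)) else pep),
                charge=int(charge[0]) if charge else 1,
                rt_minutes=float(params.get("rtinseconds", 0.0)) / 60.0,
                title=title,
            )
    return out


def write_mgf(path, spectra: list[Spectrum]) -> None:
    entries = [
        {
            "m/z array": s.mz,
            "intensity array": s.intensity,
            "params": {
                "title": s.title,
                "pepmass": s.precursor_mz,
                "rtinseconds": s.rt_minutes * 60.0,
                "charge": s.charge,
            },
        }
        for s in spectra
    ]
    _mgf.write(entries, str(path), file_mode="w")


# ---------------------------------------------------------------------------
# peak merging and spectral contrast angle
# ---------------------------------------------------------------------------

def merge_spectra(
    a: Spectrum,
    b: Spectrum,
    tol_ppm: float = 20.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Pair the peaks of two spectra into equal-length intensity vectors.

    Peaks are matched greedily by closest m/z within ``tol_ppm`` (relative to
    the mean of the two m/z values); each peak is used at most once.  Peaks
    left unmatched in either spectrum contribute a row with intensity 0 on
    the other side.
    """
    pairs: list[tuple[float, int, int]] = []
    for i, ma in enumerate(a.mz):
        for j, mb in enumerate(b.mz):
            ppm = abs(ma - mb) / ((ma + mb) / 2.0) * 1e6
            if ppm <= tol_ppm:
                pairs.append((ppm, i, j))
    pairs.sort(key=lambda t: (t[0], t[1], t[2]))
    used_a: set[int] = set()
    used_b: set[int] = set()
    ia, ib = [], []
    for _, i, j in pairs:
        if i in used_a or j in used_b:
            continue
        used_a.add(i)
        used_b.add(j)
        ia.append(a.intensity[i])
        ib.append(b.intensity[j])
    for i in range(len(a.mz)):
        if i not in used_a:
            ia.append(a.intensity[i])
            ib.append(0.0)
    for j in range(len(b.mz)):
        if j not in used_b:
            ia.append(0.0)
            ib.append(b.intensity[j])
    return np.asarray(ia, dtype=float), np.asarray(ib, dtype=float)


def spectral_angle(ia: np.ndarray, ib: np.ndarray) -> float:
    """Normalized spectral contrast angle of two paired intensity vectors."""
    ia = np.asarray(ia, dtype=float)
    ib = np.asarray(ib, dtype=float)
    if ia.shape != ib.shape:
        raise ValueError("paired vectors must have equal length")
    na, nb = np.linalg.norm(ia), np.linalg.norm(ib)
    if na == 0.0 or nb == 0.0:
        raise ValueError("zero intensity vector")
    dot = float(np.clip(np.dot(ia / na, ib / nb), 0.0, 1.0))
    return 1.0 - 2.0 * np.arccos(dot) / np.pi


def compare_spectra(a: Spectrum, b: Spectrum, tol_ppm: float = 20.0) -> float:
    return spectral_angle(*merge_spectra(a, b, tol_ppm=tol_ppm))


@dataclass
class SaVerdict:
    sa_vs_synthetic: float | None
    sa_vs_predicted: float | None
    best_sa: float
    group: str   # match | potential | mismatch


def best_sa_verdict(
    endogenous: Spectrum,
    synthetic: Spectrum | None = None,
    predicted: Spectrum | None = None,
    tol_ppm: float = 20.0,
    match_min: float = SA_MATCH_MIN,
    potential_min: float = SA_POTENTIAL_MIN,
) -> SaVerdict:
    """Best-of-two SA verdict: verified at best SA >= 0.7."""
    if synthetic is None and predicted is None:
        raise ValueError("at least one comparison spectrum is required")
    sa_syn = compare_spectra(endogenous, synthetic, tol_ppm) if synthetic is not None else None
    sa_pred = compare_spectra(endogenous, predicted, tol_ppm) if predicted is not None else None
    best = max(v for v in (sa_syn, sa_pred) if v is not None)
    if best >= match_min:
        group = "match"
    elif best >= potential_min:
        group = "potential"
    else:
        group = "mismatch"
    return SaVerdict(sa_vs_synthetic=sa_syn, sa_vs_predicted=sa_pred, best_sa=best, group=group)


# ---------------------------------------------------------------------------
# retention-time alignment
# ---------------------------------------------------------------------------

MIN_CALIBRATION_PEPTIDES = 20


@dataclass
class RtModel:
    """Per-run monotone-smoothed map from predicted iRT to observed RT."""

    irt_grid: np.ndarray
    rt_fit: np.ndarray
    residual_sd: float = 0.0

    def predict(self, irt) -> np.ndarray:
        irt = np.asarray(irt, dtype=float)
        # interpolation with clamped extrapolation to the calibration range
        return np.interp(irt, self.irt_grid, self.rt_fit)


def fit_rt_alignment(irt, rt, span: float = 0.75) -> RtModel:
    """LOESS fit of observed RT on predicted iRT over a run's identified peptides."""
    irt = np.asarray(irt, dtype=float)
    rt = np.asarray(rt, dtype=float)
    if irt.size < MIN_CALIBRATION_PEPTIDES:
        raise ValueError(
            f"need at least {MIN_CALIBRATION_PEPTIDES} calibration peptides per run "
            f"(got {irt.size}); consider a global linear fallback"
        )
    fitted = lowess(rt, irt, frac=span, it=3, return_sorted=True)
    grid, vals = fitted[:, 0], fitted[:, 1]
    grid, idx = np.unique(grid, return_index=True)
    vals = vals[idx]
    resid = rt - np.interp(irt, grid, vals)
    return RtModel(irt_grid=grid, rt_fit=vals, residual_sd=float(np.std(resid)))


@dataclass
class RtVerdict:
    rt_error: float   # observed minus aligned prediction (minutes)
    group: str        # match | deviation | mismatch


def classify_rt(
    rt_error: float,
    observed_rt: float,
    window: float = RT_WINDOW_MIN,
    zone: tuple[float, float] = RT_DEVIATION_ZONE,
) -> RtVerdict:
    """Match within the |error| window; a miss inside the low-RT zone where
    predictions are unreliable counts as a deviation, not a mismatch."""
    if abs(rt_error) <= window:
        group = "match"
    elif zone[0] <= observed_rt <= zone[1]:
        group = "deviation"
    else:
        group = "mismatch"
    return RtVerdict(rt_error=rt_error, group=group)
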