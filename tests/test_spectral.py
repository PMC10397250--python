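"""Spectral contrast angle, peak merging, and retention-time alignment."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from neoseek.spectra import (
    RtModel,
    Spectrum,
    best_sa_verdict,
    classify_rt,
    compare_spectra,
    fit_rt_alignment,
    merge_spectra,
    spectral_angle,
)


def sa_oracle(ia, ib):
    """Independent SA computation: explicit normalization and angle."""
    ia = [float(x) for x in ia]
    ib = [float(x) for x in ib]
    na = math.sqrt(sum(x * x for x in ia))
    nb = math.sqrt(sum(x * x for x in ib))
    dot = sum((x / na) * (y / nb) for x, y in zip(ia, ib))
    dot = min(1.0, max(0.0, dot))
    return 1.0 - 2.0 * math.acos(dot) / math.pi


class TestSpectralAngle:
    def test_identical_is_one(self):
        v = np.array([3.0, 1.0, 2.0])
        assert spectral_angle(v, v) == pytest.approx(1.0)

    def test_disjoint_is_zero(self):
        assert spectral_angle(np.array([1.0, 0.0]), np.array([0.0, 1.0])) == pytest.approx(0.0)

    def test_forty_five_degrees(self):
        sa = spectral_angle(np.array([1.0, 0.0]), np.array([1.0, 1.0]) / math.sqrt(2))
        assert sa == pytest.approx(0.5, abs=1e-12)

    def test_closed_form_case(self):
        sa = spectral_angle(np.array([0.6, 0.8]), np.array([0.8, 0.6]))
        assert sa == pytest.approx(1.0 - 2.0 * math.acos(0.96) / math.pi, abs=1e-12)
        assert sa == pytest.approx(0.819, abs=5e-4)

    def test_oracle_equivalence_random(self):
        rng = np.random.default_rng(3)
        for _ in range(1000):
            n = int(rng.integers(2, 40))
            ia = rng.uniform(0, 1000, n)
            ib = rng.uniform(0, 1000, n)
            assert spectral_angle(ia, ib) == pytest.approx(sa_oracle(ia, ib), abs=1e-9)

    def test_zero_vector_is_error(self):
        with pytest.raises(ValueError):
            spectral_angle(np.zeros(3), np.ones(3))

    @given(st.lists(st.floats(0.01, 1e4), min_size=2, max_size=20),
           st.floats(0.01, 100.0))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_scale_invariance_and_symmetry(self, vals, c):
        rng = np.random.default_rng(len(vals))
        ia = np.asarray(vals)
        ib = rng.uniform(0.01, 100.0, ia.size)
        assert spectral_angle(ia, ib) == pytest.approx(spectral_angle(ib, ia), abs=1e-12)
        assert spectral_angle(c * ia, ib) == pytest.approx(spectral_angle(ia, ib), abs=1e-9)


class TestMergeSpectra:
    def _spec(self, mz, inten=None):
        mz = np.asarray(mz, float)
        return Spectrum(mz=mz, intensity=np.ones_like(mz) if inten is None else np.asarray(inten, float))

    def test_within_tolerance_matched(self):
        ia, ib = merge_spectra(self._spec([500.000]), self._spec([500.005]))  # 10 ppm
        assert len(ia) == 1 and ia[0] > 0 and ib[0] > 0

    def test_outside_tolerance_unmatched(self):
        ia, ib = merge_spectra(self._spec([500.000]), self._spec([500.020]))  # 40 ppm
        assert len(ia) == 2
        assert sorted(zip(ia, ib)) == [(0.0, 1.0), (1.0, 0.0)]

    def test_identical_lists_fully_matched(self):
        s = self._spec([300.0, 400.0, 500.0], [1.0, 2.0, 3.0])
        ia, ib = merge_spectra(s, s)
        assert len(ia) == 3 and np.all(ia == ib)

    def test_each_peak_used_once(self):
        a = self._spec([500.000, 500.004])
        b = self._spec([500.002])
        ia, ib = merge_spectra(a, b)
        assert len(ia) == 2  # one match + one leftover
        assert int(np.sum(np.asarray(ib) > 0)) == 1

    def test_greedy_matches_optimal_on_small_spectra(self):
        """For <= 6 peaks the greedy pairing agrees with exhaustive optimal
        assignment (max matches, then min total ppm) in almost all cases."""
        rng = np.random.default_rng(11)
        disagreements = 0
        for _ in range(300):
            na = int(rng.integers(2, 7))
            a = np.sort(rng.uniform(300, 1000, na))
            # partner spectrum: mostly the same ions (few-ppm shifts), some new
            b = []
            for x in a:
                if rng.random() < 0.7:
                    b.append(x * (1 + rng.normal(0, 5e-6)))
                if rng.random() < 0.3:
                    b.append(rng.uniform(300, 1000))
            if not b:
                b = [rng.uniform(300, 1000)]
            b = np.sort(np.asarray(b)[:6])
            ia, ib = merge_spectra(self._spec(a), self._spec(b))
            got_matches = int(np.sum((np.asarray(ia) > 0) & (np.asarray(ib) > 0)))
            best = _optimal_match_count(a, b)
            disagreements += int(got_matches != best)
        assert disagreements <= 3  # <= 1% of cases

    def test_vector_length_accounting(self):
        a = self._spec([100.0, 200.0, 300.0])
        b = self._spec([200.0, 900.0])
        ia, ib = merge_spectra(a, b)
        assert len(ia) == 1 + 2 + 1  # matches + unmatched_a + unmatched_b


def _optimal_match_count(a, b, tol_ppm=20.0):
    """Maximum bipartite matching size by exhaustive recursion (small inputs)."""
    ok = [
        [abs(x - y) / ((x + y) / 2) * 1e6 <= tol_ppm for y in b]
        for x in a
    ]

    def rec(i, used):
        if i == len(a):
            return 0
        best = rec(i + 1, used)  # leave a[i] unmatched
        for j in range(len(b)):
            if ok[i][j] and j not in used:
                best = max(best, 1 + rec(i + 1, used | {j}))
        return best

    return rec(0, frozenset())


class TestSaVerdict:
    def _pair(self, sa_target):
        a = Spectrum(mz=np.array([400.0, 500.0]), intensity=np.array([1.0, 0.0]) + 1e-9)
        theta = math.pi / 2 * (1 - sa_target)
        b = Spectrum(mz=np.array([400.0, 500.0]),
                     intensity=np.array([math.cos(theta), math.sin(theta)]) + 1e-12)
        return a, b

    @pytest.mark.parametrize("sa, group", [(0.85, "match"), (0.65, "potential"), (0.30, "mismatch")])
    def test_grouping_bands(self, sa, group):
        a, b = self._pair(sa)
        v = best_sa_verdict(a, synthetic=b)
        assert v.group == group
        assert v.best_sa == pytest.approx(sa, abs=1e-6)

    def test_best_of_two(self):
        a, good = self._pair(0.9)
        _, bad = self._pair(0.2)
        v = best_sa_verdict(a, synthetic=bad, predicted=good)
        assert v.best_sa == pytest.approx(0.9, abs=1e-6)
        assert v.group == "match"

    def test_no_comparison_is_error(self):
        a, _ = self._pair(0.9)
        with pytest.raises(ValueError):
            best_sa_verdict(a)


class TestMonotoneCorruption:
    def test_shuffling_never_helps_on_average(self):
        """Replacing a growing share of peak m/z values with noise never
        increases the expected SA (averaged over seeds)."""
        from neoseek.synthetic.msdata import fragment_ions

        pep = "SIINFEKLK"
        mzs, _ = fragment_ions(pep)
        rng0 = np.random.default_rng(0)
        base_int = rng0.lognormal(10, 0.8, mzs.size)
        ref = Spectrum(mz=mzs, intensity=base_int)
        means = []
        for frac in (0.0, 0.25, 0.5, 0.75, 1.0):
            sas = []
            for seed in range(100):
                rng = np.random.default_rng(seed)
                mz2 = mzs.copy()
                k = int(round(frac * mzs.size))
                idx = rng.choice(mzs.size, size=k, replace=False)
                mz2[idx] = rng.uniform(200, 1400, k)
                order = np.argsort(mz2)
                s2 = Spectrum(mz=mz2[order], intensity=base_int[order])
                sas.append(compare_spectra(ref, s2))
            means.append(np.mean(sas))
        assert all(m1 >= m2 - 1e-9 for m1, m2 in zip(means, means[1:]))
        assert means[0] == pytest.approx(1.0)
        assert means[-1] < 0.3


class TestRtAlignment:
    def test_noiseless_linear_recovery(self):
        rng = np.random.default_rng(5)
        irt = rng.uniform(0, 100, 60)
        rt = 2.0 * irt + 5.0
        model = fit_rt_alignment(irt, rt)
        resid = rt - model.predict(irt)
        assert float(np.max(np.abs(resid))) < 0.1

    def test_noisy_residual_scale(self):
        rng = np.random.default_rng(6)
        irt = rng.uniform(0, 100, 200)
        rt = 2.0 * irt + 5.0 + rng.normal(0, 0.5, irt.size)
        model = fit_rt_alignment(irt, rt)
        resid = rt - model.predict(irt)
        assert 0.3 <= float(np.std(resid)) <= 0.8

    def test_too_few_calibrants_is_error(self):
        with pytest.raises(ValueError, match="calibration"):
            fit_rt_alignment(np.arange(10.0), np.arange(10.0))

    def test_extrapolation_clamped(self):
        irt = np.linspace(0, 100, 50)
        model = fit_rt_alignment(irt, 2 * irt + 5)
        assert model.predict(200.0) == pytest.approx(model.predict(100.0))


class TestClassifyRt:
    @pytest.mark.parametrize(
        "err, obs, group",
        [
            (5.0, 50.0, "match"),        # inside the ±8.56 min window
            (12.0, 14.0, "deviation"),   # outside window but in the 9-17 min zone
            (20.0, 60.0, "mismatch"),
            (-8.56, 60.0, "match"),      # window is inclusive
            (8.6, 9.0, "deviation"),     # zone boundary inclusive
        ],
    )
    def test_windows(self, err, obs, group):
        assert classify_rt(err, obs).group == group
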