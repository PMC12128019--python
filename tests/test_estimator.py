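"""Zwanzig windows, Chipot errors, accumulation, ΔU baseline, overlap diagnostic."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from spinfep.constants import KB
from spinfep.dynamics import direct_canonical_sample
from spinfep.errors import InputError, ScheduleError
from spinfep.estimator import (
    DEFAULT_SCHEDULE,
    WindowEstimate,
    WindowRecord,
    accumulate_windows,
    chipot_error,
    delta_u,
    estimate_from_series,
    estimate_window,
    lag1_autocorrelation,
    sampling_ratio,
    window_overlap,
    zwanzig_window,
)
from spinfep.fixtures import generate_ar1, generate_gaussian_dh, make_harmonic_pair
from spinfep.systems import MixedHamiltonianSpec

KBT300 = KB * 300.0


def _rec(dh, T=300.0, lam_i=0.0, lam_j=0.2):
    return WindowRecord(lam_i=lam_i, lam_j=lam_j, dh=np.asarray(dh, float), temperature=T)


def _sample_schedule(system, n, seed, schedule=DEFAULT_SCHEDULE, T=300.0):
    rng = np.random.default_rng(seed)
    return [
        direct_canonical_sample(system, MixedHamiltonianSpec(lam), T, n, rng=rng)
        for lam in schedule
    ]


class TestZwanzig:
    def test_null_perturbation_exact_zero(self):
        assert zwanzig_window(_rec(np.zeros(100))) == 0.0

    @pytest.mark.parametrize("c", [5.0, -3.0, 1e4, -1e4])
    def test_constant_shift_recovered_without_overflow(self, c):
        # log-sum-exp form: |ΔH| of 1e4 kJ/mol must not overflow or underflow
        assert zwanzig_window(_rec(np.full(50, c))) == pytest.approx(c, rel=1e-12)

    def test_gaussian_closed_form(self):
        # ⟨e^{-ΔH/kT}⟩ for ΔH ~ N(μ, σ²) gives ΔG = μ - σ²/(2 k_B T)
        mu, sigma, n = 5.0, 2.0, 200_000
        rec = _rec(generate_gaussian_dh(mu, sigma, n, seed=17))
        expected = mu - sigma**2 / (2 * KBT300)
        eps, _, _ = chipot_error(rec)
        assert zwanzig_window(rec) == pytest.approx(expected, abs=3 * eps)

    def test_empty_series_rejected(self):
        with pytest.raises(InputError):
            WindowRecord(lam_i=0.0, lam_j=0.2, dh=np.array([]), temperature=300.0)

    @settings(max_examples=50, deadline=None)
    @given(
        dh=hnp.arrays(np.float64, st.integers(2, 40),
                      elements=st.floats(-50, 50, allow_nan=False))
    )
    def test_jensen_bound(self, dh):
        # exponential averaging never exceeds the arithmetic mean
        assert zwanzig_window(_rec(dh)) <= dh.mean() + 1e-9


class TestAutocorrelation:
    def test_constant_series_zero_by_convention(self):
        assert lag1_autocorrelation(np.full(10, 3.3)) == 0.0

    def test_alternating_series_near_minus_one(self):
        x = np.tile([1.0, -1.0], 500)
        r1 = lag1_autocorrelation(x)
        assert r1 == pytest.approx(-1.0, abs=2e-3)
        assert r1 > -1.0  # clamped inside the open interval

    def test_ar1_recovers_rho(self):
        r1 = lag1_autocorrelation(generate_ar1(0.5, 100_000, seed=4))
        assert r1 == pytest.approx(0.5, abs=0.02)

    def test_too_short_rejected(self):
        with pytest.raises(InputError):
            lag1_autocorrelation([1.0, 2.0])


class TestSamplingRatio:
    @pytest.mark.parametrize("r1,expected", [(0.0, 1.0), (0.5, 3.0), (-0.5, 1 / 3)])
    def test_closed_forms(self, r1, expected):
        assert sampling_ratio(r1) == pytest.approx(expected, rel=1e-12)

    @pytest.mark.parametrize("r1", [1.0, -1.0, 1.2])
    def test_out_of_range_rejected(self, r1):
        with pytest.raises(InputError):
            sampling_ratio(r1)


class TestChipotError:
    def test_constant_dh_zero_error(self):
        eps, r1, ratio = chipot_error(_rec(np.full(10, 4.0)))
        assert eps == 0.0
        assert r1 == 0.0
        assert ratio == 1.0

    def test_replicate_calibration_iid(self):
        # mean ε should track the empirical spread of ΔG across replicates
        dgs, epss = [], []
        for rep in range(60):
            rec = _rec(generate_gaussian_dh(2.0, 2.0, 2_000, seed=1000 + rep))
            dgs.append(zwanzig_window(rec))
            epss.append(chipot_error(rec)[0])
        ratio = np.mean(epss) / np.std(dgs, ddof=1)
        assert 0.5 < ratio < 2.0

    def test_ar1_inflates_error_by_sampling_ratio(self):
        # ρ=0.8 → ratio (1.8/0.2)=9 → ε up by about √9=3 over the IID value
        iid = _rec(generate_gaussian_dh(2.0, 1.0, 20_000, seed=5))
        corr = _rec(generate_ar1(0.8, 20_000, seed=5, sigma=1.0, mu=2.0))
        eps_iid = chipot_error(iid)[0]
        eps_corr = chipot_error(corr)[0]
        assert 1.8 < eps_corr / eps_iid < 4.5

    def test_printed_variance_form_differs(self):
        # the literal ⟨X⟩−⟨X⟩² reading is kept only for comparison
        rec = _rec(generate_gaussian_dh(1.0, 1.0, 500, seed=6))
        eps_sample = chipot_error(rec, variance_form="sample")[0]
        eps_printed = chipot_error(rec, variance_form="printed")[0]
        assert eps_printed != pytest.approx(eps_sample, rel=1e-3)

    def test_single_sample_rejected(self):
        with pytest.raises(InputError):
            chipot_error(_rec([1.0]))


class TestAccumulation:
    def test_single_window_totals(self):
        w = WindowEstimate(lam_i=0.0, lam_j=1.0, dg=2.5, eps=0.1, r1=0.0,
                           sampling_ratio=1.0, n=100)
        res = accumulate_windows([w])
        assert res.total_dg == 2.5
        assert res.total_eps == 0.1
        assert res.lambda_schedule == (0.0, 1.0)

    def test_six_windows_quadrature_error(self):
        lams = np.round(np.linspace(0, 1, 7), 10)
        ws = [
            WindowEstimate(lam_i=a, lam_j=b, dg=2.0, eps=0.3, r1=0.0,
                           sampling_ratio=1.0, n=10)
            for a, b in zip(lams, lams[1:])
        ]
        res = accumulate_windows(ws)
        assert res.total_dg == pytest.approx(12.0)
        assert res.total_eps == pytest.approx(np.sqrt(6 * 0.09))

    def test_gap_in_schedule_rejected(self):
        ws = [
            WindowEstimate(lam_i=0.0, lam_j=0.4, dg=1.0, eps=0.1, r1=0, sampling_ratio=1, n=5),
            WindowEstimate(lam_i=0.6, lam_j=1.0, dg=1.0, eps=0.1, r1=0, sampling_ratio=1, n=5),
        ]
        with pytest.raises(ScheduleError):
            accumulate_windows(ws)

    def test_schedule_refinement_invariance(self):
        system, df = make_harmonic_pair(10.0, np.e**2, 1, seed=None, x0_shift=0.1)
        res6 = estimate_from_series(_sample_schedule(system, 4_000, seed=1))
        fine = tuple(np.round(np.linspace(0, 1, 11), 10))
        res11 = estimate_from_series(_sample_schedule(system, 4_000, seed=2, schedule=fine))
        combined = 3 * (res6.total_eps + res11.total_eps)
        assert abs(res6.total_dg - res11.total_dg) <= combined

    def test_missing_endpoint_rejected(self, harmonic_1d):
        series = _sample_schedule(harmonic_1d, 100, seed=3, schedule=(0.0, 0.5))
        with pytest.raises(ScheduleError):
            estimate_from_series(series)

    def test_mixed_temperatures_rejected(self, harmonic_1d):
        s0 = direct_canonical_sample(harmonic_1d, MixedHamiltonianSpec(0.0), 300.0, 50, seed=1)
        s1 = direct_canonical_sample(harmonic_1d, MixedHamiltonianSpec(1.0), 310.0, 50, seed=2)
        with pytest.raises(InputError):
            estimate_from_series([s0, s1])


class TestNullPerturbation:
    def test_identical_backends_give_exact_zero(self, identical_pair):
        series = _sample_schedule(identical_pair, 500, seed=11)
        res = estimate_from_series(series)
        for w in res.windows:
            assert w.dg == 0.0
        assert res.total_dg == 0.0


class TestDeltaU:
    def _series(self, lam, values, T=300.0):
        values = np.asarray(values, float)
        from spinfep.dynamics import EnergySeries

        e_s = values if lam == 0.0 else np.zeros_like(values)
        e_t = values if lam == 1.0 else np.zeros_like(values)
        return EnergySeries(lam=lam, steps=np.arange(1, values.size + 1),
                            e_s=e_s, e_t=e_t, e_mix=values, temperature=T, seed=0)

    def test_identical_constant_series(self):
        res = delta_u(self._series(0.0, [7.0] * 5), self._series(1.0, [7.0] * 5))
        assert res.du == 0.0 and res.sd == 0.0

    def test_constant_offset(self):
        res = delta_u(self._series(0.0, [100.0] * 4), self._series(1.0, [140.0] * 4))
        assert res.du == 40.0 and res.sd == 0.0

    def test_gaussian_sd_combines_in_quadrature(self, rng):
        n = 1_000
        s = self._series(0.0, 100 + 40 * rng.standard_normal(n))
        t = self._series(1.0, 400 + 40 * rng.standard_normal(n))
        res = delta_u(s, t)
        assert res.sd == pytest.approx(np.sqrt(2) * 40, rel=0.10)
        assert res.n_singlet == res.n_triplet == n

    def test_wrong_lambda_labels_rejected(self):
        with pytest.raises(InputError):
            delta_u(self._series(0.0, [1.0]), self._series(0.0, [1.0]))


class TestWindowOverlap:
    def test_identical_distributions_full_overlap(self):
        dh = generate_gaussian_dh(1.0, 0.5, 5_000, seed=2)
        fwd = _rec(dh)
        bwd = WindowRecord(lam_i=0.2, lam_j=0.0, dh=-dh, temperature=300.0)
        res = window_overlap(fwd, bwd)
        assert res.overlap > 0.95
        # same finite samples in both directions: discrepancy is the (negative)
        # Jensen bias, not zero — only genuine ensemble pairs cancel exactly
        assert res.discrepancy <= 0.0

    def test_disjoint_distributions_no_overlap(self):
        fwd = _rec(generate_gaussian_dh(0.0, 0.1, 1_000, seed=3))
        bwd = WindowRecord(lam_i=0.2, lam_j=0.0,
                           dh=-generate_gaussian_dh(100.0, 0.1, 1_000, seed=4),
                           temperature=300.0)
        assert window_overlap(fwd, bwd).overlap < 0.01

    def test_harmonic_windows_forward_backward_consistent(self, harmonic_1d):
        series = _sample_schedule(harmonic_1d, 4_000, seed=13)
        for s_i, s_j in zip(series, series[1:]):
            fwd = WindowRecord.from_series(s_i, s_j.lam)
            bwd = WindowRecord.from_series(s_j, s_i.lam)
            res = window_overlap(fwd, bwd)
            eps_f = chipot_error(fwd)[0]
            eps_b = chipot_error(bwd)[0]
            assert abs(res.discrepancy) <= 3 * (eps_f + eps_b)


class TestOracleEquivalence:
    def test_total_dg_matches_analytic_delta_f(self):
        system, df = make_harmonic_pair(10.0, 2.0, 3, seed=7)
        failures = 0
        for seed in range(20):
            res = estimate_from_series(_sample_schedule(system, 3_000, seed=seed))
            if abs(res.total_dg - df) > 3 * res.total_eps:
                failures += 1
        assert failures <= 2
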