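"""Tonic-current measurement chain: filters, reductions, detectors,
window placement, capacitance and QC."""

import math

import numpy as np
import pytest

from tonicephys.tonic_quant import (
    ReducedTrace,
    bessel_lowpass,
    bessel_response_variance_ratio,
    capacitance_from_step,
    detect_block_onset,
    detect_ipscs,
    measure_tonic_shift,
    modulator_response,
    qc_access_resistance,
    reduce_trace,
    remove_outliers,
    rms_shift,
)

DT = 1e-4  # 10 kHz


class TestBessel:
    def test_dc_gain_is_unity(self):
        x = np.full(20000, 5.0)
        np.testing.assert_allclose(bessel_lowpass(x, DT), 5.0, atol=1e-9)

    def test_white_noise_variance_matches_frequency_oracle(self, rng):
        """Output/input variance ratio equals the integral of the
        squared magnitude response of the zero-phase filter."""
        x = rng.normal(size=400000)
        y = bessel_lowpass(x, DT)
        expected = bessel_response_variance_ratio(DT)
        assert y.var() / x.var() == pytest.approx(expected, rel=0.05)
        assert y.var() < x.var()

    def test_fc_above_nyquist_rejected(self):
        with pytest.raises(ValueError):
            bessel_lowpass(np.zeros(100), DT, fc=6000.0)


class TestReduceTrace:
    def test_constant_trace(self):
        r = reduce_trace(np.full(600000, -30.0), DT)
        assert len(r.values) == 600
        np.testing.assert_allclose(r.values, -30.0)

    def test_point_count_is_duration_over_stride(self):
        r = reduce_trace(np.zeros(600000), DT)  # 60 s
        assert len(r.values) == 600

    def test_linear_ramp_reduces_to_ramp_at_window_centers(self):
        t = np.arange(300000) * DT
        r = reduce_trace(1.0 * t, DT)  # 1 pA/s ramp
        np.testing.assert_allclose(r.values, r.t, atol=1e-4)

    def test_brute_force_window_means(self, rng):
        x = rng.normal(size=50000)
        r = reduce_trace(x, DT)
        n_per = int(0.01 / DT)
        for k in (0, 3, len(r.values) - 1):
            i0 = int(round(k * 0.1 / DT))
            assert r.values[k] == pytest.approx(x[i0:i0 + n_per].mean())


class TestIPSCDetection:
    def test_pure_noise_false_positive_rate(self):
        """< 0.02 Hz on 1-pA Gaussian noise (multi-seed Monte-Carlo)."""
        total_events, total_time = 0, 0.0
        for seed in range(4):
            rng = np.random.default_rng(seed)
            x = rng.normal(0.0, 1.0, size=int(100.0 / DT))
            times, _ = detect_ipscs(bessel_lowpass(x, DT), DT)
            total_events += len(times)
            total_time += 100.0
        assert total_events / total_time < 0.02

    def test_injected_events_recovered(self, rng):
        n = int(120.0 / DT)
        x = rng.normal(0.0, 2.0, size=n)
        tr, td = 1e-3, 8e-3
        t_k = np.arange(0.0, 6 * td, DT)
        kern = np.exp(-t_k / td) - np.exp(-t_k / tr)
        kern /= kern.max()
        true_times = 10.0 + np.arange(10) * 10.0
        for tt in true_times:
            i = int(tt / DT)
            x[i:i + len(kern)] -= 50.0 * kern
        times, amps = detect_ipscs(bessel_lowpass(x, DT), DT)
        matched = []
        for tt in true_times:
            j = int(np.argmin(np.abs(times - tt)))
            assert abs(times[j] - tt) < 2e-3
            matched.append(j)
        assert len(set(matched)) == 10
        assert np.all(amps[matched] > 25.0)
        # unmatched detections stay within the false-positive budget
        assert len(times) - 10 <= 3

    def test_blocked_trace_is_silent(self, rng):
        x = rng.normal(0.0, 1.0, size=int(60.0 / DT))
        times, _ = detect_ipscs(bessel_lowpass(x, DT), DT)
        assert len(times) <= 2


class TestBlockOnset:
    def test_rate_drop_located(self, rng):
        pre = np.sort(rng.uniform(0.0, 300.0, size=rng.poisson(5.0 * 300)))
        t, from_epoch = detect_block_onset(pre, total_duration=500.0)
        assert not from_epoch
        assert t == pytest.approx(300.0, abs=5.0)

    def test_constant_rate_falls_back_to_epoch(self, rng):
        ev = np.sort(rng.uniform(0.0, 400.0, size=rng.poisson(2.0 * 400)))
        t, from_epoch = detect_block_onset(ev, 400.0, epoch_start=350.0)
        assert from_epoch and t == 350.0

    def test_no_events_falls_back(self):
        t, from_epoch = detect_block_onset(np.array([]), 400.0, epoch_start=100.0)
        assert from_epoch and t == 100.0

    def test_no_events_no_epoch_raises(self):
        with pytest.raises(ValueError):
            detect_block_onset(np.array([]), 400.0)


class TestOutlierRemoval:
    def _reduced(self, values):
        t = np.arange(len(values)) * 0.1 + 0.005
        return ReducedTrace(t=t, values=np.asarray(values, float),
                            win=0.01, stride=0.1)

    def test_clean_constant_series_untouched(self):
        r, n = remove_outliers(self._reduced(np.full(500, -20.0)))
        assert n == 0 and len(r.values) == 500

    def test_single_artifact_removed(self):
        vals = np.full(500, -20.0) + np.sin(np.arange(500)) * 0.1
        vals[250] = -520.0
        r, n = remove_outliers(self._reduced(vals))
        assert n == 1
        assert -520.0 not in r.values

    def test_gaussian_exclusion_fraction(self):
        """5x(raw)MAD is ~3.37 sigma: the expected exclusion fraction on
        Gaussian data stays below 0.1% (averaged over seeds)."""
        total = 0
        for seed in range(5):
            rng = np.random.default_rng(seed)
            vals = rng.normal(0.0, 2.0, size=20000)
            _, n = remove_outliers(self._reduced(vals))
            total += n
        assert total / 100000 < 1e-3

    def test_short_series_rejected(self):
        with pytest.raises(ValueError):
            remove_outliers(self._reduced(np.zeros(5)))


class TestTonicShift:
    def _step_reduced(self, pre_level, post_level, t_on=120.0, T=240.0):
        t = np.arange(int(T / 0.1)) * 0.1 + 0.005
        vals = np.where(t < t_on, pre_level, post_level).astype(float)
        return ReducedTrace(t=t, values=vals, win=0.01, stride=0.1)

    def test_noiseless_step_is_exact(self):
        r = self._step_reduced(-30.0, -20.0)
        delta, bwin, kwin = measure_tonic_shift(r, 120.0)
        assert delta == pytest.approx(10.0, abs=1e-12)
        assert bwin[1] <= 120.0 and kwin[0] >= 120.0
        assert kwin[0] <= 120.0 + 50.0  # block window within 50 s of onset

    def test_offset_invariance_and_scale_equivariance(self):
        r = self._step_reduced(-30.0, -20.0)
        d0, *_ = measure_tonic_shift(r, 120.0)
        r_shift = ReducedTrace(r.t, r.values + 137.0, r.win, r.stride)
        d1, *_ = measure_tonic_shift(r_shift, 120.0)
        r_scale = ReducedTrace(r.t, r.values * 3.0, r.win, r.stride)
        d2, *_ = measure_tonic_shift(r_scale, 120.0)
        assert d1 == pytest.approx(d0, abs=1e-9)
        assert d2 == pytest.approx(3.0 * d0, abs=1e-9)

    def test_insufficient_data_raises(self):
        r = self._step_reduced(-30.0, -20.0, t_on=5.0, T=30.0)
        with pytest.raises(ValueError):
            measure_tonic_shift(r, 5.0)


class TestRMS:
    def test_constant_trace_has_zero_rms(self):
        x = np.full(int(200.0 / DT), -25.0)
        rb, rk, d = rms_shift(x, DT, 100.0)
        assert rb == 0.0 and rk == 0.0 and d == 0.0

    def test_gaussian_noise_rms_matches_sigma(self, rng):
        x = rng.normal(0.0, 3.0, size=int(200.0 / DT))
        rb, rk, d = rms_shift(x, DT, 100.0)
        assert rb == pytest.approx(3.0, rel=0.05)
        assert rk == pytest.approx(3.0, rel=0.05)
        assert abs(d) < 0.15

    def test_noise_step_gives_positive_delta(self, rng):
        n = int(240.0 / DT)
        x = np.concatenate([rng.normal(0, 3.0, n // 2),
                            rng.normal(0, 1.0, n - n // 2)])
        rb, rk, d = rms_shift(x, DT, 120.0)
        assert d == pytest.approx(2.0, abs=0.2)


class TestCapacitance:
    def _rc_pulse(self, C_pf=100.0, Ra_mohm=10.0, dv=-10.0, dt=2e-5,
                  T=1.0, t0=0.4, dur=0.25):
        n = int(T / dt)
        x = np.zeros(n)
        tau = Ra_mohm * C_pf * 1e-6
        i0 = int(t0 / dt)
        i1 = int((t0 + dur) / dt)
        tt = (np.arange(i0, i1) - i0) * dt
        x[i0:i1] += dv / Ra_mohm * 1e3 * np.exp(-tt / tau)
        return x, dt, (t0, t0 + dur)

    def test_ideal_rc_within_one_percent(self):
        """C = Q/dV: 1 pC over 10 mV -> 100 pF."""
        x, dt, epoch = self._rc_pulse()
        c, ra = capacitance_from_step(x, dt, epoch)
        assert c == pytest.approx(100.0, rel=0.01)
        assert ra == pytest.approx(10.0, rel=0.01)

    def test_zero_capacitance_trace(self):
        x = np.zeros(50000)
        x[20000:30000] = -1000.0  # pure resistive square step, no transient
        c, ra = capacitance_from_step(x, 2e-5, (0.4, 0.6))
        assert c == pytest.approx(0.0, abs=1.0)

    def test_unresolvable_transient_returns_missing(self, rng):
        x = rng.normal(0.0, 2.0, size=50000)
        c, ra = capacitance_from_step(x, 2e-5, (0.4, 0.6))
        assert c is None and ra is None


class TestQC:
    @pytest.mark.parametrize("series,expected", [
        ([10.0, 13.0], False),          # 30% drift
        ([10.0, 11.0], True),           # 10% drift
        ([10.0, 12.5], True),           # exactly 25%: rule is strictly greater
        ([10.0, 12.500001], False),
        ([10.0], True),                 # single reading cannot fail
        ([10.0, 9.0, 12.4, 7.6], True),
    ])
    def test_boundary(self, series, expected):
        assert qc_access_resistance(series) is expected


class TestModulatorResponse:
    def _reduced_with_plateau(self, level, t0=100.0, t1=160.0, T=260.0, noise=0.0,
                              rng=None):
        t = np.arange(int(T / 0.1)) * 0.1 + 0.005
        vals = np.zeros(len(t))
        vals[(t >= t0) & (t < t1)] = level
        if noise and rng is not None:
            vals = vals + rng.normal(0.0, noise, len(t))
        return ReducedTrace(t=t, values=vals, win=0.01, stride=0.1)

    def test_noiseless_plateau_recovered(self):
        r = self._reduced_with_plateau(-6.3)
        assert modulator_response(r, (100.0, 160.0)) == pytest.approx(-6.3)

    def test_null_response_stays_small(self):
        worst = 0.0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            r = self._reduced_with_plateau(0.0, noise=0.1, rng=rng)
            worst = max(worst, abs(modulator_response(r, (100.0, 160.0))))
        assert worst < 0.5

    def test_positive_artifact_keeps_sign(self):
        r = self._reduced_with_plateau(+4.2)
        assert modulator_response(r, (100.0, 160.0)) == pytest.approx(+4.2)

    def test_missing_baseline_rejected(self):
        r = self._reduced_with_plateau(-6.3, t0=0.5)
        with pytest.raises(ValueError):
            modulator_response(r, (0.5, 60.0))
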