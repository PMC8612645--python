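"""Feature extraction: geometric oracles, exclusion rules, invariances."""

import numpy as np
import pytest

from tonicephys.ap_features import (
    FeatureConfig,
    ap_waveform_features,
    build_feature_datasets,
    cohort_feature_matrices,
    detect_action_potentials,
    extract_cell_features,
    input_resistance,
    rheobase_and_rate_features,
    sag_ratio,
)
from tonicephys.synthetic_data import ArchetypeParams, CohortConfig, simulate_cohort, simulate_iv_recording
from tonicephys.trace_io import CellRecord, Sweep

DT = 1e-5  # 100 kHz for the hand-built waveforms


def _triangle_spike(v, dt, t0, rise_ms=1.0, fall_ms=1.0, height=40.0, end_level=None):
    """Add a piecewise-linear spike starting (threshold) at t0 seconds."""
    base = v[int(round(t0 / dt))]
    end_level = base if end_level is None else end_level
    n_r = int(round(rise_ms * 1e-3 / dt))
    n_f = int(round(fall_ms * 1e-3 / dt))
    i0 = int(round(t0 / dt))
    v[i0:i0 + n_r + 1] = base + height * np.arange(n_r + 1) / n_r
    v[i0 + n_r:i0 + n_r + n_f + 1] = (base + height) + (
        (end_level - base - height) * np.arange(n_f + 1) / n_f
    )
    return v


def _voltage_sweep(v, dt=DT, step=(0.1, 0.7), step_pa=100.0):
    stim = np.zeros(len(v))
    i0, i1 = int(step[0] / dt), int(step[1] / dt)
    stim[i0:i1] = step_pa
    return Sweep(samples=v, stimulus=stim, dt=dt, signal_kind="voltage",
                 epochs=[("step", step[0], step[1])])


class TestDetection:
    def test_flat_trace_has_no_spikes(self):
        sw = _voltage_sweep(np.full(80000, -60.0))
        assert detect_action_potentials(sw) == []

    def test_current_sweep_rejected(self):
        sw = Sweep(samples=np.zeros(100), stimulus=np.zeros(100), dt=DT,
                   signal_kind="current")
        with pytest.raises(TypeError):
            detect_action_potentials(sw)

    def test_single_spike_time(self):
        v = np.full(80000, -60.0)
        _triangle_spike(v, DT, 0.30)
        sw = _voltage_sweep(v)
        det = detect_action_potentials(sw)
        assert len(det) == 1
        assert det[0] * DT == pytest.approx(0.30, abs=5e-4)

    def test_two_spikes_5ms_apart(self):
        v = np.full(80000, -60.0)
        _triangle_spike(v, DT, 0.300, rise_ms=0.5, fall_ms=0.5)
        _triangle_spike(v, DT, 0.305, rise_ms=0.5, fall_ms=0.5)
        assert len(detect_action_potentials(_voltage_sweep(v))) == 2

    def test_crossings_within_merge_window_collapse(self):
        v = np.full(80000, -60.0)
        _triangle_spike(v, DT, 0.3000, rise_ms=0.2, fall_ms=0.2)
        _triangle_spike(v, DT, 0.3006, rise_ms=0.2, fall_ms=0.2)
        assert len(detect_action_potentials(_voltage_sweep(v))) == 1


class TestWaveformFeatures:
    def test_symmetric_triangle_halfwidth(self):
        """1-ms rise, 1-ms fall: half crossings at 0.5 and 1.5 ms."""
        v = np.full(80000, -60.0)
        _triangle_spike(v, DT, 0.30, rise_ms=1.0, fall_ms=1.0, height=40.0)
        sw = _voltage_sweep(v)
        idx = detect_action_potentials(sw)[0]
        ap = ap_waveform_features(sw, idx)
        assert ap.halfwidth == pytest.approx(1.0, abs=0.02)
        assert ap.V_peak == pytest.approx(-20.0, abs=0.05)
        assert ap.V_threshold == pytest.approx(-60.0, abs=0.05)

    def test_trough_at_threshold_gives_zero_ahp(self):
        v = np.full(80000, -60.0)
        _triangle_spike(v, DT, 0.30)  # returns exactly to threshold level
        sw = _voltage_sweep(v)
        ap = ap_waveform_features(sw, detect_action_potentials(sw)[0])
        assert ap.AHP == pytest.approx(0.0, abs=0.05)

    def test_missing_downstroke_flagged_not_fabricated(self):
        v = np.full(80000, -60.0)
        i0 = int(0.499 / DT)
        v[i0:i0 + 100] = np.linspace(-60.0, 20.0, 100)
        v[i0 + 100:] = 20.0  # plateau: the downstroke never happens
        sw = _voltage_sweep(v, step=(0.1, 0.5))
        idx = detect_action_potentials(sw)
        ap = ap_waveform_features(sw, idx[0])
        assert ap.halfwidth is None


class TestInputResistance:
    def test_noiseless_passive_cell(self):
        arch = ArchetypeParams(name="p", g_h=0.0, R_in_true=150.0,
                               rheobase_true=1e9)
        rec = simulate_iv_recording(
            arch, protocol=[-100, -80, -60, -40, -20, 0], seed=0)
        assert input_resistance(rec) == pytest.approx(150.0, abs=0.1)

    def test_fewer_than_four_steps_rejected(self):
        arch = ArchetypeParams(name="p", rheobase_true=1e9)
        rec = simulate_iv_recording(arch, protocol=[-60, -40, -20], seed=0)
        with pytest.raises(ValueError):
            input_resistance(rec)

    def test_identical_step_amplitudes_rejected(self):
        v = np.full(20000, -60.0)
        sweeps = [
            Sweep(samples=v.copy(), stimulus=np.full(len(v), 0.0), dt=DT,
                  signal_kind="voltage", sweep_id=str(i))
            for i in range(4)
        ]
        for sw in sweeps:
            sw.stimulus[5000:15000] = -40.0
        rec = CellRecord(cell_id="c", iv_sweeps=sweeps)
        with pytest.raises(ValueError):
            input_resistance(rec)


class TestSagRatio:
    def _sag_sweep(self, trough, steady, base=-60.0):
        dt = 1e-4
        n = 12000  # 0.2 s pre, 0.8 s step, 0.2 s post
        v = np.full(n, base)
        i0, i1 = 2000, 10000
        v[i0:i1] = steady
        v[i0 + 200:i0 + 400] = trough  # early trough
        stim = np.zeros(n)
        stim[i0:i1] = -100.0
        return CellRecord(cell_id="c", iv_sweeps=[
            Sweep(samples=v, stimulus=stim, dt=dt, signal_kind="voltage",
                  epochs=[("step", 0.2, 1.0)])
        ])

    def test_worked_example(self):
        """baseline -60, trough -80, steady -75 -> 20/15 = 1.333."""
        assert sag_ratio(self._sag_sweep(-80.0, -75.0)) == pytest.approx(
            20.0 / 15.0, abs=1e-6)

    def test_no_sag_is_unity(self):
        assert sag_ratio(self._sag_sweep(-75.0, -75.0)) == pytest.approx(1.0)

    def test_depolarizing_sweep_rejected(self):
        rec = self._sag_sweep(-80.0, -75.0)
        rec.iv_sweeps[0].stimulus[2000:10000] = +100.0
        with pytest.raises(ValueError):
            sag_ratio(rec)

    def test_synthetic_cell_without_h_current(self):
        arch = ArchetypeParams(name="p", g_h=0.0, rheobase_true=1e9)
        rec = simulate_iv_recording(arch, protocol=[-100, -80, -60, -40],
                                    seed=0)
        assert sag_ratio(rec) == pytest.approx(1.0, abs=0.02)


class TestRateFeatures:
    def _spike_train_record(self, isis_ms, step_pa=100.0):
        dt = DT
        v = np.full(100000, -60.0)
        t = 0.30
        times = [t]
        for isi in isis_ms:
            t += isi * 1e-3
            times.append(t)
        for tt in times:
            _triangle_spike(v, dt, tt, rise_ms=0.4, fall_ms=0.4)
        return CellRecord(cell_id="c", iv_sweeps=[
            _voltage_sweep(v, dt=dt, step=(0.1, 0.9), step_pa=step_pa)
        ]), times

    def test_isi_sd_worked_example(self):
        """ISIs {10, 20, 30} ms give sample SD 10 ms."""
        rec, _ = self._spike_train_record([10.0, 20.0, 30.0])
        feats = rheobase_and_rate_features(rec)
        assert feats.rheobase == 100.0
        assert feats.isi_sd_profile[0.0] == pytest.approx(10.0, abs=0.02)

    def test_perfectly_regular_isis(self):
        rec, _ = self._spike_train_record([20.0, 20.0, 20.0, 20.0])
        feats = rheobase_and_rate_features(rec)
        assert feats.isi_sd_profile[0.0] == pytest.approx(0.0, abs=0.02)

    def test_three_spike_sweep_excluded_from_isi_profile(self):
        rec, _ = self._spike_train_record([10.0, 20.0])  # 3 spikes
        feats = rheobase_and_rate_features(rec)
        assert feats.isi_sd_profile == {}

    def test_no_spiking_sweep_flags_cell(self):
        rec = CellRecord(cell_id="c", iv_sweeps=[
            _voltage_sweep(np.full(80000, -60.0))])
        feats = rheobase_and_rate_features(rec)
        assert feats.rheobase is None
        assert "no_spiking_sweep" in feats.flags

    def test_latency_measured_from_step_onset(self):
        rec, times = self._spike_train_record([20.0, 20.0, 20.0])
        feats = rheobase_and_rate_features(rec)
        assert feats.first_spike_latency == pytest.approx(200.0, abs=0.1)


class TestFeatureDatasets:
    def test_thirteen_datasets(self, default_cohort):
        records, _ = default_cohort
        ds = build_feature_datasets(records[0])
        assert len(ds) == FeatureConfig().n_datasets == 13
        assert all(np.ndim(d) == 1 for d in ds)

    def test_zero_jitter_cohort_has_zero_between_cell_variance(self):
        arch = ArchetypeParams(name="det", cv_isi=0.0, d=0.9,
                               rheobase_true=100.0)
        cfg = CohortConfig(param_jitter=0.0, sigma_v=0.0)
        recs, _ = simulate_cohort(cfg, n_cells=4, archetype_mixture=[1.0],
                                  seed=0, archetypes=(arch,))
        mats, _ = cohort_feature_matrices(recs)
        for M in mats:
            assert np.nanmax(np.var(M, axis=0)) == pytest.approx(0.0, abs=1e-18)

    def test_stimulus_baseline_translation_invariance(self):
        """All features are dV/dI based: adding a constant holding
        current to the stimulus channel changes nothing."""
        arch = ArchetypeParams(name="a", cv_isi=0.0)
        rec = simulate_iv_recording(arch, seed=1)
        f0 = extract_cell_features(rec)
        for sw in rec.iv_sweeps:
            sw.stimulus = sw.stimulus + 50.0
        f1 = extract_cell_features(rec)
        assert f1.R_in == pytest.approx(f0.R_in, rel=1e-12)
        assert f1.sag_ratio == pytest.approx(f0.sag_ratio, rel=1e-12)
        assert f1.first_ap.V_peak == f0.first_ap.V_peak
        assert f1.accommodation_ratio == pytest.approx(
            f0.accommodation_ratio, rel=1e-12)


def test_feature_recovery_matches_truth(zero_noise_cohort):
    """On a zero-recording-noise cohort every extracted feature matches
    the generator's ground truth (0.5 mV, 0.05 ms, 2% relative)."""
    from tonicephys.synthetic_data import AMP_FLOOR

    for rec in zero_noise_cohort[:10]:
        truth = rec.ground_truth
        f = extract_cell_features(rec)
        ap = f.first_ap
        assert ap.V_threshold == pytest.approx(truth.ap_params["V_thr"], abs=0.5)
        assert ap.V_peak == pytest.approx(truth.ap_params["V_peak"], abs=0.5)
        assert ap.halfwidth == pytest.approx(truth.ap_params["halfwidth_ms"], abs=0.05)
        assert ap.AHP == pytest.approx(truth.ap_params["AHP"], abs=0.5)
        assert f.R_in == pytest.approx(truth.true_R_in, rel=0.02)
        assert f.sag_ratio == pytest.approx(truth.true_sag_ratio, rel=0.02)
        assert f.rheobase == truth.true_rheobase
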