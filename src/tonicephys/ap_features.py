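"""Intrinsic-physiology feature extraction from current-clamp IV families.

Per-spike features follow the usual manual conventions: the threshold is
the voltage at the dV/dt criterion crossing (default 20 mV/ms), the peak
is the local voltage maximum, the half-width is the time between the
upstroke and downstroke crossings of the voltage halfway between
threshold and peak, and the AHP is measured relative to threshold
(positive = trough below threshold).  Per-cell features include the
input resistance from the steady-state responses of the first four
hyperpolarizing steps, the sag ratio of the most hyperpolarizing sweep,
rheobase, the amplitude-accommodation ratio at rheobase + 60 pA and the
ISI-SD profile (sweeps with at least four spikes only).

:func:`build_feature_datasets` distils each cell's IV family into a
configurable set of fixed-length vectors (default 13) spanning
subthreshold trajectories, spike waveforms and their derivatives,
per-spike feature trajectories and rate/irregularity profiles; these are
the inputs to the firing-type clustering stage.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .trace_io import CellRecord, Sweep, step_current

__all__ = [
    "APFeatures",
    "CellFeatures",
    "FeatureConfig",
    "detect_action_potentials",
    "ap_waveform_features",
    "input_resistance",
    "sag_ratio",
    "rheobase_and_rate_features",
    "extract_cell_features",
    "build_feature_datasets",
    "cohort_feature_matrices",
]

DVDT_THRESHOLD = 20.0   # mV/ms
MERGE_WINDOW = 1e-3     # s
STEADY_WINDOW = 0.1     # s, steady state = last 100 ms of the step


@dataclass
class APFeatures:
    t_spike: float              # s, threshold-crossing time
    V_threshold: float          # mV
    V_peak: float               # mV
    halfwidth: Optional[float]  # ms, None if no downstroke half-crossing
    AHP: Optional[float]        # mV below threshold (positive = deeper)

    @property
    def amplitude(self) -> float:
        return self.V_peak - self.V_threshold


@dataclass
class CellFeatures:
    cell_id: str = ""
    R_in: float = float("nan")                # MOhm
    sag_ratio: float = float("nan")
    rheobase: Optional[float] = None          # pA; None if no sweep spikes
    first_ap: Optional[APFeatures] = None
    accommodation_ratio: Optional[float] = None
    first_spike_latency: Optional[float] = None   # ms, at rheobase
    fi_curve: dict = field(default_factory=dict)          # I (pA) -> rate (Hz)
    isi_sd_profile: dict = field(default_factory=dict)    # I - rheobase -> SD (ms)
    isi_cv_profile: dict = field(default_factory=dict)    # I - rheobase -> CV
    latency_profile: dict = field(default_factory=dict)   # I - rheobase -> ms
    max_rate: float = 0.0                     # Hz
    flags: list = field(default_factory=list)


def _step_window(sweep: Sweep) -> tuple[int, int]:
    """Sample range of the current step, from the epoch annotation if
    present, else from the stimulus waveform."""
    span = sweep.epoch_span("step")
    if span is not None:
        return int(round(span[0] / sweep.dt)), int(round(span[1] / sweep.dt))
    dev = np.flatnonzero(np.abs(sweep.stimulus - sweep.stimulus[0]) > 1e-9)
    if len(dev) == 0:
        return 0, sweep.n_samples
    return int(dev[0]), int(dev[-1]) + 1


def detect_action_potentials(
    sweep: Sweep,
    dvdt_threshold: float = DVDT_THRESHOLD,
    merge_window: float = MERGE_WINDOW,
) -> list[int]:
    """Indices of dV/dt-threshold upward crossings, one per spike.

    Crossings closer together than ``merge_window`` are merged (first
    kept).  Raises ``TypeError`` for a current-signal sweep.
    """
    if sweep.signal_kind != "voltage":
        raise TypeError("spike detection requires a voltage sweep")
    v = sweep.samples
    dvdt = np.diff(v) / (sweep.dt * 1e3)  # mV/ms, forward difference
    above = dvdt >= dvdt_threshold
    crossings = np.flatnonzero(above & ~np.concatenate(([False], above[:-1])))
    if len(crossings) == 0:
        return []
    merged = [int(crossings[0])]
    min_gap = merge_window / sweep.dt
    for c in crossings[1:]:
        if c - merged[-1] >= min_gap:
            merged.append(int(c))
    return merged


def _interp_crossing(t0: float, v0: float, t1: float, v1: float, level: float) -> float:
    if v1 == v0:
        return t0
    return t0 + (level - v0) / (v1 - v0) * (t1 - t0)


def ap_waveform_features(
    sweep: Sweep,
    spike_index: int,
    next_index: Optional[int] = None,
    search_end: Optional[int] = None,
) -> APFeatures:
    """Measure one action potential anchored at a detected threshold index.

    The peak is the voltage maximum between the threshold crossing and
    the next spike (or ``search_end``); a missing downstroke
    half-crossing before the search end leaves ``halfwidth`` as None
    rather than fabricating a value, and likewise for the AHP.
    """
    v = sweep.samples
    dt = sweep.dt
    if not 0 <= spike_index < sweep.n_samples:
        raise IndexError(f"spike index {spike_index} out of range")
    end = next_index if next_index is not None else (
        search_end if search_end is not None else sweep.n_samples
    )
    end = min(end, sweep.n_samples)

    thr_v = float(v[spike_index])
    seg = v[spike_index:end]
    i_peak = int(np.argmax(seg)) + spike_index
    peak_v = float(v[i_peak])

    half = 0.5 * (thr_v + peak_v)
    t = sweep.time
    # upstroke crossing between threshold index and peak
    up = None
    for i in range(spike_index, i_peak):
        if v[i] <= half <= v[i + 1]:
            up = _interp_crossing(t[i], v[i], t[i + 1], v[i + 1], half)
            break
    # downstroke crossing after the peak
    down = None
    for i in range(i_peak, end - 1):
        if v[i] >= half >= v[i + 1]:
            down = _interp_crossing(t[i], v[i], t[i + 1], v[i + 1], half)
            break
    halfwidth = (down - up) * 1e3 if (up is not None and down is not None) else None

    ahp: Optional[float] = None
    if down is not None:
        i_down = int(math.ceil(down / dt))
        tail = v[i_down:end]
        if len(tail) > 0:
            ahp = thr_v - float(np.min(tail))
    return APFeatures(
        t_spike=float(t[spike_index]),
        V_threshold=thr_v,
        V_peak=peak_v,
        halfwidth=halfwidth,
        AHP=ahp,
    )


def _steady_state_dv(sweep: Sweep) -> float:
    """Mean voltage over the last 100 ms of the step minus the pre-step
    baseline mean."""
    i0, i1 = _step_window(sweep)
    n_ss = max(1, int(round(STEADY_WINDOW / sweep.dt)))
    base = float(np.mean(sweep.samples[:i0])) if i0 > 0 else float(sweep.samples[0])
    return float(np.mean(sweep.samples[i1 - n_ss:i1])) - base


def input_resistance(record: CellRecord) -> float:
    """Input resistance (MOhm) from the first four hyperpolarizing steps.

    Least-squares slope of steady-state voltage deflection against step
    current over exactly the four most hyperpolarizing sweeps.
    """
    hyper = [(step_current(sw), sw) for sw in record.iv_sweeps if step_current(sw) < 0]
    if len(hyper) < 4:
        raise ValueError(
            f"need at least 4 hyperpolarizing steps, found {len(hyper)}"
        )
    hyper.sort(key=lambda p: p[0])
    steps = np.array([i for i, _ in hyper[:4]])
    if np.ptp(steps) < 1e-12:
        raise ValueError("hyperpolarizing steps have identical amplitude; singular fit")
    dv = np.array([_steady_state_dv(sw) for _, sw in hyper[:4]])
    slope = np.polyfit(steps, dv, 1)[0]  # mV/pA
    return float(slope * 1e3)            # MOhm


def sag_ratio(record: CellRecord) -> float:
    """Sag ratio of the most hyperpolarizing sweep.

    S = (V_baseline - V_trough) / (V_baseline - V_steady), with the
    trough the minimum during the step and the steady state the mean of
    the last 100 ms of the step.  S = 1 means no sag.
    """
    sw = min(record.iv_sweeps, key=step_current)
    if step_current(sw) >= 0:
        raise ValueError("most hyperpolarizing sweep is not hyperpolarizing")
    i0, i1 = _step_window(sw)
    base = float(np.mean(sw.samples[:i0]))
    trough = float(np.min(sw.samples[i0:i1]))
    n_ss = max(1, int(round(STEADY_WINDOW / sw.dt)))
    steady = float(np.mean(sw.samples[i1 - n_ss:i1]))
    denom = base - steady
    if abs(denom) < 1e-12:
        return 1.0
    return (base - trough) / denom


def _sweep_spike_stats(sweep: Sweep) -> dict:
    """Spike times/ISIs within the step window of one sweep."""
    idx = detect_action_potentials(sweep)
    i0, i1 = _step_window(sweep)
    idx = [i for i in idx if i0 <= i < i1]
    times = np.array([i * sweep.dt for i in idx])
    isis = np.diff(times) * 1e3  # ms
    return {"indices": idx, "times": times, "isis": isis}


def rheobase_and_rate_features(record: CellRecord) -> CellFeatures:
    """Rheobase, fI curve, ISI-SD/CV profiles, accommodation and latency.

    Rheobase is the smallest step current evoking at least one spike.
    ISI statistics are reported only for sweeps with four or more
    spikes.  The accommodation ratio (first/last spike amplitude) is
    taken from the rheobase + 60 pA sweep.  A cell with no spiking sweep
    has ``rheobase=None`` and is flagged.
    """
    feats = CellFeatures(cell_id=record.cell_id)
    per_sweep: list[tuple[float, Sweep, dict]] = []
    for sw in record.iv_sweeps:
        if sw.signal_kind != "voltage":
            continue
        per_sweep.append((step_current(sw), sw, _sweep_spike_stats(sw)))

    spiking = [(i_inj, sw, st) for i_inj, sw, st in per_sweep if len(st["indices"]) > 0]
    if not spiking:
        feats.flags.append("no_spiking_sweep")
        return feats
    rheo, rheo_sweep, rheo_stats = min(spiking, key=lambda p: p[0])
    feats.rheobase = float(rheo)

    i0, _ = _step_window(rheo_sweep)
    feats.first_spike_latency = (rheo_stats["times"][0] - i0 * rheo_sweep.dt) * 1e3

    first_idx = rheo_stats["indices"][0]
    nxt = rheo_stats["indices"][1] if len(rheo_stats["indices"]) > 1 else None
    _, step_end = _step_window(rheo_sweep)
    feats.first_ap = ap_waveform_features(rheo_sweep, first_idx, nxt, step_end)

    for i_inj, sw, st in per_sweep:
        dur = np.diff(_step_window(sw))[0] * sw.dt
        n_spk = len(st["indices"])
        feats.fi_curve[float(i_inj)] = n_spk / dur
        if i_inj >= rheo and n_spk >= 1:
            si0, _ = _step_window(sw)
            feats.latency_profile[float(i_inj - rheo)] = (
                st["times"][0] - si0 * sw.dt
            ) * 1e3
        if n_spk >= 4:
            feats.isi_sd_profile[float(i_inj - rheo)] = float(np.std(st["isis"], ddof=1))
            mean_isi = float(np.mean(st["isis"]))
            if mean_isi > 0:
                feats.isi_cv_profile[float(i_inj - rheo)] = (
                    float(np.std(st["isis"], ddof=1)) / mean_isi
                )
    feats.max_rate = max(feats.fi_curve.values(), default=0.0)

    acc_candidates = [p for p in spiking if abs(p[0] - (rheo + 60.0)) < 1e-6]
    if acc_candidates:
        i_inj, sw, st = acc_candidates[0]
        idx = st["indices"]
        if len(idx) >= 2:
            _, step_end = _step_window(sw)
            bounds = idx[1:] + [step_end]
            aps = [
                ap_waveform_features(sw, ix, bounds[k], step_end)
                for k, ix in enumerate(idx)
            ]
            if aps[-1].amplitude > 0:
                feats.accommodation_ratio = aps[0].amplitude / aps[-1].amplitude
        else:
            feats.flags.append("too_few_spikes_for_accommodation")
    else:
        feats.flags.append("no_rheobase_plus_60_sweep")
    return feats


def extract_cell_features(record: CellRecord) -> CellFeatures:
    """All scalar intrinsic features for one cell."""
    feats = rheobase_and_rate_features(record)
    try:
        feats.R_in = input_resistance(record)
    except ValueError as exc:
        feats.flags.append(f"R_in: {exc}")
    try:
        feats.sag_ratio = sag_ratio(record)
    except ValueError as exc:
        feats.flags.append(f"sag: {exc}")
    return feats


# ---------------------------------------------------------------------------
# feature datasets for clustering
# ---------------------------------------------------------------------------

@dataclass
class FeatureConfig:
    """Layout of the per-cell feature datasets.

    ``n_trace`` points for resampled voltage segments, ``n_profile`` for
    per-spike / per-step profiles.  ``rel_grid`` is the step-current
    grid relative to rheobase on which rate profiles are interpolated.
    """

    n_trace: int = 64
    n_profile: int = 8
    rel_grid: tuple = (0.0, 20.0, 40.0, 60.0, 80.0, 100.0)
    ap_window_ms: tuple = (-2.0, 6.0)

    @property
    def n_datasets(self) -> int:
        return 13


def _resample(y: np.ndarray, n: int) -> np.ndarray:
    if len(y) == 0:
        return np.full(n, np.nan)
    if len(y) == 1:
        return np.full(n, float(y[0]))
    x = np.linspace(0.0, 1.0, len(y))
    return np.interp(np.linspace(0.0, 1.0, n), x, y)


def _profile_on_grid(profile: dict, grid: tuple) -> np.ndarray:
    out = np.full(len(grid), np.nan)
    for i, g in enumerate(grid):
        for k, v in profile.items():
            if abs(k - g) < 1e-6:
                out[i] = v
    return out


def build_feature_datasets(
    record: CellRecord,
    config: Optional[FeatureConfig] = None,
    feats: Optional[CellFeatures] = None,
) -> list[np.ndarray]:
    """Distil one cell's IV family into fixed-length feature vectors.

    Returns 13 vectors: (1) baseline-subtracted subthreshold trajectory
    of the most hyperpolarizing step, (2) sag/rebound segment, (3) first
    AP waveform at rheobase, (4) its time derivative, (5-7) per-spike
    peak-amplitude, half-width and threshold trajectories at rheobase
    + 60 pA, (8) binned instantaneous firing rate at rheobase + 60 pA,
    (9) fI curve, (10) ISI-SD profile, (11) first-spike latency profile,
    (12) steady-state IV relation of the hyperpolarizing steps, (13)
    per-spike AHP trajectory.  Entries that a cell cannot define (e.g.
    no rheobase) are NaN; imputation happens at the cohort stage.
    """
    config = config or FeatureConfig()
    if feats is None:
        feats = extract_cell_features(record)
    nt, npf = config.n_trace, config.n_profile
    datasets: list[np.ndarray] = []

    # (1) subthreshold trajectory, (2) sag/rebound segment
    sw_hyp = min(record.iv_sweeps, key=step_current)
    i0, i1 = _step_window(sw_hyp)
    base = float(np.mean(sw_hyp.samples[:i0])) if i0 > 0 else float(sw_hyp.samples[0])
    datasets.append(_resample(sw_hyp.samples[i0:i1] - base, nt))
    n_reb = min(sw_hyp.n_samples - i1, int(round(0.2 / sw_hyp.dt)))
    seg = sw_hyp.samples[i1 - int(round(0.1 / sw_hyp.dt)):i1 + n_reb] - base
    datasets.append(_resample(seg, nt))

    # (3, 4) AP waveform and derivative at rheobase
    ap_wave = np.full(nt, np.nan)
    ap_dvdt = np.full(nt, np.nan)
    rheo_sweep = None
    if feats.rheobase is not None:
        for sw in record.iv_sweeps:
            if abs(step_current(sw) - feats.rheobase) < 1e-6:
                rheo_sweep = sw
                break
    if rheo_sweep is not None and feats.first_ap is not None:
        dt = rheo_sweep.dt
        c = int(round(feats.first_ap.t_spike / dt))
        w0 = c + int(round(config.ap_window_ms[0] * 1e-3 / dt))
        w1 = c + int(round(config.ap_window_ms[1] * 1e-3 / dt))
        if w0 >= 0 and w1 <= rheo_sweep.n_samples:
            wave = rheo_sweep.samples[w0:w1]
            ap_wave = _resample(wave, nt)
            ap_dvdt = _resample(np.gradient(wave, dt * 1e3), nt)
    datasets.append(ap_wave)
    datasets.append(ap_dvdt)

    # (5-8, 13) per-spike trajectories and binned rate at rheobase + 60
    peak_traj = np.full(npf, np.nan)
    hw_traj = np.full(npf, np.nan)
    thr_traj = np.full(npf, np.nan)
    ahp_traj = np.full(npf, np.nan)
    rate_bins = np.full(npf, np.nan)
    if feats.rheobase is not None:
        target = feats.rheobase + 60.0
        for sw in record.iv_sweeps:
            if abs(step_current(sw) - target) < 1e-6:
                st = _sweep_spike_stats(sw)
                idx = st["indices"]
                s0, s1 = _step_window(sw)
                if idx:
                    bounds = idx[1:] + [s1]
                    aps = [
                        ap_waveform_features(sw, ix, bounds[k], s1)
                        for k, ix in enumerate(idx)
                    ]
                    peak_traj = _resample(np.array([a.amplitude for a in aps]), npf)
                    hw_traj = _resample(
                        np.array([a.halfwidth if a.halfwidth is not None else np.nan
                                  for a in aps]), npf)
                    thr_traj = _resample(np.array([a.V_threshold for a in aps]), npf)
                    ahp_traj = _resample(
                        np.array([a.AHP if a.AHP is not None else np.nan
                                  for a in aps]), npf)
                edges = np.linspace(s0 * sw.dt, s1 * sw.dt, npf + 1)
                counts, _ = np.histogram(st["times"], bins=edges)
                rate_bins = counts / np.diff(edges)
                break
    datasets.append(peak_traj)
    datasets.append(hw_traj)
    datasets.append(thr_traj)
    datasets.append(rate_bins)

    # (9) fI curve on the relative grid
    fi = np.full(len(config.rel_grid), np.nan)
    if feats.rheobase is not None:
        rel = {i - feats.rheobase: r for i, r in feats.fi_curve.items()}
        fi = _profile_on_grid(rel, config.rel_grid)
    datasets.append(fi)

    # (10) ISI-SD profile, (11) latency profile
    datasets.append(_profile_on_grid(feats.isi_sd_profile, config.rel_grid))
    datasets.append(_profile_on_grid(feats.latency_profile, config.rel_grid))

    # (12) steady-state IV of hyperpolarizing steps
    hyp = sorted(
        (step_current(sw), _steady_state_dv(sw))
        for sw in record.iv_sweeps if step_current(sw) < 0
    )
    datasets.append(_resample(np.array([dv for _, dv in hyp]), npf))

    # (13) per-spike AHP trajectory
    datasets.append(ahp_traj)
    assert len(datasets) == config.n_datasets
    return datasets


def cohort_feature_matrices(
    records: list[CellRecord],
    config: Optional[FeatureConfig] = None,
    feats_list: Optional[list[CellFeatures]] = None,
) -> tuple[list[np.ndarray], dict]:
    """Stack per-cell feature datasets into per-dataset matrices.

    Missing entries are imputed with the dataset-wise (column) median;
    the returned report lists, per dataset, how many cells required
    imputation.
    """
    config = config or FeatureConfig()
    if feats_list is None:
        feats_list = [extract_cell_features(r) for r in records]
    per_cell = [
        build_feature_datasets(r, config, f) for r, f in zip(records, feats_list)
    ]
    matrices: list[np.ndarray] = []
    report: dict[int, int] = {}
    for k in range(config.n_datasets):
        M = np.vstack([pc[k] for pc in per_cell])
        bad_rows = int(np.sum(np.any(np.isnan(M), axis=1)))
        if bad_rows:
            med = np.nanmedian(M, axis=0)
            med = np.where(np.isnan(med), 0.0, med)
            nan_mask = np.isnan(M)
            M[nan_mask] = np.broadcast_to(med, M.shape)[nan_mask]
        report[k] = bad_rows
        matrices.append(M)
    return matrices, report
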