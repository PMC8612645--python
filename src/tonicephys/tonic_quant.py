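"""Tonic GABA-A current, RMS-noise and capacitance analysis of
voltage-clamp traces.

The measurement chain mirrors standard practice for small tonic
currents: the raw holding-current trace is low-pass filtered (2-kHz
8-pole Bessel, applied forward-backward so the filter is zero-phase),
reduced to 10-ms window means at 100-ms intervals, cleaned of outliers
caused by large synaptic events, and the tonic current is the
difference of 20-s mean-current windows placed on either side of the
GABA-A block onset (within 50 s of it, at the placement minimizing the
within-window linear trend).  The onset itself is located from the
disappearance of spontaneous IPSCs via a single-changepoint Poisson
rate estimate, falling back to the annotated drug epoch.  The RMS of
the current noise is computed in 0.5-s windows about each window's own
mean; its drop on block is an independent index of the tonic
conductance.  Whole-cell capacitance comes from the charge of the
capacitance-test transient (area divided by the voltage step), and
recordings are rejected when the access resistance drifts by more than
25% from its first value.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import signal

from .trace_io import Sweep

__all__ = [
    "ReducedTrace",
    "TonicResult",
    "bessel_lowpass",
    "reduce_trace",
    "detect_ipscs",
    "detect_block_onset",
    "remove_outliers",
    "measure_tonic_shift",
    "rms_shift",
    "capacitance_from_step",
    "qc_access_resistance",
    "modulator_response",
    "analyze_vc_trace",
]

MODULATOR_DRUGS = ("allopregnanolone", "DS2", "MRK-016", "gaba")


@dataclass
class ReducedTrace:
    """Windowed-mean reduction of a current trace."""

    t: np.ndarray        # window centers (s)
    values: np.ndarray   # window means (pA)
    win: float
    stride: float


@dataclass
class TonicResult:
    cell_id: str = ""
    I_tonic: float = float("nan")        # pA, positive = outward shift on block
    raw_delta: float = float("nan")      # pA, mean(block) - mean(baseline)
    rms_baseline: float = float("nan")
    rms_block: float = float("nan")
    delta_rms: float = float("nan")      # pA, baseline - block
    C_vc: Optional[float] = None         # pF
    I_tonic_per_pF: Optional[float] = None
    block_onset_time: float = float("nan")
    onset_from_epoch: bool = False
    baseline_window: tuple = (float("nan"), float("nan"))
    block_window: tuple = (float("nan"), float("nan"))
    outliers_removed: int = 0
    R_a_series: list = field(default_factory=list)
    qc_pass: bool = True
    modulator_responses: dict = field(default_factory=dict)
    flags: list = field(default_factory=list)


def bessel_lowpass(x: np.ndarray, dt: float, fc: float = 2000.0, order: int = 8) -> np.ndarray:
    """Zero-phase digital Bessel low-pass (DC gain exactly 1)."""
    nyq = 0.5 / dt
    if fc >= nyq:
        raise ValueError(f"fc={fc} Hz is not below the Nyquist frequency {nyq} Hz")
    sos = signal.bessel(order, fc, btype="low", fs=1.0 / dt, output="sos", norm="phase")
    return signal.sosfiltfilt(sos, np.asarray(x, dtype=float))


def bessel_response_variance_ratio(dt: float, fc: float = 2000.0, order: int = 8,
                                   n_freq: int = 65536) -> float:
    """Output/input variance ratio of the zero-phase Bessel filter for
    white noise, by numerical integration of |H(f)|^4 (the filter is
    applied forward and backward, so the effective magnitude response is
    |H|^2)."""
    sos = signal.bessel(order, fc, btype="low", fs=1.0 / dt, output="sos", norm="phase")
    w, h = signal.sosfreqz(sos, worN=n_freq, fs=1.0 / dt)
    return float(np.trapezoid(np.abs(h) ** 4, w) / (w[-1] - w[0]))


def reduce_trace(x: np.ndarray, dt: float, win: float = 0.01, stride: float = 0.1) -> ReducedTrace:
    """Means of ``win``-long windows anchored every ``stride`` seconds,
    timestamped at window centers."""
    x = np.asarray(x, dtype=float)
    dur = len(x) * dt
    if dur < win:
        raise ValueError("trace shorter than the averaging window")
    n_win = int(math.floor((dur - win) / stride)) + 1
    n_per = max(1, int(round(win / dt)))
    starts = (np.arange(n_win) * stride / dt).round().astype(int)
    idx = starts[:, None] + np.arange(n_per)[None, :]
    vals = x[idx].mean(axis=1)
    t = np.arange(n_win) * stride + win / 2.0
    return ReducedTrace(t=t, values=vals, win=win, stride=stride)


def _chunk_median_baseline(x: np.ndarray, dt: float, chunk: float = 1.0) -> np.ndarray:
    n_per = max(1, int(round(chunk / dt)))
    n_chunks = max(1, len(x) // n_per)
    meds = np.array([np.median(x[i * n_per:(i + 1) * n_per]) for i in range(n_chunks)])
    t_med = (np.arange(n_chunks) + 0.5) * n_per * dt
    t = np.arange(len(x)) * dt
    return np.interp(t, t_med, meds)


def detect_ipscs(
    x: np.ndarray,
    dt: float,
    k_mad: float = 4.0,
    tau_rise: float = 1.0,
    tau_decay: float = 8.0,
    min_separation: float = 5e-3,
) -> tuple[np.ndarray, np.ndarray]:
    """Detect spontaneous IPSCs (inward deflections) in a filtered trace.

    A rolling-median baseline is subtracted, the residual is correlated
    with a difference-of-exponentials template, and negative excursions
    beyond ``k_mad`` times the MAD of the matched-filter output are kept
    as events.  Returns (times, amplitudes) with amplitudes positive
    (pA, relative to the local baseline).
    """
    x = np.asarray(x, dtype=float)
    baseline = _chunk_median_baseline(x, dt)
    resid = x - baseline

    t_k = np.arange(0.0, 6.0 * tau_decay * 1e-3, dt)
    kern = np.exp(-t_k / (tau_decay * 1e-3)) - np.exp(-t_k / (tau_rise * 1e-3))
    kern /= kern.sum()
    # cross-correlation aligned so the peak sits at the event onset:
    # mf[n] = sum_k resid[n+k] * kern[k]
    L = len(kern)
    mf = signal.fftconvolve(resid, kern[::-1], mode="full")[L - 1:L - 1 + len(resid)]

    # noise scale from the noisier portion of the recording: the 75th
    # percentile of per-chunk MADs.  A quiet post-block period then
    # neither lowers the threshold (which would flood the baseline with
    # detections) nor keeps firing on residual noise (which would mask
    # the drop in event rate that marks the block onset).
    chunk = max(1, int(round(2.0 / dt)))
    n_chunks = max(1, len(mf) // chunk)
    sig_c = np.empty(n_chunks)
    for i in range(n_chunks):
        seg = mf[i * chunk:(i + 1) * chunk]
        sig_c[i] = 1.4826 * np.median(np.abs(seg - np.median(seg)))
    sigma = float(np.quantile(sig_c, 0.75))
    if sigma < 1e-12:
        return np.array([]), np.array([])
    # prominence guards against noise riding on an event's decay tail
    # being counted as a second event
    peaks, _ = signal.find_peaks(
        -mf, height=k_mad * sigma, prominence=0.5 * k_mad * sigma,
        distance=max(1, int(round(min_separation / dt))),
    )
    if len(peaks) == 0:
        return np.array([]), np.array([])
    # the matched-filter peak marks the event onset; the amplitude is the
    # residual trough within the kernel's rise-to-peak span after onset
    t_peak_k = math.log(tau_decay / tau_rise) * tau_rise * tau_decay / (
        tau_decay - tau_rise) * 1e-3
    span = max(1, int(round((t_peak_k + 2e-3) / dt)))
    times = peaks * dt
    amps = np.empty(len(peaks))
    for i, p in enumerate(peaks):
        hi = min(len(resid), p + span + 1)
        amps[i] = -np.min(resid[p:hi])
    return times, amps


def detect_block_onset(
    event_times: np.ndarray,
    total_duration: float,
    epoch_start: Optional[float] = None,
    min_pre_duration: float = 60.0,
    min_pre_rate: float = 0.5,
    min_log_lr: float = 5.0,
) -> tuple[float, bool]:
    """Locate the GABA-A block onset from the disappearance of IPSCs.

    Maximum-likelihood single changepoint of a piecewise-constant
    Poisson rate, refined to the last event before the rate drop.
    Returns ``(t_onset, from_epoch)``; when the event record is too
    sparse or no significant rate drop exists, the annotated epoch start
    is returned with ``from_epoch=True``.
    """
    ev = np.sort(np.asarray(event_times, dtype=float))
    T = float(total_duration)

    def _fallback() -> tuple[float, bool]:
        if epoch_start is None:
            raise ValueError("no usable events and no annotated epoch to fall back on")
        return float(epoch_start), True

    if len(ev) < 10:
        return _fallback()
    pre_span = ev[-1] - ev[0]
    if pre_span < min_pre_duration or len(ev) / max(pre_span, 1e-9) < min_pre_rate:
        return _fallback()

    n = len(ev)
    # candidate changepoints just after each event
    cands = ev + 1e-9
    n1 = np.arange(1, n + 1)
    n2 = n - n1
    with np.errstate(divide="ignore", invalid="ignore"):
        ll = np.where(n1 > 0, n1 * np.log(n1 / cands), 0.0) + np.where(
            n2 > 0, n2 * np.log(n2 / np.maximum(T - cands, 1e-12)), 0.0
        )
    ll0 = n * math.log(n / T)
    best = int(np.nanargmax(ll))
    if not np.isfinite(ll[best]) or (ll[best] - ll0) < min_log_lr:
        return _fallback()
    rate_pre = n1[best] / cands[best]
    rate_post = n2[best] / max(T - cands[best], 1e-9)
    if rate_post >= rate_pre:
        return _fallback()
    return float(ev[best]), False


def remove_outliers(
    reduced: ReducedTrace,
    window: float = 5.0,
    k: float = 5.0,
    mad_window: float = 120.0,
    max_fraction: float = 0.2,
) -> tuple[ReducedTrace, int]:
    """Drop reduced points deviating from a rolling median by more than
    ``k`` times the rolling MAD (automated stand-in for manual
    inspection of large synaptic events).

    The deviation is measured against a short (``window``) rolling
    median so slow drifts are tracked; the MAD scale uses the longer
    ``mad_window`` so its own sampling noise does not inflate the
    exclusion rate.
    """
    if len(reduced.values) < 20:
        raise ValueError("reduced series too short for outlier screening")
    import pandas as pd

    n_roll = max(3, int(round(window / reduced.stride)) | 1)
    n_mad = max(n_roll, int(round(mad_window / reduced.stride)) | 1)
    s = pd.Series(reduced.values)
    med = s.rolling(n_roll, center=True, min_periods=1).median().to_numpy()
    dev = np.abs(reduced.values - med)
    mad = (
        pd.Series(dev).rolling(n_mad, center=True, min_periods=1).median().to_numpy()
    )
    keep = dev <= k * mad + 1e-15
    n_removed = int(np.sum(~keep))
    if n_removed > max_fraction * len(keep):
        warnings.warn(
            f"outlier screening removed {n_removed}/{len(keep)} points"
        )
    return (
        ReducedTrace(t=reduced.t[keep], values=reduced.values[keep],
                     win=reduced.win, stride=reduced.stride),
        n_removed,
    )


def _window_stats(reduced: ReducedTrace, t0: float, t1: float) -> tuple[float, float, int]:
    """(mean, |linear trend| in pA across the window, n points) of the
    reduced points whose averaging windows lie fully inside [t0, t1]."""
    half = reduced.win / 2.0
    m = (reduced.t - half >= t0 - 1e-9) & (reduced.t + half <= t1 + 1e-9)
    tt, vv = reduced.t[m], reduced.values[m]
    if len(vv) < 3:
        return float("nan"), float("inf"), len(vv)
    slope = np.polyfit(tt, vv, 1)[0]
    return float(np.mean(vv)), abs(slope) * (t1 - t0), len(vv)


def _block_steady_time(reduced: ReducedTrace, t_onset: float, search: float = 50.0,
                       settle_frac: float = 0.95) -> float:
    """Earliest time after onset when the reduced trace has covered
    ``settle_frac`` of its step to the post-block level; fallback
    onset + 10 s."""
    m_pre = (reduced.t >= t_onset - 5.0) & (reduced.t <= t_onset)
    m_tail = (reduced.t >= t_onset + search * 0.6) & (reduced.t <= t_onset + search + 20.0)
    if m_pre.sum() < 2 or m_tail.sum() < 2:
        return t_onset + 10.0
    x0 = float(np.median(reduced.values[m_pre]))
    A = float(np.median(reduced.values[m_tail]))
    if abs(A - x0) < 1e-12:
        return t_onset + 1.0
    m_post = reduced.t >= t_onset
    frac = (reduced.values[m_post] - x0) / (A - x0)
    settled = np.flatnonzero(frac >= settle_frac)
    if len(settled) == 0:
        return t_onset + 10.0
    return float(reduced.t[m_post][settled[0]])


def measure_tonic_shift(
    cleaned: ReducedTrace,
    t_onset: float,
    window: float = 20.0,
    search: float = 50.0,
    placement_step: float = 1.0,
) -> tuple[float, tuple[float, float], tuple[float, float]]:
    """Tonic current from 20-s mean windows on either side of the onset.

    The baseline window ends at or before the onset, the block window
    starts after the block has reached steady state; both lie within
    ``search`` seconds of the onset.  Among admissible placements the
    pair minimizing the summed within-window linear trend is chosen.
    Returns ``(I_tonic, baseline_window, block_window)`` where I_tonic =
    mean(block) - mean(baseline), positive when an inward tonic current
    is blocked.
    """
    t_min, t_max = cleaned.t[0] - cleaned.win, cleaned.t[-1] + cleaned.win
    base_starts = np.arange(
        max(t_min, t_onset - search), t_onset - window + 1e-9, placement_step
    )
    t_steady = _block_steady_time(cleaned, t_onset, search)
    blk_starts = np.arange(t_steady, min(t_onset + search, t_max - window) + 1e-9,
                           placement_step)
    if len(base_starts) == 0 or len(blk_starts) == 0:
        raise ValueError("insufficient cleaned data on one side of the onset")

    def _best(starts: np.ndarray) -> tuple[float, tuple[float, float]]:
        best = None
        for s in starts:
            mean, trend, npts = _window_stats(cleaned, s, s + window)
            if npts < window / cleaned.stride * 0.5:
                continue
            if best is None or trend < best[0]:
                best = (trend, mean, (float(s), float(s + window)))
        if best is None:
            raise ValueError("no admissible window placement with enough points")
        return best[1], best[2]

    base_mean, base_win = _best(base_starts)
    blk_mean, blk_win = _best(blk_starts)
    return blk_mean - base_mean, base_win, blk_win


def rms_shift(
    x_filtered: np.ndarray,
    dt: float,
    t_onset: float,
    window: float = 20.0,
    rms_win: float = 0.5,
    block_start: Optional[float] = None,
    exclude_epochs: Optional[Sequence[tuple[float, float]]] = None,
) -> tuple[float, float, float]:
    """RMS-noise change on block.

    The RMS is computed in ``rms_win``-long windows about each window's
    own mean; baseline and block values are the means of these RMS
    values over 20-s spans ending at the onset and starting at
    ``block_start`` (default onset + 10 s).  Windows overlapping
    ``exclude_epochs`` (e.g. capacitance tests) are skipped.  Returns
    ``(rms_baseline, rms_block, delta_rms)`` with delta = baseline -
    block (positive when channel noise disappears).
    """
    x = np.asarray(x_filtered, dtype=float)
    n_per = int(round(rms_win / dt))
    n_win = len(x) // n_per
    seg = x[: n_win * n_per].reshape(n_win, n_per)
    rms = seg.std(axis=1, ddof=0)
    t0s = np.arange(n_win) * rms_win
    valid = np.ones(n_win, dtype=bool)
    for e0, e1 in exclude_epochs or []:
        valid &= (t0s + rms_win <= e0) | (t0s >= e1)

    bs = block_start if block_start is not None else t_onset + 10.0
    m_base = valid & (t0s >= t_onset - window) & (t0s + rms_win <= t_onset)
    m_blk = valid & (t0s >= bs) & (t0s + rms_win <= bs + window)
    if m_base.sum() == 0 or m_blk.sum() == 0:
        raise ValueError("insufficient data for RMS windows on one side of onset")
    rb = float(np.mean(rms[m_base]))
    rk = float(np.mean(rms[m_blk]))
    return rb, rk, rb - rk


def capacitance_from_step(
    x: np.ndarray,
    dt: float,
    epoch: tuple[float, float],
    delta_v: float = -10.0,
    pre_window: float = 0.05,
    transient_window: float = 0.05,
) -> tuple[Optional[float], Optional[float]]:
    """Whole-cell capacitance and access resistance from one cap-test pulse.

    C = |integral of (I - I_steady) over the transient| / |dV| and
    R_a = |dV| / |I_peak - I_pre|.  Returns ``(C_pF, R_a_MOhm)``; both
    None when no transient is resolvable.
    """
    t0, t1 = epoch
    i0, i1 = int(round(t0 / dt)), int(round(t1 / dt))
    if i1 <= i0 or i1 > len(x):
        raise ValueError("cap-test epoch outside the trace")
    ip = max(0, i0 - int(round(pre_window / dt)))
    pre = float(np.mean(x[ip:i0])) if i0 > ip else float(x[max(i0 - 1, 0)])
    pulse = np.asarray(x[i0:i1], dtype=float)
    n_tail = max(1, int(0.3 * len(pulse)))
    i_steady = float(np.mean(pulse[-n_tail:]))
    dev = pulse - pre
    k_peak = int(np.argmax(np.abs(dev)))
    i_peak = float(dev[k_peak])
    noise = float(np.std(x[ip:i0])) if i0 - ip > 3 else 0.0
    if abs(i_peak) <= max(5.0 * noise, 1e-9):
        return None, None
    # integrate only over the transient portion so steady-state noise
    # does not accumulate into the charge estimate
    n_tr = min(len(pulse), max(2, int(round(transient_window / dt))))
    q = float(np.trapezoid(pulse[:n_tr] - i_steady, dx=dt))  # pA*s
    c_pf = abs(q) / abs(delta_v) * 1e3
    r_a = abs(delta_v) / abs(i_peak) * 1e3  # MOhm
    return c_pf, r_a


def qc_access_resistance(r_a_series: Sequence[float], threshold: float = 0.25) -> bool:
    """True when every access-resistance reading is within ``threshold``
    (fractional, strictly-greater fails) of the first reading."""
    rs = [r for r in r_a_series if r is not None and np.isfinite(r)]
    if len(rs) < 2:
        return True
    r0 = rs[0]
    return all(abs(r - r0) / r0 <= threshold + 1e-12 for r in rs)


def modulator_response(
    reduced: ReducedTrace,
    epoch: tuple[float, float],
    baseline_window: float = 20.0,
    wash_margin: float = 60.0,
) -> float:
    """Peak signed current deflection during a modulator epoch, relative
    to the pre-epoch baseline (negative = inward, i.e. potentiation of
    an inward tonic current)."""
    t0, t1 = epoch
    m_base = (reduced.t >= t0 - baseline_window) & (reduced.t <= t0)
    if m_base.sum() < 0.5 * baseline_window / reduced.stride:
        raise ValueError("need at least 20 s of pre-epoch baseline")
    base = float(np.mean(reduced.values[m_base]))
    m_epoch = (reduced.t >= t0) & (reduced.t <= t1 + wash_margin)
    if m_epoch.sum() == 0:
        raise ValueError("modulator epoch not covered by the reduced trace")
    dev = reduced.values[m_epoch] - base
    return float(dev[np.argmax(np.abs(dev))])


def analyze_vc_trace(
    sweep: Sweep,
    cell_id: str = "",
    k_mad_ipsc: float = 4.0,
    outlier_k: float = 5.0,
) -> TonicResult:
    """Full tonic-current analysis of one voltage-clamp trace.

    Filters, reduces, locates the block onset from IPSC disappearance
    (annotated ``bicuculline`` epoch as fallback), removes outliers,
    and measures the tonic shift, RMS change, capacitance series, QC
    flag and any modulator responses annotated on the sweep.
    """
    if sweep.signal_kind != "current":
        raise TypeError("tonic analysis requires a voltage-clamp current trace")
    res = TonicResult(cell_id=cell_id)
    dt = sweep.dt
    filt = bessel_lowpass(sweep.samples, dt)
    reduced = reduce_trace(filt, dt)
    cap_epochs = sweep.epoch_spans("cap_test")

    # capacitance / access resistance series
    c_list: list[float] = []
    r_list: list[float] = []
    for e in cap_epochs:
        c, r = capacitance_from_step(sweep.samples, dt, e)
        if c is not None:
            c_list.append(c)
            r_list.append(r)
    if c_list:
        res.C_vc = float(np.median(c_list))
    res.R_a_series = r_list
    res.qc_pass = qc_access_resistance(r_list)

    # mask cap-test pulses out of the reduced trace before cleaning
    keep = np.ones(len(reduced.t), dtype=bool)
    for e0, e1 in cap_epochs:
        keep &= (reduced.t + reduced.win / 2 <= e0) | (reduced.t - reduced.win / 2 >= e1 + 0.1)
    reduced = ReducedTrace(reduced.t[keep], reduced.values[keep],
                           reduced.win, reduced.stride)

    ev_times, _ = detect_ipscs(filt, dt, k_mad=k_mad_ipsc)
    # drop reduced points whose averaging window overlaps a detected
    # deflection (including its decay tail): the automated analogue of
    # cross-checking the reduced trace against the filtered original.
    # Masking is symmetric -- outward excursions are screened with the
    # same criterion -- so slow two-sided channel noise is thinned
    # without biasing the window means, while the strictly inward IPSCs
    # are removed together with their bias.
    pos_times, _ = detect_ipscs(-filt, dt, k_mad=k_mad_ipsc)
    mask_times = np.sort(np.concatenate([ev_times, pos_times]))
    if len(mask_times):
        half = reduced.win / 2
        starts = np.searchsorted(mask_times, reduced.t - half - 0.04)
        ends = np.searchsorted(mask_times, reduced.t + half + 0.015)
        keep = starts == ends
        reduced = ReducedTrace(reduced.t[keep], reduced.values[keep],
                               reduced.win, reduced.stride)
    bic = sweep.epoch_span("bicuculline")
    try:
        t_onset, from_epoch = detect_block_onset(
            ev_times, sweep.duration, epoch_start=bic[0] if bic else None
        )
    except ValueError:
        res.flags.append("no_block_onset")
        return res
    res.block_onset_time = t_onset
    res.onset_from_epoch = from_epoch
    if from_epoch:
        res.flags.append("onset_from_annotated_epoch")

    cleaned, n_out = remove_outliers(reduced, k=outlier_k)
    res.outliers_removed = n_out
    try:
        delta, bwin, kwin = measure_tonic_shift(cleaned, t_onset)
    except ValueError as exc:
        res.flags.append(f"tonic: {exc}")
        return res
    res.raw_delta = delta
    res.I_tonic = delta
    res.baseline_window = bwin
    res.block_window = kwin
    if res.C_vc:
        res.I_tonic_per_pF = res.I_tonic / res.C_vc

    try:
        rb, rk, dr = rms_shift(
            filt, dt, t_onset, block_start=kwin[0], exclude_epochs=cap_epochs
        )
        res.rms_baseline, res.rms_block, res.delta_rms = rb, rk, dr
    except ValueError as exc:
        res.flags.append(f"rms: {exc}")

    for drug in MODULATOR_DRUGS:
        if drug in ("gaba",):
            continue
        span = sweep.epoch_span(drug)
        if span is not None:
            try:
                res.modulator_responses[drug] = modulator_response(reduced, span)
            except ValueError as exc:
                res.flags.append(f"{drug}: {exc}")
    return res
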