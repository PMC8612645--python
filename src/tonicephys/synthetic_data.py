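"""Ground-truth-labeled synthetic patch-clamp recordings.

Every quantity the downstream analysis extracts is an explicit parameter
here, so parameter recovery can be tested without any recorded data.

Current clamp (IV families)
    Subthreshold dynamics are a passive RC membrane plus a single
    hyperpolarization-activated (H) conductance state relaxing with time
    constant ``tau_h`` toward a voltage-dependent target; this produces a
    controllable sag.  Action potentials are not solved for: they are
    inserted as stereotyped piecewise waveforms (slow ramp to threshold,
    fast linear rise to peak, half-width-matched linear decay, AHP
    undershoot with exponential recovery) at times drawn from a
    gamma-renewal process whose CV equals ``cv_isi``.  The k-th spike's
    peak amplitude is scaled by ``d**k`` to model amplitude accommodation.

Voltage clamp (tonic-current traces at -60 mV)
    The holding current is a sum of: ``N_chan`` two-state (closed/open)
    GABA-A channels simulated as an exact discrete-time Markov chain on
    the open count (per-step transition probabilities ``1-exp(-a*dt)``,
    ``1-exp(-b*dt)``); a Poisson IPSC train convolved with a
    difference-of-exponentials kernel; ideal RC capacitance-test
    transients through the access resistance at 5-min intervals; and
    white recording noise.  Bicuculline closes the opening pathway with
    wash-in time constant ``tau_wash``; positive modulators scale the
    opening rate.  With 65 mM pipette chloride the chloride reversal sits
    far above -60 mV, so the tonic GABA-A current is inward (negative)
    and full block shifts the holding current in the positive direction.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict, replace
from typing import Any, Optional, Sequence

import numpy as np
from numba import njit

from .trace_io import CellRecord, PatientMeta, Sweep

__all__ = [
    "ArchetypeParams",
    "VCChannelParams",
    "SynthTruth",
    "DEFAULT_ARCHETYPES",
    "default_step_protocol",
    "default_drug_schedule",
    "simulate_iv_recording",
    "simulate_vc_trace",
    "simulate_cohort",
    "CohortConfig",
]


# ---------------------------------------------------------------------------
# parameter containers
# ---------------------------------------------------------------------------

@dataclass
class ArchetypeParams:
    """Generative parameters of one firing archetype.

    Passive: C_m (pF), R_in_true (MOhm), E_L (mV).  Sag: g_h (nS), tau_h
    (ms), E_h (mV).  Spike template: V_thr_true, peak_true (mV),
    halfwidth_true (ms), AHP_true (mV, depth below threshold).
    ``d`` is the per-spike peak decay factor in (0, 1]; ``cv_isi`` the
    inter-spike-interval coefficient of variation; ``latency_frac`` the
    first-spike delay at rheobase as a fraction of the step duration.
    """

    name: str
    C_m: float = 80.0
    R_in_true: float = 200.0
    E_L: float = -60.0
    g_h: float = 0.0
    tau_h: float = 50.0
    E_h: float = -30.0
    rheobase_true: float = 100.0
    V_thr_true: float = -40.0
    peak_true: float = 25.0
    halfwidth_true: float = 1.0
    AHP_true: float = 12.0
    d: float = 0.95
    cv_isi: float = 0.05
    latency_frac: float = 0.03
    rate_base: float = 6.0      # firing rate at rheobase (Hz)
    f_gain: float = 0.15        # rate gain above rheobase (Hz/pA)
    sigma_v: float = 0.0        # recording noise SD (mV)

    def __post_init__(self) -> None:
        if not 0.0 < self.d <= 1.0:
            raise ValueError("d must be in (0, 1]")
        if self.cv_isi < 0:
            raise ValueError("cv_isi must be non-negative")
        if self.halfwidth_true <= 0:
            raise ValueError("halfwidth_true must be positive")


@dataclass
class VCChannelParams:
    """Parameters of the voltage-clamp holding-current generator.

    ``p_open`` is the stationary open probability ``alpha/(alpha+beta)``;
    ``alpha`` is derived from ``p_open`` and ``beta`` if not given.
    ``i_unit`` is the unitary current in pA (negative = inward).
    """

    N_chan: int = 500
    p_open: float = 0.02
    i_unit: float = -1.0
    beta: float = 10.0
    alpha: Optional[float] = None
    ipsc_rate: float = 2.0            # Hz
    ipsc_amp_mu: float = 3.4          # lognormal mu of amplitude (pA)
    ipsc_amp_sigma: float = 0.45
    tau_rise: float = 1.0             # ms
    tau_decay: float = 8.0            # ms
    sigma_rec: float = 2.0            # pA
    tau_wash: float = 8.0             # s
    R_a: float = 12.0                 # MOhm
    R_a_drift_sd: float = 0.0         # random-walk SD per cap test (MOhm)
    C_m: float = 80.0                 # pF, sets the cap-test transient
    I_hold: float = -25.0             # pA, leak/holding offset
    dt: float = 1e-4                  # s (10 kHz)
    cap_interval: float = 300.0       # s between cap-test pulses
    cap_pulse_dur: float = 0.25       # s
    cap_delta_v: float = -10.0        # mV
    modulator_alpha_factors: dict = field(
        default_factory=lambda: {
            "allopregnanolone": 1.65,
            "DS2": 1.45,
            "MRK-016": 0.90,
        }
    )

    def __post_init__(self) -> None:
        if self.N_chan < 0:
            raise ValueError("N_chan must be non-negative")
        if not 0.0 <= self.p_open <= 1.0:
            raise ValueError("p_open must be in [0, 1]")
        if self.tau_rise >= self.tau_decay:
            raise ValueError("tau_rise must be smaller than tau_decay")
        if self.alpha is None:
            # alpha/(alpha+beta) = p  =>  alpha = beta * p/(1-p)
            self.alpha = self.beta * self.p_open / max(1.0 - self.p_open, 1e-12)

    @property
    def tonic_mean(self) -> float:
        """Stationary mean channel current, N*p*i (pA, signed)."""
        return self.N_chan * self.p_open * self.i_unit

    @property
    def tonic_sd(self) -> float:
        """Stationary channel-noise SD, sqrt(N*p*(1-p))*|i| (pA, unfiltered)."""
        return math.sqrt(self.N_chan * self.p_open * (1.0 - self.p_open)) * abs(self.i_unit)


@dataclass
class SynthTruth:
    """Ground truth attached to a simulated cell."""

    archetype: str = ""
    true_tonic_shift: float = float("nan")   # pA, positive (shift on full block)
    true_rms_change: float = float("nan")    # pA, unfiltered channel-noise SD
    true_C: float = float("nan")             # pF
    true_R_in: float = float("nan")          # MOhm
    true_sag_ratio: float = float("nan")
    true_rheobase: float = float("nan")      # pA (smallest spiking protocol step)
    ap_params: dict = field(default_factory=dict)
    spike_times: dict = field(default_factory=dict)   # step current (pA str) -> [s]
    step_currents: list = field(default_factory=list)
    ipsc_times: list = field(default_factory=list)
    drug_schedule: list = field(default_factory=list)
    R_a_series: list = field(default_factory=list)
    extras: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return json.loads(json.dumps(asdict(self), default=_jsonable))

    @classmethod
    def from_dict(cls, d: dict) -> "SynthTruth":
        known = {f for f in cls.__dataclass_fields__}
        return cls(**{k: v for k, v in d.items() if k in known})


def _jsonable(x: Any):
    if isinstance(x, (np.floating, np.integer)):
        return x.item()
    if isinstance(x, np.ndarray):
        return x.tolist()
    raise TypeError(f"not JSON-serializable: {type(x)}")


# ---------------------------------------------------------------------------
# default archetype table
# ---------------------------------------------------------------------------

# Five qualitative phenotypes: 1 strong-sag/irregular with narrow large
# spikes and strong accommodation; 2 high-input-resistance irregular, no
# sag, broad small spikes; 3 late-spiking regular; 4 small-spike small-AHP
# regular; 5 regular with large narrow spikes and high input resistance.
DEFAULT_ARCHETYPES: tuple[ArchetypeParams, ...] = (
    ArchetypeParams(
        name="archetype1", C_m=90.0, R_in_true=250.0, g_h=20.0, tau_h=80.0,
        rheobase_true=120.0, V_thr_true=-41.0, peak_true=32.0,
        halfwidth_true=0.75, AHP_true=13.0, d=0.80, cv_isi=0.55,
        latency_frac=0.05,
    ),
    ArchetypeParams(
        name="archetype2", C_m=60.0, R_in_true=420.0, g_h=0.4, tau_h=60.0,
        rheobase_true=60.0, V_thr_true=-38.0, peak_true=12.0,
        halfwidth_true=1.45, AHP_true=10.0, d=0.82, cv_isi=0.50,
        latency_frac=0.05,
    ),
    ArchetypeParams(
        name="archetype3", C_m=110.0, R_in_true=240.0, g_h=0.6, tau_h=60.0,
        rheobase_true=100.0, V_thr_true=-37.0, peak_true=28.0,
        halfwidth_true=1.05, AHP_true=14.0, d=0.95, cv_isi=0.06,
        latency_frac=0.62,
    ),
    ArchetypeParams(
        name="archetype4", C_m=85.0, R_in_true=230.0, g_h=0.5, tau_h=60.0,
        rheobase_true=90.0, V_thr_true=-36.0, peak_true=10.0,
        halfwidth_true=1.25, AHP_true=6.0, d=0.93, cv_isi=0.08,
        latency_frac=0.06,
    ),
    ArchetypeParams(
        name="archetype5", C_m=70.0, R_in_true=380.0, g_h=0.5, tau_h=60.0,
        rheobase_true=70.0, V_thr_true=-42.0, peak_true=30.0,
        halfwidth_true=0.70, AHP_true=15.0, d=0.96, cv_isi=0.05,
        latency_frac=0.04,
    ),
)


# ---------------------------------------------------------------------------
# current-clamp simulation
# ---------------------------------------------------------------------------

IV_DT = 4e-5          # 25 kHz default sampling for simulated IV sweeps
IV_PRE = 0.2          # s before step onset
IV_STEP = 0.8         # s step duration
IV_POST = 0.25        # s after step offset

# H-current activation curve (fixed shape; g_h scales the effect)
H_VHALF = -75.0
H_SLOPE = 6.0

# accommodation floor: the k-th spike's amplitude scale is max(d**k, AMP_FLOOR),
# so long trains decay toward a plausible minimum rather than zero
AMP_FLOOR = 0.15


def default_step_protocol(arch: ArchetypeParams, step_pa: float = 20.0) -> list[float]:
    """Step currents from -100 pA below holding to rheobase + 100 pA."""
    top = step_pa * math.ceil((arch.rheobase_true + 100.0) / step_pa)
    n = int(round(top / step_pa)) + 5
    return [(-100.0 + k * step_pa) for k in range(n + 1)]


@njit(cache=True)
def _integrate_subthreshold(n, dt_ms, I_pa, C_m, R_in, E_L, g_h, tau_h, E_h,
                            v0, m0):  # pragma: no cover - numba
    """Forward-Euler integration of the RC + H-current subthreshold model.

    dV/dt = (1000*(E_L - V)/R_in + g_h*m*(E_h - V) + I) / C_m   [mV/ms]
    dm/dt = (m_inf(V) - m) / tau_h
    """
    V = np.empty(n)
    m = np.empty(n)
    v = v0
    mm = m0
    for i in range(n):
        V[i] = v
        m[i] = mm
        m_inf = 1.0 / (1.0 + math.exp((v - H_VHALF) / H_SLOPE))
        dv = (1000.0 * (E_L - v) / R_in + g_h * mm * (E_h - v) + I_pa[i]) / C_m
        dm = (m_inf - mm) / tau_h
        v = v + dt_ms * dv
        mm = mm + dt_ms * dm
    return V, m


def _resting_state(arch: ArchetypeParams, I: float = 0.0) -> tuple[float, float]:
    """Fixed point (V, m) of the subthreshold model at constant input I."""
    from scipy.optimize import brentq

    def f(v: float) -> float:
        m_inf = 1.0 / (1.0 + math.exp((v - H_VHALF) / H_SLOPE))
        return 1000.0 * (arch.E_L - v) / arch.R_in_true + arch.g_h * m_inf * (arch.E_h - v) + I

    v = brentq(f, -150.0, 0.0, xtol=1e-10)
    m = 1.0 / (1.0 + math.exp((v - H_VHALF) / H_SLOPE))
    return v, m


def _spike_template_times(arch: ArchetypeParams, I: float, step_dur: float,
                          rng: np.random.Generator) -> np.ndarray:
    """Spike times within the step (s from step onset), gamma renewal."""
    rate = arch.rate_base + arch.f_gain * max(I - arch.rheobase_true, 0.0)
    rate = min(rate, 45.0)
    lat0 = arch.latency_frac * step_dur
    latency = max(0.012, lat0 * math.exp(-(I - arch.rheobase_true) / 80.0))
    mean_isi = 1.0 / rate
    times = [latency]
    t = latency
    min_isi = 0.016
    while True:
        if arch.cv_isi <= 1e-9:
            isi = mean_isi
        else:
            shape = 1.0 / arch.cv_isi ** 2
            isi = rng.gamma(shape, mean_isi / shape)
        isi = max(isi, min_isi)
        t = t + isi
        if t >= step_dur - 0.006:
            break
        times.append(t)
    return np.array(times)


def _insert_spike(V: np.ndarray, dt: float, t_thr: float, arch: ArchetypeParams,
                  amp_scale: float, envelope: np.ndarray) -> None:
    """Overwrite V with one stereotyped spike whose threshold is at t_thr (s).

    Geometry (times in ms relative to the threshold crossing):
      * quadratic approach from the envelope to V_thr over t_pre (slope
        stays below any dV/dt detection threshold),
      * linear rise to the (scaled) peak over t_rise,
      * a short flat top of length t_plat (so the sampled maximum equals
        the true peak at any sampling rate),
      * linear decay back to V_thr over t_fall,
      * linear drop to the AHP trough over t_dip, a flat trough of
        length t_trough, then exponential recovery toward the envelope.
    Half-amplitude crossings sit on the linear flanks at t_rise/2 and
    t_rise + t_plat + t_fall/2; t_fall is chosen so their separation is
    ``halfwidth_true`` for every amplitude scale.
    """
    thr = arch.V_thr_true
    amp = (arch.peak_true - thr) * amp_scale
    hw = arch.halfwidth_true
    t_pre = 1.8
    t_plat = 0.12
    # rise time scales with amplitude so the upstroke slope (and hence
    # dV/dt-based detectability) is the same for accommodated spikes
    t_rise_full = min(0.4, hw - 2.0 * t_plat)
    t_rise = max(t_rise_full * amp_scale, 2.0 * dt * 1e3)
    t_fall = max(2.0 * hw - t_rise - 2.0 * t_plat, 2.0 * dt * 1e3)
    t_dip = 2.0
    t_trough = 0.3
    tau_rec = 18.0
    dt_ms = dt * 1e3
    t0_ms = t_thr * 1e3
    t_peak_end = t_rise + t_plat
    t_thr_again = t_peak_end + t_fall
    t_trough_start = t_thr_again + t_dip
    t_rec_start = t_trough_start + t_trough

    i_start = int(math.floor((t0_ms - t_pre) / dt_ms))
    i_end = min(len(V) - 1, int(math.ceil((t0_ms + t_rec_start + 6.0 * tau_rec) / dt_ms)))
    if i_start < 0:
        i_start = 0
    idx = np.arange(i_start, i_end + 1)
    t_rel = idx * dt_ms - t0_ms  # ms relative to threshold time
    v_new = V[idx].copy()
    env = envelope[idx]
    trough = thr - arch.AHP_true
    # ramp from the actual pre-spike voltage (which may still be
    # recovering from the previous AHP) so the trace stays continuous;
    # the quadratic keeps dV/dt below half the detection criterion
    v_start = float(v_new[0])

    eps = 1e-9
    t_rel = t_rel + eps  # guard float round-off at segment boundaries
    for j, tr in enumerate(t_rel):
        if -t_pre <= tr < 0.0:
            x = (tr + t_pre) / t_pre
            v_new[j] = v_start + (thr - v_start) * x * x
        elif 0.0 <= tr < t_rise:
            v_new[j] = thr + amp * tr / t_rise
        elif t_rise <= tr < t_peak_end:
            v_new[j] = thr + amp
        elif t_peak_end <= tr < t_thr_again:
            v_new[j] = thr + amp * (1.0 - (tr - t_peak_end) / t_fall)
        elif t_thr_again <= tr < t_trough_start:
            x = (tr - t_thr_again) / t_dip
            v_new[j] = thr - arch.AHP_true * x
        elif t_trough_start <= tr < t_rec_start:
            v_new[j] = trough
        elif tr >= t_rec_start:
            v_new[j] = env[j] + (trough - env[j]) * math.exp(
                -(tr - t_rec_start) / tau_rec
            )
    V[idx] = v_new


def simulate_iv_recording(
    arch: ArchetypeParams,
    protocol: Optional[Sequence[float]] = None,
    seed: int | np.random.Generator = 0,
    dt: float = IV_DT,
    cell_id: str = "",
) -> CellRecord:
    """Simulate a current-clamp IV family for one cell.

    ``protocol`` lists step currents in pA relative to the holding
    current (default: 20-pA increments spanning -100 pA to rheobase
    + 100 pA; 800-ms steps).  Returns a :class:`CellRecord` whose
    ``ground_truth`` records every inserted parameter.
    """
    if protocol is None:
        protocol = default_step_protocol(arch)
    protocol = list(protocol)
    if len(protocol) == 0:
        raise ValueError("protocol must contain at least one step")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed

    n_pre = int(round(IV_PRE / dt))
    n_step = int(round(IV_STEP / dt))
    n_post = int(round(IV_POST / dt))
    n = n_pre + n_step + n_post
    dt_ms = dt * 1e3

    v_rest, m_rest = _resting_state(arch)
    sweeps: list[Sweep] = []
    spike_times: dict[str, list[float]] = {}
    true_rheo = float("nan")

    for k, I in enumerate(protocol):
        I_arr = np.zeros(n)
        I_arr[n_pre:n_pre + n_step] = I
        suprathreshold = I >= arch.rheobase_true - 1e-9 and I > 0

        if suprathreshold:
            # interspike envelope: the passive trajectory rescaled so its
            # steady state sits between just above the AHP trough and just
            # below threshold -- a firing cell's membrane rides near
            # threshold between spikes, and the post-spike minimum must be
            # the AHP trough, not the envelope
            V_env, _ = _integrate_subthreshold(
                n, dt_ms, I_arr, arch.C_m, arch.R_in_true, arch.E_L,
                arch.g_h, arch.tau_h, arch.E_h, v_rest, m_rest,
            )
            ceiling = arch.V_thr_true - 3.0
            p_ss = float(np.mean(V_env[n_pre + n_step - 100:n_pre + n_step]))
            if abs(p_ss - v_rest) > 1e-9:
                scale = (ceiling - v_rest) / (p_ss - v_rest)
                V_env = v_rest + (V_env - v_rest) * scale
            V_env = np.minimum(V_env, ceiling)
            V = V_env.copy()
            st = _spike_template_times(arch, I, IV_STEP, rng)
            # snap threshold times to the sample grid so the waveform has
            # a sample exactly at threshold (makes recovery grid-exact)
            st = np.round((IV_PRE + st) / dt) * dt
            for j, t_s in enumerate(st):
                _insert_spike(V, dt, t_s, arch,
                              max(arch.d ** j, AMP_FLOOR), V_env)
            spike_times[f"{I:.1f}"] = [float(t) for t in st]
            if math.isnan(true_rheo):
                true_rheo = I
        else:
            V, _ = _integrate_subthreshold(
                n, dt_ms, I_arr, arch.C_m, arch.R_in_true, arch.E_L,
                arch.g_h, arch.tau_h, arch.E_h, v_rest, m_rest,
            )
            spike_times[f"{I:.1f}"] = []

        if arch.sigma_v > 0:
            V = V + rng.normal(0.0, arch.sigma_v, size=n)
        sweeps.append(
            Sweep(
                samples=V,
                stimulus=I_arr,
                dt=dt,
                signal_kind="voltage",
                epochs=[("step", IV_PRE, IV_PRE + IV_STEP)],
                sweep_id=f"iv_{k:03d}",
            )
        )

    truth = SynthTruth(
        archetype=arch.name,
        true_C=arch.C_m,
        true_R_in=_true_input_resistance(arch, protocol),
        true_sag_ratio=_true_sag_ratio(arch, min(protocol), dt),
        true_rheobase=true_rheo,
        ap_params={
            "V_thr": arch.V_thr_true,
            "V_peak": arch.peak_true,
            "amplitude": arch.peak_true - arch.V_thr_true,
            "halfwidth_ms": arch.halfwidth_true,
            "AHP": arch.AHP_true,
            "d": arch.d,
            "amp_floor": AMP_FLOOR,
            "cv_isi": arch.cv_isi,
            "latency_frac": arch.latency_frac,
        },
        spike_times=spike_times,
        step_currents=[float(I) for I in protocol],
        extras={"E_L": arch.E_L, "g_h": arch.g_h, "v_rest": v_rest},
    )
    return CellRecord(cell_id=cell_id or arch.name, iv_sweeps=sweeps, ground_truth=truth)


def _true_input_resistance(arch: ArchetypeParams, protocol: Sequence[float]) -> float:
    """Slope of steady-state dV vs dI over the protocol's first four
    hyperpolarizing steps, from the model's fixed points (not traces)."""
    v0, _ = _resting_state(arch, 0.0)
    steps = np.array(sorted(I for I in protocol if I < 0)[:4])
    if len(steps) < 2:
        return arch.R_in_true
    dv = np.array([_resting_state(arch, I)[0] - v0 for I in steps])
    slope = np.polyfit(steps, dv, 1)[0]  # mV/pA
    return float(slope * 1000.0)  # MOhm


def _true_sag_ratio(arch: ArchetypeParams, I_min: float, dt: float) -> float:
    """Sag ratio of the most hyperpolarizing sweep, from a noiseless run."""
    n_pre = int(round(IV_PRE / dt))
    n_step = int(round(IV_STEP / dt))
    n = n_pre + n_step
    I_arr = np.zeros(n)
    I_arr[n_pre:] = I_min
    v_rest, m_rest = _resting_state(arch)
    V, _ = _integrate_subthreshold(
        n, dt * 1e3, I_arr, arch.C_m, arch.R_in_true, arch.E_L,
        arch.g_h, arch.tau_h, arch.E_h, v_rest, m_rest,
    )
    base = float(np.mean(V[:n_pre]))
    trough = float(np.min(V[n_pre:]))
    n_ss = int(round(0.1 / dt))
    steady = float(np.mean(V[n - n_ss:n]))
    denom = base - steady
    if abs(denom) < 1e-12:
        return 1.0
    return (base - trough) / denom


# ---------------------------------------------------------------------------
# voltage-clamp simulation
# ---------------------------------------------------------------------------

@njit(cache=True)
def _channel_open_count(n_steps, N, n0, p_close, alpha_dt_base, mult, seed):  # pragma: no cover
    """Exact discrete-time open-count chain: per step, openings are
    Binomial(N - n, 1 - exp(-alpha*dt)) and closings Binomial(n, p_close)."""
    np.random.seed(seed)
    out = np.empty(n_steps, dtype=np.int32)
    n = n0
    for i in range(n_steps):
        a = alpha_dt_base * mult[i]
        p_open_step = 1.0 - math.exp(-a)
        opened = np.random.binomial(N - n, p_open_step) if n < N else 0
        closed = np.random.binomial(n, p_close) if n > 0 else 0
        n = n + opened - closed
        out[i] = n
    return out


def default_drug_schedule(
    baseline: float = 180.0,
    gaba: float = 180.0,
    block: float = 200.0,
    modulators: Sequence[str] = (),
    modulator_dur: float = 120.0,
) -> list[tuple[str, float, float]]:
    """Standard epoch schedule: baseline, then GABA + glutamate blockers,
    optional modulator applications, then bicuculline to steady block."""
    t = baseline
    sched = [("gaba", t, t + gaba)]
    t += gaba
    for drug in modulators:
        sched.append((drug, t, t + modulator_dur))
        t += modulator_dur + 60.0  # wash-out gap
    sched.append(("bicuculline", t, t + block))
    return sched


def _alpha_multiplier(t: np.ndarray, schedule: Sequence[tuple[str, float, float]],
                      vc: VCChannelParams) -> np.ndarray:
    """Per-sample multiplier on the channel opening rate from drug epochs."""
    mult = np.ones_like(t)
    tau = vc.tau_wash
    for label, t0, t1 in schedule:
        if label == "bicuculline":
            on = t >= t0
            mult[on] *= np.exp(-(t[on] - t0) / tau)
        elif label in vc.modulator_alpha_factors:
            f = vc.modulator_alpha_factors[label]
            on = (t >= t0) & (t < t1)
            mult[on] *= 1.0 + (f - 1.0) * (1.0 - np.exp(-(t[on] - t0) / tau))
            after = t >= t1
            washed = 1.0 + (f - 1.0) * (1.0 - math.exp(-(t1 - t0) / tau))
            mult[after] *= 1.0 + (washed - 1.0) * np.exp(-(t[after] - t1) / tau)
    return mult


def _validate_schedule(schedule: Sequence[tuple[str, float, float]]) -> None:
    drugs = [e for e in schedule if e[0] != "cap_test"]
    for (la, a0, a1), (lb, b0, b1) in zip(drugs, drugs[1:]):
        if b0 < a0:
            raise ValueError("drug schedule must be ordered by start time")
    # bicuculline abolishes everything downstream: a modulator epoch
    # overlapping the block is incompatible
    bic = [e for e in drugs if e[0] == "bicuculline"]
    if bic:
        t_bic = bic[0][1]
        for label, t0, t1 in drugs:
            if label not in ("bicuculline", "gaba") and t1 > t_bic:
                raise ValueError(
                    f"epoch {label!r} overlaps the bicuculline block"
                )


def _ipsc_kernel_scale(tau_rise_s: float, tau_decay_s: float) -> float:
    """Peak value of exp(-t/td) - exp(-t/tr), for unit-peak normalization."""
    tr, td = tau_rise_s, tau_decay_s
    t_peak = math.log(td / tr) * tr * td / (td - tr)
    return math.exp(-t_peak / td) - math.exp(-t_peak / tr)


def simulate_vc_trace(
    vc: VCChannelParams,
    schedule: Optional[Sequence[tuple[str, float, float]]] = None,
    seed: int | np.random.Generator = 0,
    duration: Optional[float] = None,
) -> tuple[Sweep, SynthTruth]:
    """Simulate a voltage-clamp holding-current trace with drug epochs.

    Returns the current trace (pA, inward negative) and the attached
    ground truth.  The epoch list is copied onto the sweep, with
    additional ``cap_test`` epochs marking the capacitance-test pulses.
    """
    if schedule is None:
        schedule = default_drug_schedule()
    schedule = [tuple(e) for e in schedule]
    _validate_schedule(schedule)
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed

    t_end = duration if duration is not None else max(e[2] for e in schedule) + 20.0
    dt = vc.dt
    n = int(round(t_end / dt))
    t = np.arange(n) * dt
    current = np.full(n, vc.I_hold, dtype=np.float64)

    # --- channel ensemble ---------------------------------------------
    if vc.N_chan > 0 and vc.p_open > 0:
        mult = _alpha_multiplier(t, schedule, vc)
        p_close = 1.0 - math.exp(-vc.beta * dt)
        n0 = int(rng.binomial(vc.N_chan, vc.p_open))
        chain_seed = int(rng.integers(0, 2**31 - 1))
        n_open = _channel_open_count(
            n, vc.N_chan, n0, p_close, vc.alpha * dt, mult, chain_seed
        )
        current += n_open * vc.i_unit

    # --- IPSC train ----------------------------------------------------
    bic = [e for e in schedule if e[0] == "bicuculline"]
    t_bic = bic[0][1] if bic else float("inf")
    ipsc_times: list[float] = []
    if vc.ipsc_rate > 0:
        n_cand = rng.poisson(vc.ipsc_rate * t_end)
        cand = np.sort(rng.uniform(0.0, t_end, size=n_cand))
        # bicuculline thins the synaptic events with the wash time constant
        keep = rng.uniform(size=n_cand) < np.where(
            cand < t_bic, 1.0, np.exp(-(cand - t_bic) / vc.tau_wash)
        )
        ipsc_times = cand[keep].tolist()
        if ipsc_times:
            from scipy.signal import lfilter

            amps = rng.lognormal(vc.ipsc_amp_mu, vc.ipsc_amp_sigma, size=len(ipsc_times))
            impulses = np.zeros(n)
            idx = np.minimum((np.asarray(ipsc_times) / dt).astype(int), n - 1)
            np.add.at(impulses, idx, amps)
            a_r = math.exp(-dt / (vc.tau_rise * 1e-3))
            a_d = math.exp(-dt / (vc.tau_decay * 1e-3))
            e_d = lfilter([1.0], [1.0, -a_d], impulses)
            e_r = lfilter([1.0], [1.0, -a_r], impulses)
            scale = _ipsc_kernel_scale(vc.tau_rise * 1e-3, vc.tau_decay * 1e-3)
            current += -(e_d - e_r) / scale

    # --- capacitance-test pulses --------------------------------------
    command = np.full(n, -60.0)
    cap_epochs: list[tuple[str, float, float]] = []
    r_a_series: list[float] = []
    r_a = vc.R_a
    t_pulse = vc.cap_interval
    while t_pulse + vc.cap_pulse_dur < t_end:
        if vc.R_a_drift_sd > 0:
            r_a = max(1.0, r_a + rng.normal(0.0, vc.R_a_drift_sd))
        r_a_series.append(r_a)
        tau = r_a * vc.C_m * 1e-6  # MOhm * pF -> s
        i0 = int(round(t_pulse / dt))
        i1 = min(n, int(round((t_pulse + vc.cap_pulse_dur) / dt)))
        seg_t = (np.arange(i0, i1) - i0) * dt
        peak = vc.cap_delta_v / r_a * 1e3  # mV/MOhm -> nA -> pA
        current[i0:i1] += peak * np.exp(-seg_t / tau)
        command[i0:i1] += vc.cap_delta_v
        # discharging transient at pulse offset
        i2 = min(n, i1 + (i1 - i0))
        seg_t2 = (np.arange(i1, i2) - i1) * dt
        current[i1:i2] += -peak * np.exp(-seg_t2 / tau)
        cap_epochs.append(("cap_test", t_pulse, t_pulse + vc.cap_pulse_dur))
        t_pulse += vc.cap_interval

    if vc.sigma_rec > 0:
        current += rng.normal(0.0, vc.sigma_rec, size=n)

    sweep = Sweep(
        samples=current,
        stimulus=command,
        dt=dt,
        signal_kind="current",
        epochs=list(schedule) + cap_epochs,
        sweep_id="vc",
    )
    truth = SynthTruth(
        true_tonic_shift=abs(vc.tonic_mean),
        true_rms_change=vc.tonic_sd,
        true_C=vc.C_m,
        ipsc_times=ipsc_times,
        drug_schedule=[list(e) for e in schedule],
        R_a_series=r_a_series,
        extras={
            "N_chan": vc.N_chan,
            "p_open": vc.p_open,
            "i_unit": vc.i_unit,
            "t_block_onset": t_bic if math.isfinite(t_bic) else None,
        },
    )
    return sweep, truth


# ---------------------------------------------------------------------------
# cohort simulation
# ---------------------------------------------------------------------------

@dataclass
class CohortConfig:
    """Knobs for cohort-level simulation.

    ``param_jitter`` is the multiplicative SD applied to continuous
    archetype parameters within an archetype.  ``tonic_base`` is the
    cohort-mean true tonic shift (pA); ``tonic_sd`` the cell-to-cell SD;
    ``archetype_tonic_effects`` adds a per-archetype offset, and
    ``age_tonic_slope`` a patient-age effect (pA/year, centred on the
    pool's mean age) -- both default to zero so that any configured
    effect is a deliberate experiment.
    """

    param_jitter: float = 0.07
    sigma_v: float = 0.0
    iv_dt: float = IV_DT
    simulate_iv: bool = True   # False: ground-truth-only records (no traces)
    tonic_base: float = 10.0
    tonic_sd: float = 5.0
    archetype_tonic_effects: dict = field(default_factory=dict)
    age_tonic_slope: float = 0.0
    simulate_vc: bool = False
    vc_params: VCChannelParams = field(default_factory=VCChannelParams)
    vc_schedule: Optional[list] = None   # default_drug_schedule() when None
    n_patients: int = 12


_JITTERED_FIELDS = (
    "C_m", "R_in_true", "g_h", "tau_h",
    "halfwidth_true", "AHP_true", "rate_base",
)

_ARCH_AXON = {
    "archetype1": ["rosehip", "L2-3"],
    "archetype2": ["L2-3", "other"],
    "archetype3": ["neurogliaform", "stalked"],
    "archetype4": ["other", "not_recovered"],
    "archetype5": ["neurogliaform", "stalked"],
}

_PATHOLOGIES = (
    "glioblastoma", "oligodendroglioma", "meningioma",
    "metastatic adenocarcinoma", "temporal lobe epilepsy",
)
_AREAS = {
    "temporal": "inferior temporal gyrus",
    "frontal": "superior frontal gyrus",
    "parietal": "inferior parietal lobule",
    "occipital": "superior occipital gyrus",
}


def _random_patient_pool(n: int, rng: np.random.Generator) -> list[PatientMeta]:
    pool = []
    for i in range(n):
        lobe = rng.choice(["temporal", "frontal", "parietal", "occipital"],
                          p=[0.5, 0.3, 0.1, 0.1])
        hemi = rng.choice(["left", "right"], p=[0.35, 0.65])
        pool.append(
            PatientMeta(
                patient_id=f"P{i + 1:02d}",
                age=float(np.clip(rng.normal(55.0, 9.0), 30.0, 80.0)),
                sex=str(rng.choice(["M", "F"])),
                pathology=str(rng.choice(_PATHOLOGIES, p=[0.55, 0.1, 0.1, 0.15, 0.1])),
                cortical_area=f"{hemi} {_AREAS[lobe]}",
                seizure_history=str(
                    rng.choice(["none", "more_than_1y_ago", "within_1y"], p=[0.6, 0.15, 0.25])
                ),
                dexamethasone=str(
                    rng.choice(["none", "at_surgery", "presurgery"], p=[0.4, 0.3, 0.3])
                ),
                levetiracetam=bool(rng.uniform() < 0.5),
                hemisphere=hemi,
                lobe=lobe,
            )
        )
    return pool


def _jitter_arch(arch: ArchetypeParams, jitter: float, sigma_v: float,
                 rng: np.random.Generator) -> ArchetypeParams:
    if jitter <= 0:
        return replace(arch, sigma_v=sigma_v)
    kwargs = {}
    for f in _JITTERED_FIELDS:
        v = getattr(arch, f)
        kwargs[f] = v * float(np.exp(rng.normal(0.0, jitter)))
    # rheobase spreads additively (SD comparable to the 20-pA protocol
    # step, as in real within-type variability) so the realized rheobase
    # is not quantization-locked to one protocol step per archetype
    kwargs["rheobase_true"] = max(20.0, arch.rheobase_true + rng.normal(0.0, 15.0))
    # keep spike voltages additive so thresholds stay plausible
    kwargs["V_thr_true"] = arch.V_thr_true + rng.normal(0.0, 1.2)
    kwargs["peak_true"] = arch.peak_true + rng.normal(0.0, 1.5)
    kwargs["d"] = float(np.clip(arch.d + rng.normal(0.0, 0.02), 0.05, 1.0))
    kwargs["cv_isi"] = max(0.0, arch.cv_isi * float(np.exp(rng.normal(0.0, jitter))))
    kwargs["latency_frac"] = float(np.clip(
        arch.latency_frac * np.exp(rng.normal(0.0, jitter)), 0.01, 0.85))
    kwargs["sigma_v"] = sigma_v
    return replace(arch, **kwargs)


def simulate_cohort(
    config: Optional[CohortConfig] = None,
    n_cells: int = 100,
    archetype_mixture: Optional[Sequence[float]] = None,
    patient_pool: Optional[Sequence[PatientMeta]] = None,
    seed: int = 0,
    archetypes: Sequence[ArchetypeParams] = DEFAULT_ARCHETYPES,
) -> tuple[list[CellRecord], list[PatientMeta]]:
    """Draw a labeled cohort of simulated cells.

    Cells are assigned archetypes by ``archetype_mixture`` (default
    equal proportions), given within-archetype parameter jitter, linked
    to patients from the pool, and given a true tonic shift composed of
    the configured base, archetype and age effects plus cell-level
    noise.  With ``config.simulate_vc`` a full voltage-clamp trace is
    generated per cell; otherwise only the tonic ground truth is set.
    """
    import warnings

    config = config or CohortConfig()
    mixture = np.asarray(
        archetype_mixture if archetype_mixture is not None
        else np.full(len(archetypes), 1.0 / len(archetypes))
    )
    if abs(mixture.sum() - 1.0) > 1e-8:
        raise ValueError("mixture proportions must sum to 1")
    if n_cells < int(np.count_nonzero(mixture)):
        warnings.warn("fewer cells than nonzero mixture components")

    rng = np.random.default_rng(seed)
    if patient_pool is None:
        patient_pool = _random_patient_pool(config.n_patients, rng)
    patients = list(patient_pool)
    mean_age = float(np.mean([p.age for p in patients]))

    # deterministic assignment honouring the mixture as closely as possible
    counts = np.floor(mixture * n_cells).astype(int)
    while counts.sum() < n_cells:
        counts[int(np.argmax(mixture * n_cells - counts))] += 1
    labels = np.repeat(np.arange(len(archetypes)), counts)
    rng.shuffle(labels)

    records: list[CellRecord] = []
    for i, lab in enumerate(labels):
        base_arch = archetypes[lab]
        arch = _jitter_arch(base_arch, config.param_jitter, config.sigma_v, rng)
        cell_seed = int(rng.integers(0, 2**31 - 1))
        if config.simulate_iv:
            rec = simulate_iv_recording(
                arch, seed=cell_seed, dt=config.iv_dt, cell_id=f"cell_{i:03d}"
            )
        else:
            rec = CellRecord(cell_id=f"cell_{i:03d}",
                             ground_truth=SynthTruth(archetype=base_arch.name))
        rec.ground_truth.archetype = base_arch.name
        patient = patients[int(rng.integers(0, len(patients)))]
        rec.patient_id = patient.patient_id
        rec.axonal_class = str(
            rng.choice(_ARCH_AXON.get(base_arch.name, ["other", "not_recovered"]))
        )

        shift = (
            config.tonic_base
            + config.archetype_tonic_effects.get(base_arch.name, 0.0)
            + config.age_tonic_slope * (patient.age - mean_age)
            + rng.normal(0.0, config.tonic_sd)
        )
        shift = max(shift, 0.01)
        rec.ground_truth.true_tonic_shift = float(shift)
        if config.simulate_vc:
            vc = config.vc_params
            denom = max(vc.p_open * abs(vc.i_unit), 1e-9)
            vc_cell = replace(vc, N_chan=max(0, int(round(shift / denom))))
            trace, vtruth = simulate_vc_trace(
                vc_cell, schedule=config.vc_schedule,
                seed=int(rng.integers(0, 2**31 - 1)),
            )
            rec.vc_trace = trace
            rec.ground_truth.true_tonic_shift = vtruth.true_tonic_shift
            rec.ground_truth.true_rms_change = vtruth.true_rms_change
            rec.ground_truth.ipsc_times = vtruth.ipsc_times
            rec.ground_truth.drug_schedule = vtruth.drug_schedule
            rec.ground_truth.R_a_series = vtruth.R_a_series
        records.append(rec)
    return records, patients
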