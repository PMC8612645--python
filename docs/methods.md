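# Methods

`tonicephys` analyzes whole-cell patch-clamp recordings from human
cortical layer-1 GABAergic interneurons: current-clamp IV families for
intrinsic-physiology phenotyping and firing-type clustering, and long
voltage-clamp holding-current recordings for quantifying tonic
GABA_A-receptor-mediated currents under timed drug applications. Because
no raw human recordings can be redistributed, the package ships a
synthetic-data generator whose every output quantity is an explicit
ground-truth parameter; the analysis chain is validated by parameter
recovery against that truth.

Units are fixed package-wide: seconds, millivolts, picoamps, megaohms,
picofarads. Times are measured from sweep start.

## Synthetic current-clamp recordings

Subthreshold dynamics are a passive RC membrane plus one
hyperpolarization-activated (H) conductance:

    C_m dV/dt = (E_L − V)/R_in + g_h·m·(E_h − V) + I_inj
    dm/dt     = (m_inf(V) − m)/tau_h,   m_inf(V) = 1/(1+exp((V−V_half)/k))

with V_half = −75 mV, k = 6 mV fixed; `g_h` and `tau_h` control the
depth and kinetics of the hyperpolarization sag. Integration is forward
Euler at the trace sampling rate (default 25 kHz; the linear fixed point
is exact under Euler, so Ohmic steady states are reproduced to
integration precision). True input resistance and sag ratio recorded in
the ground truth are computed from the model's fixed points
(`scipy.optimize.brentq`) and from a noiseless reference integration,
respectively — not from the returned trace.

Action potentials are not solved for. When a step reaches the cell's
rheobase parameter, spikes are *inserted* as stereotyped piecewise
waveforms at times drawn from a gamma-renewal process whose CV is the
archetype's `cv_isi` (CV 0 gives perfectly regular trains) and whose
rate is `rate_base + f_gain·(I − rheobase)`. The template consists of a
slow quadratic ramp to threshold (slope below the 20 mV/ms detection
criterion), a linear rise, a 0.12-ms flat top at the true peak, a linear
decay whose duration is chosen so the half-amplitude crossings are
exactly `halfwidth_true` apart, a linear drop to a flat AHP trough at
`V_thr − AHP_true`, and exponential recovery to the interspike envelope.
Threshold times are snapped to the sample grid and the rise time scales
with spike amplitude, so threshold, peak, half-width, AHP and per-spike
amplitudes are recoverable grid-exactly at any sampling rate — by
construction, which is the point of a generator used as a test oracle.
The k-th spike's amplitude is scaled by `max(d^k, 0.15)`; the 0.15 floor
keeps long accommodating trains detectable, as real trains do not decay
to zero. The interspike envelope is the passive trajectory rescaled to
approach `V_thr − 3 mV`, reflecting that a firing cell's membrane rides
near threshold between spikes (and guaranteeing the post-spike minimum
is the AHP trough).

Five default archetypes span the qualitative phenotypes seen among
layer-1 interneurons: (1) strong-sag (ratio ≈ 1.8), irregular, large
narrow spikes, strong accommodation — the rosehip-like phenotype; (2)
high input resistance, no sag, irregular, broad small spikes; (3)
late-spiking regular (first spike beyond half the step at rheobase); (4)
small-spike, small-AHP regular; (5) regular with large narrow spikes and
high input resistance. No quantitative parameter table exists for these
types, so values were calibrated once to plausible human-interneuron
ranges and are fully config-overridable.

Cohorts draw cells from a mixture of archetypes with within-archetype
log-normal jitter (SD 0.07) on continuous parameters. Rheobase jitters
*additively* with SD 15 pA: a spread comparable to the 20-pA protocol
step is both realistic and necessary — a much narrower spread locks the
realized (protocol-quantized) rheobase to a single step per archetype
and creates artificial bimodality in latency/rate features. Default
recording noise on IV sweeps is zero so parameter-recovery tests are
exact; noise is a config knob (`sigma_v`).

## Synthetic voltage-clamp recordings

The holding current at −60 mV is the sum of:

* **Channel ensemble.** `N_chan` identical two-state (closed/open)
  channels with opening rate α and closing rate β, stationary open
  probability p = α/(α+β), unitary current `i_unit` (negative = inward;
  with 65 mM pipette chloride the chloride reversal is far above
  −60 mV, so tonic GABA_A current is inward and its block shifts the
  holding current positive). The open count is simulated as an exact
  discrete-time Markov chain: per sample, openings ~ Binomial(N−n,
  1−e^{−α·dt}) and closings ~ Binomial(n, 1−e^{−β·dt}) (numba-compiled).
  Stationary mean and variance are N·p·i and N·p(1−p)·i²; the true
  tonic shift recorded in the ground truth is N·p·|i|.
* **IPSC train.** Poisson events (default 2 Hz) with log-normal
  amplitudes (median ≈ 30 pA), convolved with a unit-peak difference of
  exponentials (rise 1 ms, decay 8 ms), inward.
* **Capacitance-test pulses.** Ideal RC transients through the access
  resistance for a −10-mV step every 5 min (`I = ΔV/R_a·e^{−t/R_aC}`),
  annotated as epochs; R_a optionally drifts as a random walk to
  exercise the 25% QC rule.
* **White recording noise** (default 2 pA SD) and a constant holding
  offset.

Drugs act on the opening rate: bicuculline multiplies α by
`e^{−(t−t_on)/tau_wash}` (competitive block, default wash time constant
8 s) and thins the IPSC train identically; positive allosteric
modulators scale α by configured factors during their epochs with the
same wash kinetics. Default sampling is 10 kHz.

## Feature extraction

Conventions follow standard manual practice: spike detection by a
20 mV/ms dV/dt criterion with 1-ms merge window; threshold = voltage at
the criterion crossing; peak = local maximum; half-width = time between
upstroke and downstroke crossings of (threshold+peak)/2 (linear
interpolation between samples); AHP = threshold − post-spike minimum
before the next spike or step end, with missing downstrokes flagged
rather than fabricated. Input resistance is the least-squares slope of
steady-state voltage deflection (mean of the last 100 ms of the step)
against current over exactly the four most hyperpolarizing steps. The
sag ratio is (baseline − trough)/(baseline − steady) on the most
hyperpolarizing sweep, measured relative to the pre-step baseline — an
absolute-voltage trough/steady ratio would depend on the holding
potential and could not produce the conventional >1 range. Rheobase is
the smallest step current evoking at least one spike; the amplitude
accommodation ratio (first/last spike amplitude) is read from the
rheobase + 60 pA sweep; ISI statistics (sample SD, ddof = 1) are
reported only for sweeps with at least four spikes.

Thirteen per-cell feature datasets are built for clustering (resampled
subthreshold and sag/rebound trajectories, the first AP waveform and its
derivative, per-spike amplitude/half-width/threshold/AHP trajectories,
binned firing rate, fI curve, ISI-SD and latency profiles on a grid
relative to rheobase, and the steady-state IV relation). Cells that
cannot define an entry (e.g. no rheobase) contribute NaNs, imputed
dataset-wise by the cohort median with a per-dataset exclusion report.
The number of datasets, grid lengths and interpolation points are
configurable.

## Firing-type clustering

Each dataset matrix is z-scored column-wise and reduced by sparse PCA
(`penalty = 0` reduces exactly to ordinary PCA; for `penalty > 0`
explained variance is the adjusted variance from a QR decomposition of
the score matrix, the standard correction for non-orthogonal sparse
components). Components are retained to 95% cumulative explained
variance with a per-dataset cap (default 5). The concatenated scores
are clustered with Gaussian mixtures over K = 1…10 and covariance
structures {diagonal, full}, selecting the minimum of
BIC = −2 logL + k·log n, ties broken toward smaller K and the simpler
structure.

Two numerical choices matter here. First, EM uses k-means++
initialization with 5 restarts. Second, the covariance floor
(`reg_covar`) defaults to 1e-2, not sklearn's 1e-6: with ~30 score
dimensions and ~100 cells, an unconstrained full covariance whose
eigenvalues may shrink six orders of magnitude below the data scale can
"profit" from degenerate volume shrinkage and split heavy-tailed
clusters; a floor at the data scale removes that failure mode. On
default cohorts the selection is insensitive to this value across
[1e-3, 1e-1].

The rule-based Petilla-style classification labels a cell irregular if
its ISI CV at rheobase + 40 pA exceeds 0.35 (a convention separating the
generator's regular, CV ≤ 0.1, from irregular, CV ≥ 0.5, archetypes);
irregular cells with sag ratio > 1.6 form the high-sag (rosehip-like)
group; regular cells are late-spiking if the first spike at rheobase
arrives later than half the step. t-SNE embedding is provided for
visualization only.

## Tonic-current quantification

The measurement chain: (1) zero-phase 8-pole Bessel low-pass at 2 kHz
(forward–backward `sosfiltfilt`; the analog instrument filter it stands
in for was causal, but zero-phase filtering avoids biasing the block
onset time); (2) reduction to 10-ms window means every 100 ms; (3) IPSC
detection on the filtered trace by matched filtering with the
difference-of-exponentials template, thresholded at 4× a robust noise
scale — the 75th percentile of per-2-s-chunk MADs, anchored to the
noisier (pre-block) portion of the recording so the quiet post-block
period neither floods the baseline with detections nor hides the rate
drop; (4) block-onset localization as the maximum-likelihood single
changepoint of a piecewise-constant Poisson event rate, refined to the
last pre-silence event, falling back to the annotated drug epoch (with
a flag) when events are sparse or no significant drop exists; (5)
masking of reduced points whose averaging window overlaps a detected
deflection of either polarity — one-sided masking of inward events
alone measurably biases the baseline when slow channel noise is large —
plus a 5×MAD outlier screen against a 5-s rolling median (MAD taken
over 120 s for a stable scale); (6) the tonic current as the difference
of 20-s mean windows, baseline ending at or before the onset and block
window starting after the reduced trace has covered 95% of its step to
the post-block level (fallback onset + 10 s), both within 50 s of the
onset, at the placement pair minimizing the within-window linear trend.
The sign convention reports block of an inward current as positive; the
raw signed difference is stored alongside.

RMS noise is computed in 0.5-s windows about each window's own mean and
averaged over 20-s spans either side of the onset (capacitance-test
windows excluded). Note that subtracting each window's mean high-passes
the noise at ~1/T; for a two-state ensemble with correlation time
τ = 1/(α+β) the retained variance fraction is
g = 1 − (2τ/T)(1 − (τ/T)(1 − e^{−T/τ})), the closed form used as the
oracle in tests. Whole-cell capacitance is the charge of the
capacitance-test transient divided by the step (C = |∫(I−I_steady)dt|/
|ΔV|, integrated over a 50-ms transient window so steady-state noise
does not accumulate), and R_a = |ΔV|/|I_peak|. A recording fails QC
when any access-resistance reading drifts more than 25% (strictly
greater) from the first. Modulator responses are the signed extremum of
the reduced trace relative to the 20-s pre-epoch baseline, within the
epoch plus a 60-s wash margin.

## Statistics

Omnibus families: one-way ANOVA with Tukey HSD post hocs, Kruskal–
Wallis with Dunn's z-tests on mean ranks (tie-corrected,
Bonferroni-adjusted), Student and Welch t tests, and two-way ANOVA with
Type II sums of squares (appropriate for unbalanced designs). Constant
input returns statistic 0 and p = 1 rather than NaN; p-values are
floored at 1e-300.

The regression ledger fits ordinary least squares for thirteen model
specifications of increasing covariate sets — age and sex; firing-
cluster dummies (reference: cluster 5); axonal-class dummies
(reference: pooled other/not-recovered); pathology indicators; region
terms (hemisphere, lobe, cortical infiltration); and clinical terms
(seizures within the last year vs longer ago as mutually exclusive
dummies, dexamethasone presurgery vs at surgery, levetiracetam).
Reference categories are recorded in every ledger entry. Exactly
collinear columns are dropped iteratively with an explicit report,
never silently. Each entry stores coefficient ± SE and p per term,
residual df and SS, R², adjusted R², and the overall F test; tests
verify the R²/SS and F/(R², df) identities to 1e-10.

## Pipeline

`run_pipeline` executes simulate → features → cluster → tonic → stats,
with per-stage seeds spawned from one top-level seed via
`numpy.random.SeedSequence`, resumable stages, and a manifest (config
hash, versions, stage seeds). The CLI (`tonicephys`) exposes each stage
and the full run.

## Problem sizes and what the tests show

The standard validation cohort is 100 cells, all five archetypes in
equal proportion, default jitter. Feature-recovery checks use a 50-cell
zero-noise cohort. Tonic-estimator recovery uses 200 voltage-clamp
traces with true shifts uniform on [0, 42] pA under the default
channel/IPSC/noise model (each trace 250 s at 10 kHz: 120 s GABA
baseline, then bicuculline), plus 10 true-zero traces; the acceptance
script reports the same quantities from 60 + 10 traces. Type-I-error
calibration uses 1000 null cohorts per scalar omnibus family and 300
for the two-way ANOVA. The regression-ledger recovery uses a 200-cell
ground-truth cohort with a +10 pA archetype-1 effect (cell-level SD
5 pA).

Passing these tests shows the estimators are unbiased and accurate
*under the generator's assumptions*: stationary two-state channel
noise, Poisson IPSCs with a fixed kernel, ideal RC capacitance
transients, stereotyped spikes, and drug effects with first-order wash
kinetics. Real recordings add slow drifts, seal instability,
electrode-capacitance artifacts, correlated synaptic barrages,
non-stationary channel gating and manual-analysis judgment calls that
the generator does not emulate; results on real data should be read
with those limitations in mind. The sPCA penalty and the exact mixture
family of the original mclust-based analysis are unreported upstream,
so both remain configuration parameters here, and published cluster
memberships are not reproducible without the original recordings.
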