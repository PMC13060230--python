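# Methods

`photoglu` analyses paired recordings of hypothalamic AgRP-neuron population
activity (fiber photometry, calcium-dependent signal plus isosbestic
reference) and arterial glucose (1 Hz continuous monitoring) around an oral
gavage (OG) of water or glucose. The pipeline decomposes the neural response
into an anticipatory, dose-invariant *first phase* and a glucose-dynamics-
coupled *second phase*, and quantifies the temporal coupling between each
component and blood glucose (BG).

## Session model

A session is a 1 Hz grid spanning at least −25 to +90 min around the gavage
(t = 0), carrying `fp_signal`, `fp_reference` (arbitrary fluorescence
units) and `glucose` (mg/dL). Streams recorded on separate rigs are aligned
by linear interpolation onto integer seconds relative to the event;
alignment requires ≥ 115 min of shared support and never extrapolates.
Missing samples up to 5 s are bridged by linear interpolation with a logged
warning; longer gaps invalidate the session (at 1 Hz a 5 s bridge is
negligible against the 60 s smoothing that follows).

## Glucose processing

Cleaning: robust MAD despiking → centered median filter (7 samples) →
causal moving average (60 samples). The despike rule flags samples whose
deviation from a centered 7-sample rolling median exceeds `k·MAD` (k = 2)
of those deviations, then replaces them by linear interpolation between
unflagged neighbours. Deviations are measured from the *rolling* median
because a single whole-trace median would flag the entire post-gavage
excursion (~40% of samples at 2 g/kg) and flatten the very signal the
metrics measure; the rolling form removes impulsive sensor artifacts while
leaving slow physiology untouched, and gives the same answer on isolated
spikes. The causal moving average uses an expanding window during warm-up
so trace length is preserved; its group delay is (w−1)/2 ≈ 29.5 s, which
propagates into every timing metric (see Limitations).

ΔG(t) subtracts the mean over the −25 to 0 min baseline. The derivative is
the right-aligned 1 s forward difference, expressed per minute, smoothed
with the same 60-sample causal average.

Onset θ: y0(t) = cleaned trace minus the median over [−5, 0) min. The
*level* condition tests y0(t) > 3·σ̂y directly; the *slope* condition
smooths y0 with a 2-min causal boxcar, differences it, and tests
d > md + 3·σ̂d. Both scales are 1.4826·MAD over the pre-event segment
(floored at machine scale when degenerate, with a warning). θ is the first
sample of the first run of ≥ 60 consecutive post-event samples satisfying
either condition. The level condition is evaluated on the unsmoothed y0 so
that an abrupt level shift is timed at the sample where it occurs rather
than one boxcar-width later.

Excursion metrics: peak ΔG on [0, 90] min; peak derivative on [0, 30] min;
fall rate as the magnitude of the steepest post-peak decline; half-max
recovery as the first post-peak crossing of baseline + peak/2 with linear
interpolation; plateau as the first sustained interval where |dG/dt| stays
within ±10% of the peak rise rate (the band fraction is configurable; no
canonical value exists); return to baseline as the first ΔG ≤ 0 after the
peak, falling back to a sustained (≥ 60 s) positive-derivative relaxation.
iAUC is the trapezoidal integral of max(ΔG, 0) over [0, 90] min.

## Photometry processing

Order: (1) affine regression of the isosbestic reference onto the signal
channel, subtracting the fitted component (motion and bleaching are shared
between channels; neural activity is not); (2) the same
despike/median/causal-average cleaning as glucose; (3) a zero-phase
(forward–backward) Butterworth low-pass, order 3, cutoff period 4 min,
odd-reflection padding extended to 3× the filter time constant so edge
transients decay inside the padding; (4) z-scoring against the −25 to 0 min
baseline (mean 0, SD 1 there). The regression runs first because it must
see the artifacts it removes.

Scalar metrics: peak z on [0, 15] min; peak inhibition (minimum z) with its
time on [0, 10] min; negative AUC as the trapezoidal integral of min(Z, 0)
from the event to the time of peak BG; total AUC of the unmodified Z to the
session end.

Spectral onset: a Hann spectrogram of Z (20-min windows, 99% overlap, hop
12 s) is averaged over the band of periods 14–20 min. Band power at offsets
τ ∈ [−10, +10] min around the event is ranked against the same band power
around 200 pseudo-events drawn without replacement from the admissible
window-center grid (≥ 5 min from the true event, full window support);
p(τ) = (1 + #{null ≥ real}) / 201, and the onset is the first τ with
p < 0.05. Baseline aperiodic structure is summarised by the exponent k of
a 1/f^k fit: Welch PSD (8-min Hann segments, 50% overlap) regressed in
log–log space over periods 1–10 min, the range a 25-min baseline resolves;
k = −slope. Note that after the 4-min low-pass the measured k includes the
filter roll-off, so pipeline values are substantially larger than the
exponent of the underlying noise; comparisons are meaningful within, not
across, filter settings.

## Early-response (first-phase) template model

Training sessions are the 1.0/2.0/2.5 g/kg gavages; water and 0.5 g/kg are
held out. The window template is the pointwise across-session median of
training Z on [−25, +1] min (median for robustness to outlying sessions).
Each session is modelled as

    F̂ᵢ(t; τ) = β₀ + β₁ · F_train(t − τ),

with β by OLS and τ chosen on the grid −1 to +1 min in 0.25-min steps by
K-fold cross-validation (K = 5, folds grouped by subject when subject
counts allow): the template is rebuilt from K−1 folds, one pooled β is fit
on those folds, and validation MSE accumulates on the left-out fold; ties
break by higher validation R², then smaller |τ|. Template shifts use linear
interpolation.

Because the fit window ends at +1 min, predictions beyond it come from a
second template: the across-session median of the held-out low-dose
sessions over the full span, affine-calibrated to the window template on
their overlap. Low-dose sessions carry the same anticipatory component but
essentially no second phase, so their median extends the first-phase shape
through the post-event period. Per-session (β₀, β₁) are refit after lag
selection (so β₁ serves as a session-level baseline-state statistic);
prediction = β₀ + β₁·template_ext(t − τ*), residual = session − prediction,
and the decomposition is exact wherever the prediction is defined. A
`single_template` switch uses the low-dose template for fitting as well.

A caveat on lag selection: when every training session shares a common
temporal offset, the fold-rebuilt template inherits it and the CV correctly
returns τ = 0 — a common shift is unidentifiable from the cohort alone.
`select_lag_cv` therefore accepts an optional fixed external template,
which the lag-recovery tests use.

## Lagged coupling

Spearman correlation between a photometry-derived series (early-model
prediction, residual, or raw Z) and a glucose series (ΔG or its smoothed
derivative) at every lag in ±20 min; positive lag means the neural series
*follows* glucose. Rank correlations are recomputed on the exact
overlapping support at each lag. The analysis window defaults to the
post-event response period [0, 60] min — the same range over which
residuals are aggregated — because including the 25-min baseline and the
drifting 60–90 min tail dilutes the response coupling and biases the trough
location; the full session is available via `window_min=None`. Group curves
average per-session correlations in Fisher z space (tanh of the mean
atanh, values clipped at 1 − 10⁻⁶ with a warning). Nulls pair each neural
trace with circular shifts (≥ 20 min, uniform) of other sessions' glucose;
per-lag significance is a two-sided rank-sum test of observed vs null
correlations with Benjamini–Hochberg adjustment across the whole lag grid
as one family. The peak lag is the most negative group correlation
(couplings here are inhibitory), ties resolving to the smallest |lag| and
an exact ±|lag| tie to the negative (leading) lag.

## Cohort statistics

Paired comparisons use the Wilcoxon signed-rank test, unpaired the rank-sum
(Mann–Whitney U) test, both two-sided. The one-sample Student t-test also
accepts printed summary statistics (t = mean/SEM, n−1 df). Regressions are
OLS with subject indicator variables (the subject is the experimental
unit) and HC3 heteroskedasticity-consistent standard errors; HC3 is the
most conservative of the common sandwich flavours at these sample sizes.
The report builder runs the dose-response, early-invariance, residual, and
baseline-state comparison families; session-level p values are reported
unadjusted by default (BH is applied across lags within the coupling
analysis, and optionally within report families).

## Synthetic cohort generator

The generator targets the statistical structure the pipeline assumes, not
mechanistic physiology. Defaults define the study conditions: 6 subjects ×
doses {0, 0.5, 1, 2, 2.5} g/kg, each subject receiving every dose in
randomized order; identical (config, seed) reproduces the cohort
bit-for-bit.

Glucose: baseline 150 mg/dL (5-h-fasted mouse) plus a gamma-variate
excursion ((t/tp)^α·e^{α(1−t/tp)}) starting 3.6 min after gavage (SD 0.5 min
per-session jitter). The exponent α is solved so the shape's peak-fall to
peak-rise slope ratio equals fall_rate/rise_rate (defaults 2.0 and 6.0
mg/dL/min per g/kg), and tp so the realized peak rise rate is
rise_rate·dose; amplitude is 60 mg/dL per g/kg. Amplitude, rise and fall
rates all scale with dose while the time constants do not, so recovery time
is dose-invariant (peak ~120 mg/dL at 20 min, peak derivative at ~8.6 min,
half-max recovery ~40 min for 2 g/kg). White sensor noise (SD 2 mg/dL) and
sparse ±15 mg/dL single-sample spikes (2/h) are added.

Photometry, in z-units before conversion to raw fluorescence: an
anticipatory component starting 4 min before the event (smoothstep drop
over 6.4 min, so peak inhibition falls at +2.4 min; depth 2.5 z,
dose-invariant; exponential recovery, 25 min time constant; per-session
lognormal amplitude scale, SD 0.25, stored as ground truth); a second-phase
component −0.05 z per (mg/dL/min) of max(0, dG/dt), delayed 5 min (the gain
puts the residual trough near a quarter of the raw peak inhibition, and
keeps the raw peak inhibition time at ~+2.4 min at every dose); and
1/f-shaped noise (exponent 1, SD 0.3 z) generated by spectral shaping of
white noise. The raw signal adds exponential bleaching (5%/h of a 100 a.u.
baseline) and smoothed shared motion (SD 1 a.u.); the isosbestic reference
carries 0.8× the same drift+motion plus independent noise and no neural
component, making the artifact exactly removable by the affine regression
in the noise-free limit. All component traces and the per-session scale and
absorption delay are stored on the session for recovery tests.

What the generator does not emulate: insulin/gastric-emptying dynamics,
hemodynamic or pH artifacts with spectral overlap to the signal,
sensor-calibration drift, inter-subject differences in excursion shape, or
session-to-session learning of the anticipatory response. Passing tests
therefore demonstrate that the pipeline recovers the statistical structure
it assumes, not that the structure is present in any particular recording.

## Numerical choices and problem sizes

- Windows quoted in minutes convert exactly (1 min = 60 samples); baseline
  windows are half-open so the event sample is excluded.
- Robust scales use 1.4826·MAD; degenerate (zero) scales are floored at
  machine epsilon relative to the trace amplitude, with a warning.
- Acceptance-style checks run at sizes that keep the whole suite within a
  few minutes: coupling directionality uses 10 cohorts at the default size
  with 5-s lag steps; null-calibration of the spectral onset uses 100
  stationary records of 24 h, where the 200-draw pseudo-event ensemble is
  effectively independent; FDR calibration uses 25-min toy series, 15-s lag
  steps and 30 nulls per session.

## Known limitations

- Every causal filter delays timing metrics: the 60-sample moving average
  contributes ~29.5 s and the onset boxcar up to ~1 min; the detected BG
  onset runs ~1 min behind the true departure from baseline on the
  synthetic cohort. The standard configuration is kept as-is; users
  comparing onsets to external clocks should budget for this delay.
- The single affine isosbestic regression absorbs any covariance between
  the neural component and the drift into its slope, re-injecting a small
  drift-shaped leftover. At realistic noise this is negligible; in the
  noise-free limit it caps ground-truth recovery at r ≈ 0.95.
- On a single 115-min session the pseudo-event null for the spectral onset
  contains only ~5 effectively independent 20-min windows, making p(τ)
  anticonservative (P(p ≤ 0.05) ≈ 1/6) and the scan across ±10 min prone
  to false onsets on pure noise (~25–30%). A sustained post-event
  oscillation also contaminates its own null (the 5-min guard is smaller
  than the window half-width), so only transients localized relative to
  the 20-min window are reliably detectable. These are properties of the
  jittered-null design at session length, documented rather than patched.
- Rank correlations on heavily smoothed series have few effective degrees
  of freedom; per-session ρ magnitudes should be read against the
  pseudosession nulls, not nominal sample sizes.
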