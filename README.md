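# photoglu

Analysis pipeline for paired fiber-photometry and continuous arterial
glucose recordings around an oral glucose load. It is written for
physiologists who record hypothalamic AgRP-neuron population calcium
activity (signal + isosbestic channels) together with 1 Hz arterial
glucose in mice given water or glucose by oral gavage, and who want to
separate the *anticipatory* neural response from the component that
*tracks* the glycemic excursion.

## What it computes

Given sessions on a common event-anchored 1 Hz grid, the pipeline runs:

1. **Glucose metrics** — robust despiking, median + causal smoothing,
   baseline subtraction to ΔG(t), a sustained slope-or-level onset
   detector (thresholds `m_d + 3σ̂_d` and `3σ̂_y` from the pre-event
   baseline, held ≥ 1 min), peak ΔG and peak derivative, half-max
   recovery, plateau, return to baseline, and positive-only iAUC.
2. **Photometry metrics** — affine isosbestic regression, the same
   cleaning chain, zero-phase Butterworth low-pass (4-min cutoff),
   baseline z-scoring to Z_FP(t), peak z / peak inhibition, negative and
   total AUC, a spectral low-frequency onset tested against jittered
   pseudo-event nulls, and the baseline aperiodic 1/f^k exponent.
3. **Early-response model** — a first-phase template
   `F̂ᵢ(t; τ) = β₀ + β₁·F_train(t − τ)` fit on [−25, +1] min, with the lag
   τ* selected by inner K-fold cross-validation on high-dose sessions and
   full-span predictions extended from held-out low-dose sessions; the
   residual Rᵢ(t) = Fᵢ(t) − F̂ᵢ(t) isolates second-phase activity.
4. **Lagged coupling** — per-session Spearman ρ(λ) over ±20 min between
   neural and glucose series (positive λ = neural follows glucose),
   Fisher-z group aggregation, pseudosession nulls from circularly shifted
   glucose of other sessions, and Benjamini–Hochberg correction across
   lags.
5. **Cohort statistics** — Wilcoxon tests, one-sample t (also from printed
   summary statistics), and OLS with subject fixed effects and HC3 robust
   errors, assembled into dose-response / early-invariance / residual /
   baseline-state report tables.

A seeded synthetic-cohort generator (`photoglu.synthetic`) produces
sessions with the structure the analysis assumes — dose-scaled glucose
excursions with dose-invariant recovery, a dose-invariant anticipatory
inhibition beginning ~4 min before the event, a second-phase inhibition
lagging the glucose derivative by ~5 min, 1/f noise, bleaching, shared
motion and spikes — with every ground-truth component stored for recovery
tests. See `docs/methods.md` for the model details and limitations.

## Worked example

```python
import numpy as np
import photoglu as pg

cohort = pg.simulate_cohort(pg.SyntheticConfig(seed=1))       # 30 sessions
analysis = pg.analyze_cohort(cohort, rng=np.random.default_rng(1))

tab = analysis.table
glu = tab[tab.dose > 0]
print(f"BG rise onset      {glu.theta.mean():5.2f} min")
print(f"peak dG/dt time    {glu.peak_deriv_time.mean():5.2f} min")
print(f"FP spectral onset  {tab.lf_onset.mean():5.2f} min")
print(f"template lag tau*  {analysis.early.tau_star:+5.2f} min")

idx = [i for i, s in enumerate(cohort) if s.dose == 2.0]
res = pg.compute_coupling(
    [analysis.early.residuals[i] for i in idx],
    [analysis.glucose_traces[i]["deriv"] for i in idx],
    pg.CouplingConfig(lag_step=5.0), with_null=False, t=cohort[0].t,
)
print(f"residual vs dG/dt peak lag {res.peak_lag_s/60:+.1f} min")
```

prints (seed 1):

```
BG rise onset       4.68 min
peak dG/dt time     9.54 min
FP spectral onset  -4.22 min
template lag tau*  -0.25 min
residual vs dG/dt peak lag +6.0 min
```

Read: blood glucose starts rising ~4.7 min after gavage and climbs fastest
at ~9.5 min, while the neurons' low-frequency inhibition begins ~4 min
*before* gavage (the anticipatory first phase). After subtracting the
first-phase template, the residual inhibition follows the glucose rate of
change by ~6 min — the second phase tracks how fast glucose is changing,
not its level.

A command-line interface mirrors the stages
(`photoglu simulate | glucose-metrics | fp-metrics | early-model |
coupling | report`); run `photoglu --help`.

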