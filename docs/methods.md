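# Methods

## Waveform model

Each inflation–expiration cycle is a single-compartment linear lung driven
by the square pressure wave of a flow-driven T-piece resuscitator. The
airway pressure at the sensor approaches the delivered PIP with a 20 ms
time constant during inspiration and relaxes to the delivered PEEP with a
30 ms constant during expiration. Lung volume obeys

    dV/dt = (1 − f) · (P_aw − V/C) / R        (inspiration)
    dV/dt =           (P_aw − V/C) / R        (expiration)

integrated with the exact exponential step per sample (stable for any
compliance, including the near-zero compliance of a closed valve). `f` is
the per-breath mask-leak fraction: the sensor sits between T-piece and
mask, so of the inspiratory flow it measures, a fraction `f` escapes at the
mask seal; expiration is taken leak-free, consistent with using expired
volume as the tidal-volume estimate. Two consequences are built in rather
than incidental: in cyclic steady state the measured leak
`100·(V_insp − V_exp)/V_insp` equals `100·f` (parameter recovery), and
expired volume strictly decreases with `f` at fixed compliance, which is
what couples leak negatively to eV_T.

The fill resistance R = 0.30 mbar/(mL/s) (0.26 for newborns) is an
*effective* constant for the whole circuit–mask–airway path, deliberately
high enough that inflation is flow-limited at a 0.48 s inspiratory time:
with R·C comparable to the inspiratory time, eV_T is sensitive to leak and
sits in the 3–5 mL/kg range observed during T-piece ventilation at
PIP 30/PEEP 5, rather than saturating at C·ΔP.

Default sampling is 100 Hz (trapezoidal integration error well under 1%),
inflation rate 50/min with inspiratory fraction 0.4 — guideline-typical
values, both configurable. Pressures are in mbar (1 mbar = 1.02 cmH₂O,
exposed as `MBAR_TO_CMH2O`).

## Recipients

**Manikin.** Open-valve compliance 0.55 mL/mbar in the easy scenario (S1)
and 0.80 in the hard one (S4), whose valve starts closed and opens abruptly
after 15 adequate inflations (PIP ≥ 0.9 × set PIP — "adequate" is a design
choice, as is the threshold count). The closed valve multiplies compliance
by 0.3: strongly reduced volumes with a clear step at opening, but
deliberately *not* near zero — a near-zero closed valve is
waveform-indistinguishable from an upper-airway obstruction (low flow at
target PIP with a typical breath adjacent), which would make every
long-scenario sequence read as obstructed. A human reviewer separates the
two by context; a rule-based detector cannot. `simulate_breath` honours a
caller-supplied compliance ≈ 0 for the fully blocked case. The scenario
clock credits only adequate inflations and declares baby-cry at exactly
30 s (S1) / 90 s (S4) of credited PPV, so optimal ventilation succeeds at
the scripted constants and suboptimal ventilation (a configurable fraction
of deliberately inadequate inflations) takes longer. Heart rate rises
logistically from the scenario's initial value toward 160 bpm with the
count of effective inflations — only this qualitative behaviour is modelled,
the commercial manikin's data-derived algorithm being proprietary.

**Newborn.** Effective compliance ramps as
`floor + (1 − floor)(1 − e^(−k·b))` with the rate k chosen so 95% of the
plateau (0.70 mL/mbar) is reached by breath 20 — functional residual
capacity established over the first ~20 inflations — starting from
floor = 0.35 of plateau. Newborns additionally get: per-breath lognormal
compliance jitter (σ = 0.18 × jitter scale; the manikin's mechanical lung
has none), a 2.5× parameter jitter scale on delivered pressures, occasional
spontaneous-effort flow artefacts (2/min), at most one >5 s pause per
episode (probability 0.35, 6–12 s), and a gradual end transition: over the
final 4 inflations delivered PIP/PEEP fall by up to 30% while leak rises by
up to +0.3, emulating a loosened mask while the provider assesses
spontaneous breathing. The manikin's transition at success is abrupt.

**Leak.** Per-breath fraction `clip(mean + drift·b + N(0, sd), 0, 0.93)`;
manikin mean 0.40 (sd 0.12), newborn mean 0.48 (sd 0.18), drift
−0.0025/breath for both. The negative drift models successful
leak-reducing adjustments over time and is the mechanism behind the lower
median leak — and therefore higher median eV_T — of long sequences. Delivered
PIP jitter is capped at +0.5 mbar above the set value so that episode
pressure maxima stay within set PIP + 1 mbar; newborn PIP variability is
therefore mostly downward, which matches mask-ventilation reality
(pressures are lost, not gained, at a leaky mask).

**Study generator.** `simulate_study(n_providers=18, seed)` yields one S1
and one S4 manikin episode per provider (optimal quality, ±5% inflation-rate
jitter between providers) and, for each, a newborn episode whose ventilated
duration matches within ±4% — guaranteeing the ±15% pairing tolerance is
satisfiable. Four manikin and seven newborn episodes (capped at a third of
each arm at small scale) receive an injected obstruction: 3–5 consecutive
inflations with flow attenuated to 2% while pressure is untouched, placed
away from episode edges and from the S4 valve-opening phase. Everything is
driven by a `SeedSequence` tree, so identical (config, seed) gives
byte-identical output.

## Measurement pipeline

Inflation onsets are upward crossings of `baseline + 5 mbar` (baseline =
10th pressure percentile) with hysteresis at half the rise; window starts
back up 30 ms so fast early inspiratory flow is not lost, and windows are
capped at 1.5 median cycles so a pause is not absorbed into the preceding
breath's integrals. PIP is the window maximum; PEEP the median of the last
20% of the expiratory segment, flagged if no plateau was reached (the
commercial monitor's extraction rules are undocumented; these are this
package's definitions). Volumes are trapezoidal integrals of the positive
and negative flow (mL/min → mL/s). Leak is clamped to [0, 100]: negative
raw values (expired > inspired, possible with spontaneous efforts) are
clamped to 0 and flagged, the raw value kept in a diagnostic column; zero
inspired volume yields a flagged missing value. Breaths with missing leak
are excluded from leak summaries but keep their pressure/volume rows.

Pauses are onset-to-onset gaps whose excess over the median cycle time
exceeds 5 s; total PPV time is the ventilated span minus those excesses.
Obstruction windows are maximal runs of ≥3 consecutive breaths with
eV_T < 1 mL/kg (the "minimal volume" floor, a config key) *and*
PIP ≥ 0.9 × target, accepted only if an adjacent breath has eV_T ≥ half the
sequence median — low-volume runs where PIP also collapsed are failed
inflations, not obstruction.

## Statistics

*Panel comparison.* One-way random-effects model
`value_it = α + β·group_i + u_i + ε_it`, Swamy–Arora variance components
(within residuals for σ²_ε; the between regression, corrected for
`mean(1/T_i)`, for σ²_u), quasi-demeaning by
`θ_i = 1 − √(σ²_ε/(σ²_ε + T_i σ²_u))`, OLS on transformed data. The
contrast's variance is Newey–West with Bartlett weights `1 − j/(L+1)`,
accumulated within each subject's ordered series (no cross-subject
leakage), truncation `L = ⌊4(T̄/100)^{2/9}⌋`; p-values are two-sided t with
n_subjects − 2 df. Degenerate σ²_u falls back to pooled OLS with a warning.
The implementation is validated against statsmodels' White/HAC sandwich
estimators, a hand-computed 4-observation case, and Monte-Carlo size/power
checks: the null calibration uses random intercepts with iid within-subject
noise (the model's own null; 18 subjects/arm × 40 breaths, 500 replicates),
the power check AR(1) errors with a 5 mbar offset.

*LOESS.* Local linear fits with tricube weights over the nearest 50% of
pooled points, evaluated at integer breath indices observed in ≥5 subjects;
standard errors from the local weighted residual variance. Fitted values
match statsmodels' `lowess` at the same span to ~1e-8.

*Dynamical correlation.* Subjects' two curves are aligned on the breath
indices shared by all subjects (unequal lengths truncated to the common
grid), each curve centred by its time average and detrended against the
cross-subject mean curve, scaled to unit L2 norm; subject-level inner
products are averaged. Identical curves give +1, negated curves −1; the
estimate is invariant to per-subject offsets and a common positive
rescaling (per-subject *scales* interact with the mean-trend removal, so
exact invariance holds only for the common-scale case; mean-trend removal
can be disabled). Inference: subjects resampled with replacement (1000
draws), percentile 95% CI, p = twice the proportion of resamples with sign
opposite to the point estimate, floored at 1/n_boot. Groups smaller than 5
subjects get the point estimate without bootstrap.

*Other.* Median/IQR (Q3 − Q1) on pooled per-breath values per group;
pooled Pearson r reported for comparability despite autocorrelation bias;
obstruction compared by Pearson chi-square on the 2×2 table without
continuity correction (Yates by flag); an augmented Dickey–Fuller screen
per subject series is available as an advisory stationarity check that
gates nothing. No multiple-testing correction is applied.

## What the synthetic data does and does not show

The generator reproduces the *structure* the analysis assumes: square-wave
pressure delivery, leak-mediated volume loss, FRC establishment, valve-gated
compliance, duration-matched arms, and the qualitative group-level pattern
(greater newborn dispersion; higher eV_T and lower leak in long sequences;
strong negative leak–eV_T coupling; obstruction in a minority of sequences
in both arms). It does not emulate: real provider behaviour (PIP escalation
to 35 mbar in difficult episodes, stimulation breaks), CPAP after PPV,
capnography, true spontaneous-breath mechanics beyond flow artefacts, or
the commercial heart-rate algorithm. Passing tests therefore validate the
measurement and statistical machinery and the simulator's internal
consistency — not clinical equivalence to any specific recorded cohort, whose
exact medians and correlation magnitudes depend on behaviour the simulator
does not model.

## Problem sizes

Default test and reproduction scale is the full design (18 providers, 72
episodes, ~3700 inflations), which runs in seconds; Monte-Carlo
calibrations use 500 replicates of 36×40 panels and the bootstrap demos 99
to 1000 resamples. All sizes are configuration, not limits.
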