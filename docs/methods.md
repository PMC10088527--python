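# Methods

## The measurement model

Intermittent-flow respirometry alternates a *flush* phase (oxygenated water
pumped through the chamber, 1–4 min here) with a sealed *measure* phase
(4–8 min). During a sealed phase the percentage air saturation falls at a
rate proportional to total oxygen uptake; with the fish's uptake ṀO₂
(mg O₂ h⁻¹ kg⁻¹), body mass M (kg, taken equal to displaced volume in
litres), respirometer volume V_t (l), net volume V_n = V_t − M, solubility β
(mg O₂ l⁻¹ at 100% air saturation) and microbial background slope α_b
(% s⁻¹, from fish-free end-of-series runs over the full volume V_t), the
per-cycle estimate inverts to

    ṀO₂ = (|α_a|·V_n − |α_b|·V_t) · β/100 · 3600 / M.

β comes from the Benson–Krause unit-standard-atmosphere coefficients with
the standard salinity correction; it is monotone decreasing in temperature
and salinity (11.29 mg l⁻¹ at 10 °C/0 ppt, 9.14 at 10 °C/33 ppt). A
user-supplied constant β overrides the computed value anywhere a β argument
is exposed.

Quality control: the first 30–60 s of every sealed phase are excluded
(default 45 s, the midpoint of that range); slopes are ordinary least
squares and accepted only when R² > 0.90 — a strict inequality, so an exact
0.90 tie and an undefined R² (zero-variance window) are both rejected. The
audit invariant is that every scheduled cycle appears exactly once, either
accepted or rejected with a single reason code (`low_r2`,
`too_few_samples`, `straddles_chase`).

Background correction applies the end-of-series fish-free slope as a
constant to all cycles of that respirometer, matching the protocol in which
background is measured once after the animal is removed; a linear-ramp mode
(zero at start of run to the end value) exists but is off by default.

## Phenotype definitions and numerical choices

* **SMR** — mean of the lowest ⌈0.2·n⌉ accepted pre-chase samples after a
  one-pass mean ± 2 s.d. outlier screen *within that subset* (the screen's
  reference set is switchable to the full pre-chase window). The ceiling
  rounding guarantees at least one sample; the estimator is order-invariant
  and shift-equivariant.
* **MMR** — the single highest accepted post-chase sample; ties resolve to
  the earliest occurrence so that cardiac maxima align with the first
  physiological peak.
* **Activity smoothing** — scanning forward, a sample ≥ (1+5%) of the
  running value is replaced by the pre-spike value and held until a raw
  sample returns to ≤ (1+5%) of the held value. The rule is one-sided
  (upward spikes only), never increases any sample, and is idempotent. For
  coronary-ligated fish the first 2 h after the chase pass through
  unsmoothed: their early post-chase depression is physiology (AV block),
  not activity.
* **EPOC** — threshold SMR+10%; duration is the first time the smoothed
  series reaches the threshold, linearly interpolated between the
  straddling samples (cycle-resolution quantisation otherwise biases
  duration upward); magnitude is the trapezoidal integral of
  max(ṀO₂ − threshold, 0) from the chase to that time, with the first
  sample's value extended back to the chase instant (the first cycle starts
  minutes after the chase; without the anchor the head of the integral is
  systematically lost). "Reaching" the threshold is first-touch, not
  sustained. A fish that never reaches the threshold is flagged
  `recovered=False` and carries null EPOC fields — a valid outcome that
  propagates into per-group footnotes, never an error.
* **Cardiac summaries** — CO is the calibrated mean flow over the cycle
  window per kg; f_H = (n_beats − 1)/span × 60 from peak detection (minimum
  inter-peak distance half the period of the expected maximum rate, default
  120 beats min⁻¹; prominence 25% of window amplitude with a 0.5 ml min⁻¹
  absolute floor so flat traces yield no beats); SV = CO/f_H. Resting values
  average the cycles that defined SMR; maxima are read at the MMR cycle;
  scope = max − rest and may be negative (seawater fish have post-chase
  heart rates below resting). The peak-detection constants are this
  package's choices; the original acquisition software's internals are not
  documented.
* **Time course** — values are collected at 0, 10, 20, 30, 60, 120, 300,
  600 and 900 min post-chase, taking the temporally closest sample and
  recording its offset; targets with nothing within 30 min are null.

## Statistics

Two-way ANOVA (salinity × surgery) with interaction uses Type II sums of
squares — the cells are near-balanced but per-variable exclusions (anaemia,
non-recovery, missing cardiac windows) make exact balance unreliable, which
is also why every reported table carries per-variable n rather than a
study-wide n. On balanced designs the result equals the textbook
sums-of-squares decomposition (tested to 1e-9 relative). Significant main
effects are followed by simple main effects of that factor at each level of
the other, with the Bonferroni divisor equal to the number of levels tested.
Variance-stabilising transforms are registered per variable (log: resting
CO, SV scope; square root: maximum f_H; square: maximum SV) and applied
before ANOVA only. The time-course analysis delegates to a standard linear
mixed model (random intercept per fish) behind a thin wrapper; the
per-time-point Bonferroni simple effects are implemented natively.
Significance is p < 0.05, strict. Anaemic fish (Hct < 20, strict; exactly
20.0 retained) are excluded with a logged rule id.

Percent effects are 100·(reference − treatment)/reference rounded to the
nearest integer, and the cross-salinity comparison of ligation losses is
100·((a₁−a₂)/(b₁−b₂) − 1). Both are recomputed from the printed group means
stored in `respicard.reference` — the only quantitative anchor available,
since the raw recordings were never deposited.

## What the synthetic generator emulates

Each simulated fish gets a continuous ṀO₂ profile: pre-chase, SMR plus
intermittent routine-activity elevations (piecewise-constant multiplicative
bumps, 35% of 14-min steps elevated by 10–60%, aligned to the cycle grid so
each sealed window sees a constant rate); post-chase, single-exponential
decay from MMR toward an asymptote. The saturation trace integrates this
profile exactly within each sealed window (conservation holds by
construction), relaxes exponentially toward 100% during flushes, and adds
Gaussian optode noise (default 0.2% saturation). Flow traces are half-sine
ejections per beat, one beat stream integrated from the heart-rate profile,
each beat's discrete flow integral renormalised to its stroke volume so the
CO = f_H·SV contract holds exactly at the sampling rate (10 Hz). Coronary
ligation adds a second-degree AV block from 2 to 32 min post-chase: every
second beat is dropped (per-beat SV unchanged, so detected f_H and CO
halve), then the drop probability falls linearly to zero over 30 min. The
ṀO₂ profile dips correspondingly, scaling the *excess above the recovery
asymptote* by the same factor — maintenance metabolism continues through
the bradycardia, so an impairment dip cannot masquerade as EPOC recovery.

Default cell means reproduce the published group means (sham SMR cells,
which were not printed, are derived as MMR − aerobic scope); between-fish
CVs follow the printed s.e.m.·√n (8–15%). Recovery time constants are not
published; τ ~ U(2.4, 3.0) h (fresh) and U(2.0, 2.5) h (sea) put SMR+10%
recovery at roughly 8–12 h — inside the ≥15 h post-chase window — and yield
EPOC magnitudes near the printed salinity means. A configurable fraction of
fish (44% ligated, 6% sham, the published non-recovery rates) receive a
recovery asymptote of 1.25×SMR, above the SMR+10% threshold, and therefore
never recover. Body mass is drawn from 0.5–0.8 kg: realistic for 10 l
respirometers, large enough that the shallow resting slopes of low-SMR fish
still clear the R² gate with 10-min pre-chase measure phases, and small
enough that end-of-cycle saturation stays near the 80% floor even at MMR
with the short early post-chase cycles (1 min flush + 3 min measure for the
first 30 min, then 3 + 6 min; pre-chase 4 + 10 min).
Post-chase spontaneous-activity spikes are exposed as a parameter but off
by default, as their magnitude is not characterised.

**What the generator does not emulate** — and hence what passing tests do
not establish about real data: optode drift and temperature transients,
respirometer mixing heterogeneity, multi-exponential or activity-contaminated
recovery kinetics, beat-to-beat stroke-volume variability and dicrotic
waveform detail, probe nonlinearity, and any behavioural structure beyond
the bump/spike model. Parameter-recovery results certify the estimators
against the stated model, not against instrument pathology.

### Oracles and estimands

`TruthRecord` stores the generating parameters per fish. For MMR the honest
estimand under the highest-measured-cycle definition is the
maximum cycle-mean of the true profile under the fish's own schedule,
computed by dense quadrature at generation time (`mmr_observable`); for
ligated fish this differs from the envelope parameter because the AV-block
dip is part of the biology being measured. True EPOC and duration are dense
quadrature (1 s grid) of the same profile. Parameter-recovery checks on the
32-fish study at 0.2% noise find SMR within ~3%, MMR within ~2% and heart
rate within ~0.5% of truth; recovery flags can disagree with truth for
borderline fish whose true recovery time sits within estimation noise of
the 15 h window end.

### Replicated null studies

The type-I error of the simulate→analyse loop is measured on a reduced
design chosen so that 500 replicates fit in minutes: 6 fish per cell, 2.5 h
of pre-chase recording only (12 cycles of 2 + 10 min at 2 s sampling, no
flow traces, masses 0.5–0.7 kg so every fish clears the R² gate), all group
effects set to 1, pooling the p-values of the three factorial effects on
SMR. The observed rejection rate is ≈0.044.

## Known limitations

* The respirometry inversion assumes instantaneous mixing; real chambers
  have finite mixing times beyond the 30–60 s head exclusion.
* SMR's lowest-quantile estimator is mildly biased downward (≈1%) under
  noise, as order statistics select negative noise excursions.
* The mixed-model time-course wrapper fits a random intercept only; no
  autoregressive within-fish covariance or sphericity correction machinery
  is provided.
* ECG morphology is out of scope: AV block exists only as beat dropping in
  the flow trace, not as P/QRS waveform structure.
* EPOC is reported as a single magnitude; no fast/slow component
  partitioning, and no alternative SMR estimators (quantile regression,
  mixture models) are offered.
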