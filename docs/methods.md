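# Methods

This note documents the models implemented in `rabbitecg`, the defaults
and why they were chosen, what the synthetic-data generator does and does
not emulate, and the numerical conventions the code commits to.

## The measurement model

All stages operate on a per-beat record (`BeatSeries`: R time in seconds,
RR and QT in milliseconds, a beat label in {normal, ectopic, tdp}, and a
protocol phase label) or on a sampled single-lead waveform
(`EcgWaveform`: mV at a fixed rate, optionally with per-beat ground-truth
fiducial sample indices P, Q, R, S, T-end).  Sample indexing is 0-based,
times are seconds, intervals milliseconds, lipids mmol/L.

### Rabbit QTc

The rabbit heart-rate correction is linear and referenced to a 300 ms
cycle length:

    QTc = QT − 0.175·(RR − 300)     [ms]

`qtc_rabbit` exposes the slope and reference as parameters for other
models; the correction is affine in both arguments, and the generator uses
its exact inverse for QT/RR coupling, so generated QTc is stationary by
construction and round-trips to machine precision.  Report tables round
half-up to integer ms.

### Short-term variability (STV)

    STV = Σₙ |Dₙ₋₁ − Dₙ| / (N·√2),   D = per-beat QTc

The published description fixes "30 consecutive beats" with a denominator
of 30.  Those two readings conflict (31 beats give 30 differences); the
default here uses **31 beats → 30 differences** so the divisor equals the
number of summed terms, and `stv_strict30` provides the strict-30-beat
reading (29 differences, divisor still 30) for comparison.  The window is
the last one of the analyzed phase by default; a sliding-window mean is
available (`window="sliding"`).  STV satisfies STV(aD + b) = |a|·STV(D)
and is invariant under window reversal — both property-tested.

### R-peak detection

A derivative-threshold detector: the signal is smoothed with a short
zero-phase moving average (8 ms; odd window length to avoid a half-sample
shift), the first difference is thresholded at a fraction (default 0.4) of
its maximum magnitude, and each crossing is refined to the extremum of a
more heavily smoothed copy (16 ms) within a 40 ms search window, with a
120 ms refractory period.  The original description names the algorithm
but no parameters; these defaults suit rabbit rates of 100–200 bpm and are
all exposed in `DetectionConfig`.  The wider localization smoothing is
what keeps the R-time error within ±1 sample under realistic noise; at a
signal-to-noise ratio of 20 dB the detector recovers all beats of the
synthetic waveforms within ±2 ms (pooled F1 = 1.0 over 100 seeds in the
test suite).

### Ectopic-RR cleaning

Intervals deviating from the mean RR of the analyzed segment by more than
20% are flagged in a single pass (global mean, not a running mean, not
iterated — the simplest reading of the rule; threshold configurable) and
replaced by linear interpolation between the nearest retained neighbours;
flagged boundary values take the nearest retained value.  Cleaning is
applied only on the HRV path; interval tables use raw RR.  The generator
injects ectopic beats at 0.6× / compensatory 1.4× the phase-mean RR
(> 25% deviation), deliberately clear of the 20% boundary so generator
correctness and detector sensitivity are separately testable.

### QT measurement

With ground-truth fiducials (synthetic data) QT = (T_end − Q_onset)·1000/fs
and fiducials take precedence; TdP beats yield NaN rather than a
fabricated value.  In waveform mode, Q onset is the point before the R
upstroke where the smoothed derivative falls below 10% of the QRS slope,
and T end comes from the tangent method (maximum T downslope extrapolated
to the isoelectric baseline).  Tangent conventions carry a constant offset
relative to the template's nominal T end (about −28 ms for the rendered
Gaussian T wave, since the tangent of a Gaussian meets baseline 2σ past
the peak while the template defines T-end at 2.5σ); the tests therefore
check that waveform-mode QT is stable and tracks true QT changes 1:1
rather than matching the fiducial value absolutely.

### Lomb–Scargle HRV

The classical Lomb–Scargle periodogram is evaluated on the mean-centred RR
tachogram at the uneven beat times (the interval's end time is the
abscissa) — no resampling, which is the point of the estimator.  Grid:
0.005 Hz steps over [0.02, 0.5] Hz by default.  Two normalizations are
emitted: `"ms2_per_hz"` scales the raw periodogram by 2T/n so a sinusoidal
modulation of amplitude A integrates to ≈ A²/2 ms² when the grid resolves
the spectral peak (for short windows the 1/T peak width can be below the
grid step, so absolute band powers of narrowband modulations are
grid-resolution-limited — band *ratios*, which the analysis uses, are
not); `"variance"` is the classically normalized periodogram used for
cross-checks against the Schuster periodogram, with which Lomb–Scargle
coincides at Fourier frequencies of evenly sampled data.  Band powers are
trapezoidal integrals over closed intervals, so splitting [0.04, 0.40] at
0.15 is exactly additive.  LF/HF is NaN when HF is non-positive.  Analysis
uses the last 5 minutes of baseline (half-open window [end − 300 s, end)),
falling back to the full phase with a warning when it is shorter.

### Ordinal-pattern entropy

Embedded vectors of order m at delay τ are ranked with ties broken by
order of occurrence (stable sort: earlier sample ranks lower); the rank
permutation is Lehmer-encoded to an index in [0, m!).  **rePE** is the
Shannon entropy of the pattern counts.  **AAPE** weighs each vector by

    (A/m)·Σ|xₖ| + ((1−A)/(m−1))·Σ|xₖ − xₖ₋₁|

normalizes the weights over all vectors, and takes the entropy of the
resulting pattern distribution.  Defaults m = 4, τ = 1, A = 0.5, natural
log — A = 0.5 is the standard mixing default of the method, and the
parameters are all in `OrdinalConfig` because the decision threshold of
the quadrant rule is only meaningful for one parameterization.  AAPE is
invariant to positive rescaling (weights are ratio-normalized) but not to
general monotone transforms; rePE is invariant to monotone transforms and
equals AAPE exactly when every vector carries the same weight (e.g. ±c
alternation).  An all-zero series has zero total weight and is assigned
zero entropy (all mass on the tie pattern).  The implementation is
verified against a brute-force enumeration oracle to 1e−12 on hundreds of
random short series.

Waveform-level entropy is computed after FIR decimation to 250 Hz
(configurable) so the m-sample ordinal windows span morphological features
rather than sampling noise; segments shorter than 20 s raise a recorded
exclusion, mirroring how recordings without long artifact-free sections
are dropped from stratification.

### IEIN σ (reconstruction)

The information-exergy index is under-specified in its source material;
the concrete pipeline implemented (and versioned) here is:

1. sliding-window rePE trace (window 500 samples, hop 250, m = 3);
2. per block of 8 trace values, a trajectory (Hankel) matrix with
   embedding k = 4;
3. singular values per block;
4. energy shares pᵢ = sᵢ²/Σsⱼ² over the retained spectrum (99% cumulative
   energy, never fewer than two components — the spread beyond the leading
   direction is what carries the temporal-development signal);
5. block exergy = block energy × negentropy (log r + Σpᵢ log pᵢ);
6. σ = standard deviation of block exergy across the record.

Its contract — stationary-irregularity records score near zero, records
whose irregularity drifts score above the stationary 95th percentile — is
the tested surface, not bit-level identity with any prior implementation.
Consequently the published quadrant threshold of 670 for σ is shipped as a
named constant for reproducing the classification *rule*, but its numeric
scale is parameterization-dependent and is not validated against data.

### Event rules

Maximal runs of non-normal labels partition into: single ectopic → SEB;
runs of 2–4 → MEB; ≥ 5 consecutive `tdp` labels → TdP.  Singles separated
by exactly one normal beat chain into a bigeminy episode at ≥ 3
alternations (threshold unstated in the source; chosen and exposed),
subsuming those singles.  Degenerate cases the generator never produces
are still defined: ectopic runs > 4 split into consecutive MEBs (tail
adjusted 3+2), `tdp` salvos < 5 degrade to MEB/SEB.  Inducibility: ≥ 3
TdP episodes or one lasting **more than** 10 s (strict, per wording);
termination: the first episode persisting 20 s (non-strict) ends the
experiment at onset + 20 s, else the protocol end.  Outcome categories:
`tdp` iff inducible; `non_tdp` for any non-inducible animal with at least
one episode; `no_arrhythmia` otherwise.  SEB/MEB presence flags consider
only episodes before the first TdP onset ("prior to TdP").  In waveform
mode, TdP is operationalized as ≥ 5 detected complexes with RR < 0.6× the
record mean and alternating R polarity across the run, using a more
permissive crossing threshold (0.2) because polymorphic complexes are
shallower than normal R upstrokes; the original study classified TdP
manually, so this is a documented reconstruction with a label-mode bypass
for exact testing.

### Risk statistics

Sensitivity tp/(tp+fn) and specificity tn/(tn+fp) with NaN for undefined
denominators; the quadrant rule is strict (< threshold on both indices,
matching points clustering strictly inside the low-risk quadrant); the
two-sample proportion test is the pooled z without continuity correction
(the variant is unnamed in the source; Yates correction available by
flag); the Grubbs test uses the two-sided t-based critical value
((n−1)/√n · √(t²/(n−2+t²)), t at 1 − α/2n with n − 2 df), one outlier per
pass; Friedewald LDL = TC − HDL − TAG/2.2 warns on negative estimates.
Threshold calibration for the entropy rule picks the midpoint of the gap
between the highest low-risk and lowest at-risk training value (training
sensitivity 1 by construction).

## The synthetic-data generator

The generator emulates the study conditions, not rabbit physiology:

- **Protocol** — baseline 600 s, methoxamine 600 s, low-dose dofetilide
  1200 s, high-dose 1200 s; phases are piecewise-stationary (nothing
  quantitative is reported about reflex-bradycardia dynamics beyond phase
  means, so no within-phase trends are modelled).
- **Intervals** — per phase, RR is i.i.d. Gaussian at the published group
  mean/SD plus sinusoidal modulations ((0.10 Hz, 8 ms), (0.30 Hz, 6 ms) by
  default, emulating LF/HF variability); QT follows the inverse QTc
  coupling plus i.i.d. Gaussian QTc jitter whose SD is set from the
  published baseline STV (STV ≈ 0.798·σ for Gaussian jitter: 6.8/6.4/7.3
  ms for the three groups).  The profile's `qt_sd_ms` describes the
  published between-animal dispersion and is carried for table-shaped
  reporting; it does not add a second within-animal noise term, which
  would corrupt the mean/STV contracts.  Because the i.i.d. RR noise uses
  the full published SD (which in real data is largely slow, band-limited
  variability), the 20% cleaning rule flags more normal beats here than it
  would on real recordings; HRV-focused tests therefore use profiles with
  modest i.i.d. SD plus explicit modulations.
- **Ectopy** — per-phase Poisson event counts at the profile rates;
  default rates are calibrated so the expected fraction of animals with
  any arrhythmia matches the published 100%/64%/43% (young control always
  has events via its deterministic bigeminy stretch).  MEB run lengths are
  uniform on {2, 3, 4}.
- **TdP** — responder status is Bernoulli with the published
  inducibilities (0.83/0.18/0.21); responders get 3 episodes of 9 beats at
  0.45× phase-mean RR (±15% uniform irregularity) in the high-dose phase,
  satisfying the ≥3-episode inducibility rule.
- **Waveforms** — Gaussian-wave PQRST templates anchored to the R time,
  T placement tied to the series QT; TdP complexes are wide monophasic
  waves with sinusoidally modulated amplitude and strictly alternating
  polarity (sufficient for detector testing, not physiologic simulation).
  Default rate 1000 Hz (a ~70 ms rabbit QRS needs fine resolution);
  cohort runs render the first 60 s of baseline, which is what the
  entropy stage consumes.
- **Baseline irregularity of prone animals** — arrhythmia-prone animals
  (responders or animals with any injected ectopy) carry multiplicative
  sample-wise amplitude jitter (default 10%) in their rendered baseline.
  Sample-wise modulation, rather than a per-beat scale factor, is the
  deliberate choice: scaling identical beat templates leaves the AAPE
  weight distribution exactly unchanged (weights are linear in a per-beat
  scale), whereas sample-wise amplitude noise produces the subtle
  waveform irregularity the entropy stage is designed to detect.
- **Determinism** — one integer seed; per-animal substreams via
  `SeedSequence([seed, group, animal, stage])`, so cohorts are exactly
  reproducible and writing a cohort twice is byte-identical.

What passing tests on this generator show: the analysis stages implement
their stated rules exactly, recover known ground truth through the full
waveform→beats→metrics chain, and discriminate the constructed
irregularity classes.  What they do not show: performance on real rabbit
ECG, whose noise, artifacts, morphology variants (e.g. AV block) and
correlated variability the generator does not model.

## Problem sizes

Defaults for the full pipeline are the study design (37 animals, 60 min
protocol, 1 kHz rendering of 60 s baseline).  The test suite and examples
run the same code on scaled-down cohorts (2–10 animals per group, phases
of tens to hundreds of seconds, 500 Hz rendering) — sizes chosen so the
whole suite completes in well under a minute while every statistical
assertion retains comfortable margins (e.g. detection F1 pooled over 100
short records; entropy separation tested on 20-animal training and
held-out cohorts; proportion-test power over 100 simulated cohorts).

## Known limitations

- Waveform-mode QT carries a tangent-convention offset (documented above);
  fiducial mode is authoritative on synthetic data.
- IEIN σ is a reconstruction; only its qualitative contract is validated,
  and the 670 threshold scale is not transferable.
- The quadrant thresholds (1.975, 670) are parameterization-dependent
  constants for reproducing the published rule, not calibrated decision
  boundaries for new data.
- WFDB records are not read; all I/O is plain CSV/JSON.
- No AV-block detection, no multi-lead support, no P-wave/PQ/QRS-duration
  analytics beyond the fiducial mechanism, no pharmacokinetics.
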