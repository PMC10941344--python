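# Methods

`hralab` analyses beat-to-beat RR-interval (tachogram) series recorded
under three consecutive conditions — supine rest, sympathetic stimulation
by isometric handgrip, and post-stimulation recovery — and asks how heart
rate dynamics and asymmetry change across them. The recordings of
interest are short (5–6 min) and deliberately non-stationary: the
methods here (symbolic dynamics, Poincaré-based asymmetry, run
statistics) are chosen because, unlike spectral analysis, they remain
interpretable on such data. This note describes the models, conventions
and parameter choices; the package never states a result its own tests
or the acceptance script do not compute.

## Data model and units

RR intervals are stored in milliseconds as positive floats; beat onset
times are derived in seconds with the first beat at t = 0, so a beat's
onset is the cumulative sum of the preceding intervals. A series of N
beats yields N−1 Poincaré pairs and N−2 overlapping 3-symbol words.
Interchange is plain text (one interval per line, `#` comments, or a
`rr_ms[,label]` CSV); floats are written with `repr` so write→read is
bit-exact.

## Artifact screening and correction

Detection uses two conservative rules with configurable thresholds: a
physiological range gate (default 300–2000 ms) and a deviation gate
against a centred running median (window 11 beats, default relative
deviation 0.30). Full artifact taxonomies used by ECG platforms depend
on device-specific criteria that are not portable; the two-rule detector
is standard practice and pluggable. Only `normal` beats can be flagged,
so detection is idempotent.

Correction interpolates each flagged beat on the beat-index axis from
the surrounding normal beats: a cubic spline when at least 4 normal
beats flank the gap on *each* side, otherwise linear between the nearest
normal neighbours. Requiring two-sided support for the cubic path keeps
the interpolant local and reproduces the intuitive midpoint answer for
an isolated artifact between equal flanks. Recordings with more than 5%
flagged beats (configurable) are rejected rather than repaired,
mirroring the clinical practice of excluding rhythm-compromised
recordings.

## Stationarity screening

Each full recording is screened with the Augmented Dickey–Fuller
unit-root test (constant-only regression; lag order by AIC up to the
Schwert bound ⌊12·(N/100)^¼⌋; α = 0.05). Constant-only regression is
used because the series are short and are intentionally *not*
detrended — trends carry the physiological response. The flag is
attached to every result row as metadata and never gates analysis.
Note the decision-theoretic limit: on a pure random walk the test's
false-stationary rate equals its size (~5%), so discrimination can never
exceed ~95% on unit-root inputs.

## Time-domain metrics

mRR, HR (60000/mRR), HRmin/HRmax, SDNN, RMSSD, lnRMSSD and pNN50.
Conventions, stated because HRV software differs: SDNN uses the sample
form (N−1); RMSSD divides by the number of successive differences
(N−1); pNN50 counts |ΔRR| strictly greater than 50 ms; HRmin/HRmax
default to instantaneous per-beat HR (a configurable moving-average
window is provided but off by default, as the averaging used by
commercial software is rarely documented).

## Symbolic dynamics

Three quantizations produce integer symbols:

- **σ method** (default a = 0.05): three levels split at (1−a)·μ and
  (1+a)·μ with inclusive band edges. The level count follows the stated
  three-level scheme; because some descriptions also treat μ as a
  boundary, a four-level variant (middle band split at μ) is available
  behind `four_level=True` rather than silently chosen.
- **Max–min** (default ξ = 6): uniform bins over [min, max], half-open
  lower-inclusive, maximum assigned to the top bin; constant series map
  to symbol 0.
- **Equal probability** (q = 4 and 6): rank-based bins with occupancies
  differing by at most one; ties broken by original position (stable),
  making output deterministic.

Overlapping words of three symbols are classified by the two successive
differences: 0V (both zero), 1V (exactly one zero), 2LV (same sign),
2UV (opposite signs). Rates are percentages of the N−2 words and sum to
100 by construction. 0V tracks sympathetic and 2UV vagal modulation;
all four families are computed, with 0V/2UV the headline outputs.

## Poincaré asymmetry

For pairs (RR_i, RR_{i+1}), decelerations lie above the identity line
(RR_{i+1} > RR_i), accelerations below, neutral on it. With
d_i = (RR_{i+1}−RR_i)/√2 and e_i = (RR_i+RR_{i+1}−2m)/√2, second moments
over the n pairs give SD1² and SD2², partitioned by pair kind;
neutral pairs contribute zero to the SD1 partition (they sit on the
line) and are shared half/half between the SD2 partitions so that
additivity (SD1d²+SD1a² = SD1², SD2d²+SD2a² = SD2²) is exact to machine
precision. Contribution indices C1d/C1a, C2d/C2a, Cd/Ca are the
normalized partitions; Guzik's index GI = C1d (reported as a fraction,
matching the scale on which C-indices are tabulated in the field);
Porta's index PI = percentage of below-identity points among off-line
points. HRA is "present" when C1d > C1a and C2a > C2d. Because the
partitions are plain second moments rather than ellipse fits, SD1/SD2
may differ marginally from ellipse-fitting software; the additivity
identities are the design priority. Time reversal provably maps
GI → 1−GI, PI → 100−PI and swaps the run tables, and the tests enforce
these dualities.

On a PI subtlety: since below-identity points are accelerations,
PI < 50% means accelerations are *less* numerous than decelerations.
Prose in parts of the literature inverts this reading; the
implementation follows the definition.

Monotonic runs are maximal blocks of consecutive same-kind pairs,
counted by kind (DR/AR/NR) and length. All lengths are retained; the
tabular report truncates at length 5 without folding longer runs into
the last bucket. The length-weighted counts sum to N−1.

## Windowing

Short-term metrics use a 5-min window from each 6-min recording;
the default is the final five minutes, discarding the first minute as a
settling period consistent with the rest-stabilization protocol (the
start is configurable). Ultra-short-term metrics use named 1-min
windows: minute 5 of rest, minute 5 of stimulation, minutes 1–3 of
recovery. Membership is by beat onset time in half-open
[start, start+length), so consecutive windows partition the beats.

## Cohort statistics

Per metric, the n×3 subject-by-condition matrix is tested with
Friedman's ANOVA by ranks (mid-rank ties, standard tie correction,
chi-square approximation with k−1 df — the approximation matches common
statistical software even at n = 9), followed by Dunn's pairwise
rank-mean z-tests with Bonferroni adjustment over the 3 pairs, all
two-sided at α = 0.05. For k = 3 tie-free blocks an exact permutation
p-value is available (`friedman_test(..., method="exact")`), computed by
dynamic programming over column rank sums; the chi-square route remains
the default because it is what the field's software reports. Associations between condition deltas
(stimulation−rest, recovery−stimulation) and respiratory-rate deltas,
HR deltas and career duration use Spearman's rank correlation with the
two-sided t approximation. No multiplicity control is applied across
metrics in the delta-correlation table. Monte-Carlo calibration at
n = 9, k = 3 puts the Friedman type-I error at ≈0.058 and the Dunn
family-wise error at ≈0.032 (10,000 null replicates), both within the
accepted band around the nominal 0.05.

## Synthetic generator

The generator is a beat-domain additive model, a deliberate stand-in
rather than a physiological (e.g. integral-pulse-frequency-modulation)
cardiac model:

RR_i = m + trend·t_i + A_resp·s_κ(2π f_resp t_i) + A_lf·sin(2π f_lf t_i + φ) + ε_i

with ε_i ~ N(0, σ_n²), the next onset t_i + RR_i/1000, and generation
stopping when a beat would end past the nominal duration. s_κ(θ) =
sin(θ + κ·sin θ) is a phase-warped sine: κ > 0 gives a steep rise and
slow fall, concentrating squared beat-to-beat increments on the
deceleration side and pushing GI above 0.5; κ = 0 recovers a symmetric
sine. The κ→GI response is monotone and crosses 0.5 near κ = 0, which
is how asymmetry is planted and validated (by direction and
monotonicity only — no published asymmetry magnitude exists to match).

Condition presets encode the study conditions' scales: rest m = 936 ms,
f_resp = 11/60 Hz, ample RSA (A_resp = 42 ms), no trend, κ = +0.08;
stimulation m = 833 ms with trend −0.15 ms/s (5-min-window mean ≈ 801 ms,
progressive RR shortening), f_resp = 13/60 Hz, damped RSA, κ = −0.08;
recovery m = 903 ms with trend +0.15 ms/s (window mean ≈ 935 ms),
rebounding RSA, κ = +0.12. LF amplitude 18–25 ms at 0.1 Hz and
beat-to-beat noise 7–9 ms throughout. Amplitudes were set once so that
rest RMSSD/SD1 land in the tens of milliseconds and stimulation damps
them, the scale a practitioner would call realistic for fit adults.

Cohorts draw per-subject jitter (baseline SD 40 ms, RSA SD 8 ms,
respiratory-rate SD 1.5 breaths/min) around the presets; career
duration ~ N(6.4, 4.2²) years, floored at 0.5. A coupling coefficient
links standardized career duration to the magnitude of the subject's
stimulation response (extra beat-to-beat noise and RSA damping during
stimulation), planting recoverable negative career↔delta correlations
in alternation-driven metrics such as AR1. Artifact injection perturbs
a seeded, non-adjacent subset of interior beats (range-violating spikes
or halved-then-compensated ectopic patterns) with ground truth returned
for sensitivity testing. All randomness flows from explicit integer
seeds; there is no global random state.

What the generator does *not* emulate — baroreflex feedback,
respiratory-cardiac phase coupling, true 1/f fractal structure,
breathing-depth effects — bounds what passing tests show: they validate
the estimators and pipeline on data with known structure, not the
physiological conclusions one would draw from real athletes.

## Numerical and degenerate-input choices

- Constant series: max–min symbols all 0; ADF undefined (error);
  asymmetry indices undefined (explicit error, reported as NaN plus an
  `hra_defined=False` flag in pipeline rows); lnRMSSD is NaN when
  RMSSD = 0.
- Tie-breaks: equal-probability ranking is stable by position; Friedman
  uses mid-ranks with the standard tie factor; an all-tied block returns
  Q = 0, p = 1.
- Tolerances: partition identities and rate sums are exact up to 1e-9;
  table round-trips are bit-exact.
- Generation treats RR < 1 ms as degenerate: just above zero the beat
  clock advances by RR/1000, so RR would decay geometrically without
  ever crossing zero.

## Problem sizes used in validation

The validation suite enumerates all 3-symbol words over alphabets up to
6, uses 100–500 random series for oracle and invariant checks, 10,000
null replicates for test calibration at n = 9, 100 seeded series per arm
for stationarity discrimination, 20 seeds per point for generator
response curves, and 20 cohorts of 30 subjects for coupling recovery —
sizes at which every Monte-Carlo band in use is comfortably resolved.

## Known limitations

- The artifact detector is a screening rule, not a clinical classifier;
  ectopy is only labelled when injected or pre-annotated upstream.
- SD1/SD2 differ from ellipse-fit values by O(1/n) factors; comparisons
  across software should use one convention throughout.
- The default chi-square Friedman approximation is slightly liberal at
  n = 9 (measured 0.058); the exact option covers only k = 3 without
  ties.
- Ultra-short (1-min) windows contain ~60–80 beats; symbolic rates and
  run counts on such windows carry large sampling variance and should be
  read as descriptive, not inferential.
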