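# Methods

This note documents the models and procedures `statephys` implements,
the defaults it ships, the design choices that were genuinely open, and
what the synthetic validation does and does not establish about real
recordings.

## Locomotion-state segmentation

Wheel position comes from an angle sensor on a 15-cm wheel. The angle is
unwrapped before differentiation (so the 2π→0 sensor wrap produces no
velocity transient), converted to arc length via the wheel radius,
differentiated with a central difference, and smoothed with a 0.25-s
boxcar — below the 2-s minimum run duration of interest, so smoothing
cannot blur a qualifying bout away.

States are segmented by binary segmentation on the rank-transformed
speed with an L2 (mean-shift) cost. Working on ranks makes the split
criterion sensitive to any shift of the speed *distribution* rather
than assuming Gaussian residuals; it is the natural segmentation
counterpart of the rank-based group tests used downstream. A split is
accepted when it reduces cost by more than a BIC-style penalty
`penalty_scale · log(n)` on unit-variance ranks (default
`penalty_scale = 3`), with a 0.5-s minimum segment. Segments with mean
speed ≥ 1 cm/s are labeled L, the rest Q, and adjacent same-label
segments are merged, so over-segmentation inside a state is harmless.
The L/Q intervals always tile the session exactly (asserted on
construction).

Selection rules, all exposed as config defaults: quiescent periods
longer than 20 s are analyzed; for LFP the usable data additionally
start 20 s after quiescence onset and end 10 s before the next bout
onset. The phrase "stationary for a minimum of 20 s" admits two
readings — trim the first 20 s (literal; default) or merely require
duration > 20 s — and both are implemented behind the
`stationarity` switch (`"trim"` / `"duration"`). Locomotion-onset
trials require preceding quiescence > 20 s, mean speed from onset to
offset > 1 cm/s, and run duration > 2 s (all strict inequalities).

## LFP spectra and coherence

The spectral estimator is an averaged modified periodogram: 2-s Hann
windows with 50 % overlap, restricted to windows wholly inside the
selected epochs, mean-removed per window, density-scaled so the
integrated PSD equals the signal variance (verified against Parseval to
1 %). 2-s windows give 0.5-Hz resolution — adequate for the 3-Hz-wide
low band. Relative band power is the trapezoidal band integral divided
by the integral over the analysis range, 0.5–100 Hz by default: the
range covers both reported bands while excluding DC drift, and band
edges are interpolated so a flat spectrum yields the exact bandwidth
ratio. Normalized spectra integrate to 1 over the analysis range.

Spike-field coherence bins the train at the LFP rate and averages
cross- and auto-spectra over the same windows. The raw magnitude-squared
coherence `C` is debiased as `(C − 1/K)/(1 − 1/K)` with `K` windows,
which keeps perfect locking at 1, makes independent processes converge
to 0 in expectation, and is clipped to [0, 1]. Trains with fewer than
50 spikes inside the epochs return a flagged result rather than a
silent NaN.

## Unit metrics

Firing rate is spike count over total duration of the (half-open)
intervals. ISI contamination is the fraction of inter-spike intervals
below the 1.5-ms refractory period; for a Poisson train of rate λ it
equals `1 − exp(−λ·0.0015)`, which the tests verify by simulation.
Isolation distance is the squared Mahalanobis distance — in the metric
of the cluster's own mean and covariance — of the n-th nearest noise
point, n being the cluster size; with fewer than n noise points it is
unbounded (`inf`), and a singular covariance is an error rather than a
silent pseudo-inverse. Units are accepted when isolation distance
exceeds 20 (strict) and contamination is at most 0.1 % (inclusive).
Accepted units are split RS/FS at a 0.4-ms trough-to-peak width — the
conventional cortical boundary, exposed in config since no single
published value is canonical.

The modulation index compares FR_L ([−0.5, 0.5] s around onset) with
FR_Q ([−5, −2] s before onset) over accepted trials. Rates are pooled
(total spikes / total window time) rather than averaged per trial —
robust for sparse trains; per-trial averaging is available behind a
flag. Trials whose quiescent window would precede the session start are
excluded; a 0/0 index is marked undefined, excluded from population
averages, and counted.

## Behavior scoring

Positions are body centroids in cm. Occupancy assigns each sample the
time to its successor; tracking gaps longer than 1 s are excluded from
the denominator. EPM: percent of scored time in the open arms, the
center counted in neither arm. Open field: path length after a 5-sample
median despike (mode `nearest`, so endpoints are preserved).
Sociability: chamber-occupancy times for the conspecific and empty-cage
side chambers, and approaches as debounced entries into a 5-cm disc
around each cage — a re-entry counts only after the animal has left a
7-cm hysteresis radius, preventing jitter double-counts. Marble
burying: connected components of the before mask are matched to after
components by centroid proximity (match radius one marble diameter,
unmatched = fully buried); a marble is buried when its exposed area
drops by ≥ 2/3 — the per-marble threshold is not standardized in the
literature, so it is a config parameter. A detected marble count other
than 12 warns and proceeds with the detected count.

Chamber occupancy (not proximity-zone occupancy) defines Time_C/Time_E;
"time spent in each of the three partitions" is the assay's standard
scoring and the dividers make chambers the natural unit.

## Cohort statistics

The animal is the statistical unit: unit- and trial-level metrics are
averaged within animal before any test. The omnibus test is the
tie-corrected Kruskal-Wallis H with a χ²(k−1) p-value; all-identical
data return (H = 0, p = 1) by convention. Dunn's post-test compares
each group's pooled-rank mean to the control's with the tie-corrected
variance `N(N+1)/12 − ΣT/(12(N−1))`; that variance is exactly the
finite-population permutation variance of the rank-mean difference,
which the tests confirm against exhaustive enumeration. P-values are
Bonferroni-adjusted over the family of control comparisons — the
convention GraphPad-style "Dunn's multiple comparisons" applies — and
the adjustment is recorded in the output. Survival curves are empirical
fractions alive by day with censoring at P500 (censored animals count
as alive throughout and are excluded from mean death age); seizure
incidence counts animals with ≥ 1 event at Racine level 4–5, onset
being the first qualifying event.

## Synthetic cohorts: what they emulate

The generators exist so every stage can be tested against planted
truth. Their defaults are the study conditions, not tuning knobs:

* Wheel: 100 Hz sampling, trapezoidal bout velocity (0.5-s ramps, so
  onsets are well defined and onset localization is actually stressed),
  white velocity noise 0.3 cm/s, bouts 3–8 s at 4–10 cm/s separated by
  ≥ 25-s quiescent gaps so the 20-s trial rule has headroom.
* LFP: band-limited Gaussian components (3–6 Hz at 3 µV RMS, 40–55 Hz
  at 2 µV RMS, 0.5 µV broadband noise), sampled at 1 kHz — the analyses
  use no content above 100 Hz, so simulating the 40-kHz acquisition
  rate would add cost without information. The low band is mildly
  suppressed (×0.7) during locomotion, as in awake cortex.
* Spikes: inhomogeneous Poisson, 5 Hz quiescent vs 10 Hz locomotion by
  default (planted index 1/3). The rate transition leads locomotion
  onset by 0.5 s — the anticipatory modulation seen in awake cortex —
  so the planted index is exactly the closed form over the
  onset-centered window. Optional phase locking thins candidates with a
  von-Mises acceptance on the instantaneous band phase, candidate rate
  inflated by `e^κ / I₀(κ)` so the expected rate is unchanged.
* Behavior: dwell-block reflected random walks; block target
  probabilities encode planted occupancy preferences exactly, and a
  weak pull toward the holding cages makes approach counts emergent.
  Marble masks keep a concentric exposed disc per marble whose area
  implements the chosen coverage fraction analytically.
* Outcomes: exponential death and first-seizure hazards from weaning
  (P21), censored at P500; qualifying events get Racine 4–5 and
  sub-threshold events are sprinkled in as noise.
* The mutant-like preset plants 0.7× gamma amplitude (0.49× power),
  a 3× firing-rate increase, zero locomotion modulation, reversed
  social preference (−0.4 vs +0.4), reduced marble burying, and
  elevated seizure hazard; a second mutant group drawn from the control
  distribution provides the specificity check.

What passing these tests shows: the estimators are unbiased at planted
effect sizes, the selection rules are implemented exactly, the rank
statistics match exact oracles, and the pipeline detects a planted
multi-metric phenotype with the intended specificity. What it does not
show: robustness to non-Poisson spiking, non-stationary or 1/f LFP
backgrounds, tracking noise and posture ambiguity in video, imperfect
mask registration, or sorting errors upstream of the QC metrics — real
data carry all of these.

## Numerical and scale choices

Pipeline runs use 240-s sessions with 6 bouts and 4 units per animal
and 8 animals per group: at the planted effect sizes this gives
essentially deterministic detection while keeping a 20-cohort
validation sweep to well under a minute, and the acceptance script's
sizes are chosen the same way. Epoch arithmetic uses half-open
intervals and 1e-9 tolerances at boundaries; rank ties use average
ranks everywhere; quantiles are linear-interpolation. Determinism is
guaranteed by threading a single integer seed through
`numpy.random.default_rng` in every generator; identical config + seed
reproduce result tables byte for byte.

## Known limitations

* The change-point penalty is BIC-styled, not theoretically calibrated
  for rank costs; very slow speed drifts could in principle fragment
  quiescence, though merged same-label segments absorb this.
* Spike-field coherence assumes the binned train is well approximated
  as a windowed stationary process; very low rates return flagged,
  noisy estimates.
* The marble matcher assumes marbles do not move farther than one
  diameter between frames.
* Survival handling supports only end-of-study censoring at P500, not
  arbitrary loss to follow-up.
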