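# Methods

## Sublevel-set persistence of a tachogram

The tachogram of a recording is the piecewise-linear interpolation f
of the RR sequence (r_0, …, r_n) over beat indices 0…n. We compute the
0-dimensional persistence of the sublevel filtration f⁻¹((−∞, t]):
components are born at local minima, die at the merging local maxima
(elder rule), and the global component is paired with max f. Because
linear interpolation introduces no critical points beyond the
vertices, this equals the lower-star filtration of the path graph on
the beat indices, which `compute_persistence` evaluates with a
union-find sweep over vertices in ascending (value, index) order —
O(n log n) and exact.

Numerical conventions:

* **Ties.** Vertices with equal values are processed by index; at a
  merge of two components with equal births the one whose originating
  minimum has the smaller index survives. The choice is arbitrary in
  the underlying theory; the returned *multiset* of pairs is invariant
  under it, and fixing it makes runs reproducible.
* **Plateaus.** A run of equal consecutive values enters the
  filtration as a single connected piece; no zero-length pair is
  emitted for plateau interiors, matching the continuous sublevel-set
  picture. Consequently k equals the number of strict local minima of
  the plateau-collapsed sequence (a property test asserts this).
* **Degenerate input.** A single-beat series returns the pair
  (r_0, r_0); a constant series returns one zero-length pair.
* The x-axis is beat index, not cumulative time: persistence depends
  only on the ordered values.

`oracle_persistence` recomputes the diagram definitionally — sweeping
the sorted distinct values and tracking components of the sublevel set
by interval arithmetic on the x-axis. It is quadratic and exists only
as an independent cross-check; the suite verifies exact agreement on
1000 random series including heavily tied ones.

## Diagram indices

With lengths sorted ascending l_1 ≤ … ≤ l_k and L = Σ l_i:

* Standard deviations (length, midpoint, birth, death, and the
  classical sdnn/sdsd/std_hr) are *sample* standard deviations
  (denominator k − 1), 0 when only one element. The convention is not
  dictated by the definitions; sample sd matches common HRV practice.
* Persistent entropy excludes zero-length pairs (0·log 0 := 0) but k
  and the length statistics include them. Normed entropy divides by
  log₂ L, which makes it unit-dependent and undefined at L = 1 ms;
  both are reported as missing (NaN) when undefined.
* The length threshold is 0.05 · l_k (the fraction is configurable);
  the split index p puts ties at exactly the threshold on the noise
  side (the signal set is {l_i > threshold}). signal_to_noise is the
  supra-threshold length sum over the sub-threshold sum, +∞ when no
  interval lies below the threshold. The noise sum runs over
  i = 1 … p−1 (interval indexing starts at 1).
* Undefined values (ratios with k < 2 or l_k = 0, entropy with L = 0,
  location statistics with no qualifying interval) propagate as NaN
  into feature tables, never as 0 — imputing 0 would create spurious
  class signal downstream.
* length_sum is reported raw and additionally as length_sum_per_rr
  (divided by the number of beats), since the total persistence grows
  with recording length; for equal-length recordings the two are
  proportional.

## Topological triangle

The triangle T(D) = ABC is fitted by an exhaustive 50 × 50 grid search
over the angles of its two slanted sides, each measured against the
diagonal: φ ∈ [−π/2, 0) for the left side k = AC (50 equidistant
values including −π/2, excluding 0, which would be parallel to the
diagonal) and ψ ∈ (0, π/2] for the right side l = BC (excluding 0,
including π/2). For each candidate angle the side is anchored at the
⌈0.1·N⌉-th point of D in the outward perpendicular direction, so that
exactly that many points (the anchor included, which lies on the line)
fall on or outside the side. The objective minimised over angle pairs
is

    SSQ(k) + SSQ(l) + |A − p(c)|² + |B − p(c)|² + h²,

where SSQ(side) sums squared perpendicular distances over a
⌊0.75·N⌋-point zone (the outer points plus the inner points closest to
that side), c is the centroid of D (all points, multiplicities
counted), p(c) its projection onto the diagonal, and h the height of
the apex C above the diagonal. The three term groups carry implicit
weight 1. Ties on the grid resolve to the smallest (φ index, ψ index).
Candidate pairs with parallel sides (only φ = −π/2 with ψ = π/2) are
skipped. Counts use ⌈·⌉ for the 10 % and ⌊·⌋ for the 75 % so the zone
is always a subset of D; both fractions and the grid size are
configuration knobs.

Diagrams with fewer than 3 points or with all points coincident return
a flagged degenerate fit: width 0, height 0, location at the common
coordinate, proportion NaN, misalignment 0.

The construction is equivariant under translation along the diagonal
and under positive scaling (width/height scale linearly, misalignment
quadratically, proportion is invariant); the suite asserts these to
machine precision, and asserts that a cloud mirror-symmetric across
the perpendicular through its centroid yields proportion ≈ 1 within
one angle-grid step.

## Classical HRV parameters

Time-domain indices are computed over normal (annotated ``N``) beats;
successive differences use only adjacent normal-to-normal pairs.
Heart-rate statistics are per-beat: HR_i = 60000/r_i, summarised by
mean/max/min/sd.

Frequency-domain analysis resamples the tachogram on its
cumulative-time axis with a cubic spline at 4 Hz, removes the mean,
and estimates the PSD by Welch's method (256-sample Hann segments,
50 % overlap) — standard short-term HRV settings, all exposed in
`SpectralConfig`. Band powers integrate the PSD over VLF
0.003–0.04 Hz, LF 0.04–0.15 Hz and HF 0.15–0.40 Hz (trapezoid rule);
lfnu = 100·lf/(lf+hf) and symmetrically hfnu. total_power is defined
as the variance of the RR intervals themselves (so total_power = sdnn²
holds exactly under the shared sample-variance convention), not as a
PSD integral; the spectral estimator's absolute calibration therefore
does not leak into that index.

## Editing rules

For spectral analysis, each maximal run of non-normal beats flanked by
normal beats is linearly interpolated between the flanking values;
boundary runs without a flank are dropped. For all other analyses only
normal beats are used, and the topological path additionally applies a
bounded outlier rule: values strictly outside [Q1 − m/4, Q3 + m/4]
(quartiles by linear interpolation and median m of the normal beats)
are removed if there are at most 4 of them; a larger count is treated
as genuine rhythm structure and kept in full. Quartiles are computed
after dropping annotated beats. The rule therefore removes at most 4
beats, and the output is always a subsequence of the normal beats.

## Evaluation protocol

Candidate models are all quadruples from 7 base topological
descriptors (number of intervals, length median, length stdev, length
sum, frac5%, signal to noise, persistent entropy) with at most 2 of
the 5 triangle descriptors: C(7,4) + C(7,3)·5 + C(7,2)·10 = 420
models. Each is evaluated by stratified 3-fold cross-validation
(3 rather than 5 folds, suited to cohorts of a few dozen subjects):
per fold a StandardScaler is fitted on the training rows only, a
linear-kernel SVM (C = 1, configurable) is trained, and test rows are
scored by the decision function. Fold ROC curves are averaged
vertically on a 101-point FPR grid; reports carry the AUC of the mean
curve and mean ± sd of the three fold AUCs. Fold assignment depends
only on the labels and the seed, so results are bit-reproducible.
Models whose features are undefined for some subject (NaN, or the +∞
signal-to-noise sentinel) are skipped by the search and counted,
never imputed.

## Synthetic cohorts

`generate_rr` builds r_i = mean_rr + A_LF sin(2π f_LF t_i + φ₁) +
A_HF sin(2π f_HF t_i + φ₂) + trend·i + ε_i with t_i the cumulative
time of the preceding beats, ε_i i.i.d. Gaussian, and ectopic couplets
(premature beat 0.6× the local RR followed by a 1.4× compensatory
beat, both annotated non-normal) at a per-beat rate of 0.002, i.e.
0.2 % of beats. Subjects within a cohort draw their resting RR from
N(mean_rr, 70 ms) and scale their LF amplitude, HF amplitude and noise
level by independent unit-mean lognormal factors (CV 0.5, 0.5, 0.45)
— LF and HF tone vary independently across individuals. Subject noise
draws are floored at 6 ms (R-peak detection jitter and sampling
quantization contribute several ms in any real recording), but never
above the nominal level requested.

Two presets define the study conditions: `con_like` (healthy-like:
mean RR 900 ms, A_LF 35, A_HF 25, noise 15 ms) and `str_like`
(reduced-variability: mean RR 870 ms, A_LF 12, A_HF 10, noise 24 ms).
The str-like noise level is chosen so the expected
successive-difference power matches the con-like preset: the groups
differ in the *composition* of their variability (organised
oscillation versus uncorrelated beat-to-beat noise), not primarily in
its beat-to-beat magnitude. This makes rmssd/pnni50 overlap between
groups while the persistence-interval count — which responds to the
noise-to-oscillation structure, not to magnitude — separates them,
so topological quadruples outperform the classical time-domain
quadruple directionally, with the frequency-domain quadruple weakest;
the acceptance script measures this ordering, with all models far from
both the AUC ceiling and chance.

What the generator does *not* emulate: 1/f baseline wander,
respiratory frequency drift, nonstationary autonomic shifts,
baroreflex feedback, or realistic ectopy morphology. Passing tests
therefore demonstrate correctness of the computations and the
qualitative behaviour of the indices under controlled variability
structure — not clinical performance on real recordings.

## Problem sizes

The test suite and the acceptance script use 512-beat recordings (the
standard short-term segment length the pipeline targets), cohorts of
25–40 subjects per group, 1000 random series for the oracle
cross-check, and n = 200 for the permutation-null calibration of the
evaluation harness.

## Known limitations

* The triangle fit is a grid search; descriptors are only resolved to
  one angle-grid step (π/100 by default), and the anchoring percentile
  is a point statistic, so descriptors respond discretely to single
  points entering or leaving the outer 10 %.
* Normed entropy is unit-dependent (it divides by log₂ of a quantity
  in ms); it is reported as defined, and comparisons across different
  RR units are not meaningful.
* frac100/frac200 use absolute 100/200 ms cutoffs and are not
  scale-invariant by construction.
* The spectral estimator's absolute band powers depend on the
  resampling and windowing choices; only total_power (an RR variance)
  is estimator-independent.
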