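# Methods

## Problem and model

The package predicts energy expenditure (EE, kcal/min scale) during exercise
from two wearable-sensor signals: heart rate (HR, bpm) and a movement index
(MI) derived from chest-worn accelerometry. The relationship is monotone but
saturating, the predictors are strongly correlated, and users want calibrated
uncertainty, not just a point estimate. The model is a Takagi–Sugeno–Kang
linguistic model (TSK-LM): fuzzy rules whose premises are found by clustering
and whose consequents are fuzzy numbers plus affine input terms, yielding a
triangular-fuzzy-number output `(f⁻, f*, f⁺)`.

### Linguistic contexts

The output range is covered by `p ≥ 2` triangular fuzzy sets with strictly
increasing apexes; adjacent triangles cross at membership 0.5 and the two
boundary sets are open-shouldered (membership 1 beyond the outer apex), so
the family is a Ruspini partition — memberships sum to exactly 1 everywhere
in the range. The stored break points `(r⁻, r, r⁺)` of a boundary context
have the outer point clamped to the range limit.

Two placement schemes:

* **uniform** — apexes equally spaced over `[min(y), max(y)]`;
* **flexible** (default) — apexes at the quantiles of `y` at levels
  `t/(p−1)`. Each context then holds roughly `N/(p−1)` observations.

The flexible scheme is the default because it is the configuration of the
original predictor and because equally spaced contexts demonstrably starve
the boundary contexts on skewed outputs: on the default synthetic treadmill
profile the lowest uniform context contains only ~2 points with positive
membership, so any `c ≥ 3` clustering inside it must fail. Such failures are
surfaced per cell by the evaluation harness rather than hidden.

### Context-based fuzzy c-means (CFCM)

Within each context `t`, `c` clusters are fitted in the min–max-normalised
input space under the constraint that the membership column of point `k`
sums to its context weight `w_tk`:

    u_tik = w_tk / Σ_j (‖x_k − v_i‖/‖x_k − v_j‖)^(2/(m−1))
    v_i   = Σ_k u_tik^m x_k / Σ_k u_tik^m

Distance is Euclidean; inputs are generalised from the original two columns
to any `d ≥ 1`. The alternation minimises `J = Σ_{i,k} u_tik^m ‖x_k − v_i‖²`
subject to the column constraint, so the recorded objective trace is
non-increasing; with `w ≡ 1` the procedure is exactly standard fuzzy
c-means. Defaults and numerical rules:

* fuzzifier `m = 2.0`; the `2/(m−1)` exponent is used verbatim for other `m`;
* random membership initialisation, uniform on (0,1), columns rescaled to
  sum to `w_k`, seeded (`numpy.random.default_rng`);
* convergence when `max |ΔU| < 1e−5` or after 200 iterations (the source
  studies state no values; these are conservative for N ≈ 76);
* a point coincident with one or more centers gives its full weight to
  those centers, split equally;
* distance ratios are normalised by the column minimum before powering, so
  near-coincidences cannot overflow;
* `c` greater than the number of positive-weight points, or an all-zero
  weight vector, is an error naming the context.

### Rule activation at inference

The training constraint defines memberships only for training points, so
activation of an unseen input is defined as follows: fuzzy c-means
memberships of `x` are computed context-free over the pooled `p·c` centers
(unit weights, same fuzzifier), then summed within each context to give
`z_t`. By construction `z_t ≥ 0` and `Σ_t z_t = 1`, which makes every output
a convex combination of rule consequents and hence guarantees
`f⁻ ≤ f* ≤ f⁺`. An input coincident with a pooled center activates that
center's context fully.

### Consequents, least squares, bias

The rule consequent is `[r_t⁻, r_t, r_t⁺] + δ_t + β_t·x`: the context's
fuzzy number, a fitted location offset `δ_t`, and a fitted linear term.
All `β, δ` are estimated by **one global** least-squares problem

    min ‖ (y − Z r) − Φ θ ‖²,   Φ = [ z_t x_j … | z_t … ]

because the modal output is linear in all of them jointly; per-rule weighted
fits would not minimise the actual training error. The offsets `δ_t` are
part of this package's design: with consequent intercepts fixed entirely to
the context apexes, `Σ_t z_t r_t` is a non-affine function of `x` and even a
noiseless affine target could not be fitted exactly; the offsets restore the
standard first-order TSK consequent, keep the interval ordering (they shift
all three break points equally), and make affine targets exactly
representable. The solve is `numpy.linalg.lstsq` (minimum-norm on rank
deficiency, so rules that never activate get exactly zero coefficients),
with a ridge fallback (`λ = 1e−8`) only if the SVD fails.

After the least squares, a global bias `b₀ = mean(y − f*)` is added, making
the modal output unbiased on the training set. The **conventional LM**
baseline keeps `β = δ = 0`, `b₀ = 0`; its modal output `Σ_t z_t r_t` uses
this package's activation rule (the historical model's internals are not
reproduced — this baseline is a reconstruction). Because the TSK parameters
are fitted by least squares over a family containing the baseline, the TSK
training RMSE can never exceed the baseline's on the same granulation.

All fitting happens in min–max [0,1] space computed from training data only;
predictions are denormalised for reporting. Only the modal value and the
support endpoints of the output fuzzy number are exposed; intermediate
α-cuts are not defined by the formulation.

## Synthetic data generator

The original study data (30 participants, five activities, N = 76 rows per
activity) are not publicly deposited, so the generator emulates the stated
structure rather than any real table:

* HR and MI are a bivariate standard normal with configurable correlation
  (treadmill default 0.892), clipped at ±3σ and mapped linearly onto the
  profile ranges (treadmill: HR 90–185 bpm, MI 5–60 units). Clipping
  preserves the mean and shrinks the SD by a known winsorisation factor
  (~0.25%), which the tests account for in closed form.
* EE is a saturating monotone surface `ee = lo + (hi−lo)·(1−e^{−ρs})/(1−e^{−ρ})`
  of the drive `s = 0.6·hr_norm + 0.4·mi_norm` (curvature ρ = 2.5, treadmill
  EE 2–14), plus Gaussian noise (sd 0.5 for the treadmill profile). The
  saturation makes the problem genuinely nonlinear — exactly the regime where
  the per-rule linear terms earn their keep — and gives HR the larger single-
  factor influence, mirroring the reported factor study.
* Five profiles (treadmill, normal/brisk walking, slow running, jogging)
  differ in ranges, noise and correlation; ranges are qualitative choices on
  the published scatter, not fitted values.

What passing tests on these data do **not** show: performance on real
physiological signals with heteroscedastic noise, drift, activity
transitions, or inter-subject variability. The generator draws i.i.d. rows;
it has no temporal structure.

The movement index operation reconstructs the published signal feature: zero
crossings of the acceleration waveform are feature points, the extremum
between consecutive crossings is a triangle apex, and the MI of a second is
the mean area `½·base·|extremum|` of the triangles whose apex falls in that
second (0 for an empty second). Crossing times are linearly interpolated;
exact-zero samples count as crossings. The exact feature-point rule of the
original hardware pipeline is unpublished, so this is a stated stand-in; it
is non-negative, sign-flip invariant and exactly homogeneous in amplitude.

## Evaluation protocol

`run_experiment` reproduces the study design: per iteration a seeded 60/40
train/check split (train size `round(0.6N)`, disjoint and exhaustive), all
`(variant, p, c)` cells trained on the training split, RMSE on both splits,
means over 10 iterations; the best cell per variant minimises mean check
RMSE. Choices the source protocol leaves open:

* cell means over iterations are reported (per-iteration values retained);
* per-iteration split seeds and per-cell training seeds derive from the
  master seed by a fixed counter scheme that excludes the variant, so both
  variants see identical splits and identical granulations — paired
  comparisons;
* normalisation is recomputed from each training split and applied to its
  check split (no leakage);
* improvement percentages are `(baseline − model)/baseline` on mean RMSE;
* a failing cell (e.g. data scarcity under the uniform scheme) is recorded,
  reported as NaN, and the run continues; the CLI exit status reflects it.

Problem sizes used throughout testing are the study's own: N = 76 rows,
grid `p, c ∈ 2..6`, 10 iterations, two variants; one full protocol run takes
a few seconds, and the headline-ordering check repeats it ten times on
independently seeded datasets.

## Known limitations

* The activation rule for unseen inputs is this package's construction; the
  original architecture describes the summation layer but not how context
  weights extend beyond training data.
* The conventional-LM baseline is a reconstruction sharing this activation
  rule, not a reimplementation of the historical model.
* Interval coverage is whatever the fuzzy-number geometry implies; the bounds
  are not calibrated prediction intervals.
* `p` and `c` are grid-searched, never selected automatically; fuzzifier
  variants other than triangular contexts (Gaussian sets, possibilistic or
  kernelised clustering, premise tuning) are out of scope.
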