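# Methods

`burrowacc` implements an accelerometry-based workload analysis for
fossorial cooperative breeders (Damaraland mole-rat societies are the
motivating system): collar loggers record tri-axial acceleration at
25 Hz, the stream is classified into behaviours, and per-individual
time budgets feed the statistics that separate breeder workload from
helper workload and probe for a caste system among non-breeders.

## Signal processing

**Windows.** Streams are cut into contiguous, non-overlapping 2-s
windows aligned to the series start (50 samples per axis at 25 Hz);
the trailing partial window is discarded. Ground-truth behaviour
intervals label a window only when a single interval covers it
entirely; intervals shorter than a window can never label one and are
tallied as omitted, mirroring how short video-labelled behaviours are
dropped from classifier training.

**ODBA.** Overall dynamic body acceleration is computed per window by
smoothing each axis with a 10-point running mean (centred, spanning
offsets −5…+4, truncated at the edges) and summing the absolute
deviations over samples and axes. Axes are centred by their window
mean before smoothing — analytically a no-op, numerically it makes
ODBA exactly zero for static postures. Whether the per-window
aggregate should be a sum or a per-sample mean is a convention choice;
both are exposed (`scale="sum"` default), and all downstream use is
scale-invariant (relative comparisons and log-link models).

**Features.** Each window is summarised by a frozen 50-feature vector:
per axis (×3) mean, SD, min, max, range, skewness, kurtosis, the 25th/
50th/75th percentiles, mean absolute first difference, zero crossings
of the mean-subtracted signal, and the dominant-frequency power
fraction (39); the three pairwise axis correlations (42); and
whole-window ODBA, its three per-axis components, vector-magnitude
mean and SD, the tilt angle of the mean vector, and the
vector-magnitude interquartile range (50). Effectively constant axes
(relative tolerance 1e-9) return zeros for shape/spectral/correlation
features so the vector is always finite.

**Posture.** The dorso-ventral (z) axis carries ~9.8 ms⁻² when the
animal is horizontal. Mean window z below half standard gravity
(4.9 ms⁻², strict less-than) marks an upright posture pitched more
than 60° — the operational definition of vertical eating (eating
directly from an in-ground tuber rather than from detached pieces).

## Behaviour classification

The ethogram has 14 behaviours grouped into four analysis categories:
rest; excavating activities (dig, sweep, back-kick); movement (run,
walk, food-carry); and other (eat, groom, scratch, sniff, gnaw, rear,
shuffle). A histogram-based gradient-boosted tree classifier
(scikit-learn, 300 trees, depth 3, learning rate 0.1, fixed seed) maps
feature vectors to behaviours. Evaluation uses leave-individuals-out
grouped cross-validation — individuals, not windows, are partitioned
into folds — because windows of one animal are strongly dependent and
a window-level split would overstate accuracy. Reports carry both the
behaviour-level and category-level confusion matrices; the category
matrix is exactly the behaviour matrix aggregated through the category
map, so grouping can only merge errors.

## Derived behaviours and time budgets

Consecutive windows of one category form bouts. *Walk-around* is
movement in bouts strictly longer than 5 s (≥3 windows of 2 s, the
smallest duration exceeding 5 s) whose preceding minute — the
half-open interval [start−60 s, start) — contains no excavate window;
it proxies locomotion unrelated to digging work sequences, possibly
tunnel patrolling. Bouts are built at category level because run/walk
cannot be separated below category reliability; food-carry windows are
dropped from walk-around output by default (a different task), behind
a flag. Daily time budgets give per individual-day category
proportions, the raw window counts behind them (the totals for
beta-binomial models), mean ODBA and the vertical-eating share of
eating windows; days with under half the expected windows are flagged
incomplete but kept.

## Growth index

Juvenile growth is summarised from the first two captures when the
first mass is below 90 g and the recapture falls 3–8 months later
(91–244 days inclusive — calendar months are ambiguous, so the day
bounds are fixed). The mass gain is modelled per sex as a penalized
cubic B-spline smooth of first mass plus a linear day-gap effect;
smoothing strength is picked by generalized cross-validation over a
log-spaced grid. Separate per-sex fits implement the sex-specific
smooth (the sex main effect is absorbed by the per-sex intercepts).
The growth index is the residual — positive means faster-than-average
growth. Predictions outside the fitted mass range clamp to the
boundary and are flagged.

## Statistics

**Dip test.** The dip statistic — the minimal sup-norm distance
between the empirical CDF and the class of unimodal CDFs — is computed
with the iterative greatest-convex-minorant / least-concave-majorant
algorithm, in step-count units scaled by 1/(2n), so the balanced
two-point sample gives 0.25 and the universal floor is 1/(2n). The
test suite verifies it to 1e-8 against an independent linear-program
oracle that minimises the sup distance over piecewise-linear unimodal
CDFs directly. The null is the classical uniform(0,1) bootstrap at the
observed n (the least-favourable unimodal case, so normal samples are
accepted conservatively); the null table for a given n can be
precomputed and shared.

**Repeatability.** Intra-class correlation of daily metrics comes from
a Gaussian random-intercept model on the observed scale (a logit-scale
option exists), r = var_ind / (var_ind + var_res), with a
likelihood-ratio test against the pooled model referred to the
boundary mixture ½χ²₀ + ½χ²₁. The mixture reference is mildly
conservative in finite samples (empirical type-I error ~0.02–0.05 in
the calibration test).

**Mixed models.** Mean ODBA is gamma-distributed with a log link;
category proportions are beta-binomial on (window count, total
windows) with a logit link, parameterized by mean π and precision
s = (1−ρ)/ρ. The single group-level random intercept is integrated by
adaptive Gauss–Hermite quadrature (15 nodes centred and scaled at the
per-group posterior mode found by Newton iterations); one node would
be the Laplace approximation, and the fit matches glmmTMB's to ~1e-3
on test fixtures. Design columns are standardized internally for
optimizer and finite-difference-Hessian conditioning and results
rescaled. Standard errors are Wald from the numerical Hessian of the
marginal likelihood; non-convergence is flagged, never silently
patched. Marginal R² follows the latent-scale variance partition with
π²/3 as the logit distribution-specific variance and the trigamma of
the estimated shape for the gamma log link (beta-binomial
overdispersion is not added to the denominator; stated here because
conventions differ). No multiple-testing correction is applied
anywhere. The breeder-contrast design is: breeding status, group size
centred to the sample mean (centred only, not variance-scaled), their
interaction, and sex.

## Synthetic data generator

The generator defines the study conditions and exists in two tiers.

**Population.** 11 groups with log-normal sizes (median ~9, clipped
3–22; wild groups span pairs to over twenty animals, and this spread
also matches the interaction-to-status precision ratio of the target
design), one breeding pair per group, non-breeders aged 5–36 months,
breeders 36–96; deployments ~N(17, 3.9²) days of 25 Hz recording.
Masses follow a logistic growth curve with individual asymptotes; each
animal has a log-normal growth multiplier, the planted quantity behind
its two early-life captures.

**Planted effects** (logit scale for proportions, log for ODBA):
excavation — status −0.542, group size −0.005, status×group size
−0.066, sex(male) −0.139, an age hump −0.002·(age−14 mo)², and
+0.01 per g of growth deviation; resting — 0.324 / 0.011 / 0.018 /
0.181; ODBA — −0.274 / −0.007 / −0.020 / −0.100. Age and growth
effects apply within non-breeders and are centred over that stratum,
so the planted status coefficients are exactly the contrasts the
models estimate. The planted daily-excavation ICC is 0.37: the day-level logit SD is
0.447, and the between-individual variance budget (0.1175 latent) is
the sum of the age-hump (~0.075), growth-slope (~0.017) and group
(0.01) contributions plus a free individual term absorbing the
remainder. Measured on the observed proportion scale the realized ICC
is ~0.35 ± 0.05 across populations — slightly below the latent target
because inverse-logit compression at very low excavation probabilities
shrinks between-individual spread. Breeding females get a −0.8 logit offset on vertical eating.
Food carrying shares the excavation propensity (+0.5 logit coupling);
walk-around does not — the task-specialization structure the
correlation analyses should recover.

**Budget tier** draws daily window counts and ODBA means directly from
these models (excavate binomially, rest from the remainder with its
conditional probability, movement/other splitting the rest). A full
study is ~86 animals × 17 days × 43,200 windows/day; skipping raw
signal synthesis makes 100-replicate parameter-recovery runs a
minutes-scale exercise at the full design size.

**Signal tier** generates behaviour schedules as a semi-Markov renewal
process — log-normal dwell times per behaviour, bout-frequency weights
solved per individual-day so the expected category time shares equal
the planted targets (renewal-reward) — and synthesizes raw 25 Hz
signal per bout: gravity set by a behaviour-specific pitch, a
band-limited oscillation (behaviour-specific amplitude, frequency and
axis mix, plus a 0.35-weight first harmonic) and Gaussian noise.
Individuals carry small posture/amplitude/frequency offsets so grouped
CV is a real test. A `separability` dial interpolates all behaviours
toward one shared signal model; at 0 a classifier can only reach
chance. Dwell-time medians are assumptions (rest 180 s, digging ~10–20
s, locomotion ~8–10 s), not field estimates.

**What the generator does not emulate:** logger drift and dropout
beyond simple gaps, behaviour-dependent autocorrelation in posture,
transitional windows spanning behaviour changes (these stay unlabelled
rather than mislabelled), seasonal or circadian structure, and
pregnancy/lactation dynamics. Classifier accuracies on this synthetic
fixture (category ~98%) therefore bound what matters — that the
pipeline recovers planted structure — and say nothing quantitative
about accuracy on field data.

## Problem sizes in the checks

The acceptance checks run at: 16 individuals × 300 windows per
behaviour for classification; the full study design (11 groups,
~90 animals, ~17 days at the budget tier) for mixed-model and
repeatability recovery with 100 replicates of the former; n = 65 with
2000 uniform bootstrap draws for dip-test calibration; and 100 random
samples (n ≤ 40) against the LP dip oracle. The end-to-end dataset
smoke test writes a micro deployment (fractional days) rather than a
full 17-day stream.

## Known limitations

* Wald CIs from the adaptive-GH likelihood under-cover slightly when
  the generative individual heterogeneity is logit-normal but fitted
  as beta mixing (replicate coverage ~93% rather than 95% for the
  status contrast at study scale).
* The dip implementation assumes mostly distinct values; heavy ties
  beyond an all-equal sample are not specially handled.
* The growth smoother clamps rather than extrapolates outside the
  observed first-mass range.
* Calendar handling is logger-local day indexing; time zones and DST
  are out of scope.
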