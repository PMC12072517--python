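# Methods

## The analysis in outline

`oxprofile` treats a three-group study (healthy reference, disease model,
treated disease model) as a pipeline with five stages:

1. **Assay arithmetic.** Raw plate reads become endpoint values by closed-form
   formulas: kinetic ALT activity from the A340 decline, creatinine clearance
   from urine/plasma creatinine, analyte concentrations from 4PL calibration
   curves, and protein normalization. These are deterministic unit
   conversions; the only estimation step is the 4PL least-squares fit.
2. **Efflux kinetics.** Luminal fluorescence traces from isolated brain
   capillaries are fitted with a first-order decay; the rate constant k
   (min⁻¹) is the barrier-leakage readout, and capillaries are the replicate
   unit for group means.
3. **Behavioural scoring.** Y-maze retrieval trials yield per-arm entry and
   dwell percentages and a cohort-level forced-alternation percentage.
4. **Group statistics.** Technical replicates are averaged to subject level;
   endpoints are compared across groups by fixed-effects ANOVA with
   likelihood-ratio χ² statistics; p-values receive a Benjamini–Hochberg
   step-up adjustment; pairwise group contrasts use Welch standard errors.
5. **Correlation profiling.** The study-level question — does treatment
   restore the *web of relationships* among endpoints, not merely their
   means — is answered by comparing per-group correlation matrices.

## Correlation-profile comparison

Within group g, each endpoint pair (i, j) has a Pearson (optionally
Spearman) correlation r_g(i,j), computed on subject-level data with
pairwise-complete observations. All quantities are Fisher-transformed,
z = atanh(r), whose sampling variance is approximately 1/(n − 3) and roughly
independent of r — the property all downstream steps rely on.

**Steiger-type matrix test.** Two groups' matrices are compared by

    χ² = Σ_{i<j} (z_A(i,j) − z_B(i,j))² / (1/(n_A − 3) + 1/(n_B − 3)),

referred to a χ² distribution with df = p(p−1)/2. Between-group coefficients
are independent, so the statistic's null distribution is exact up to (a) the
1/(n−3) variance approximation and (b) dependence *among* pairs within a
matrix when the population matrix is far from diagonal. The test suite
calibrates the test by simulation at the study's size (n = 15/group, 2000
replicates, mild single-factor population matrix) and requires the α = 0.05
rejection rate to stay within [0.03, 0.07]. With strongly correlated
endpoint panels the statistic should be treated as a descriptive index rather
than an exact test. p-values across the three group pairs are BH-adjusted.

**Dissimilarity and tree.** Profile dissimilarity is the Euclidean distance
between z-vectors over unique pairs. The three (or more) groups are displayed
as an unrooted neighbor-joining tree (Saitou–Nei, via scikit-bio); for three
leaves NJ reproduces the closed-form branch lengths
b_A = (d_AB + d_AC − d_BC)/2, and for additive matrices it recovers the
generating tree exactly. Negative branch lengths are clamped to zero, the
standard NJ convention. Pairs with undefined correlations in any group are
excluded from every distance so the metric stays comparable across group
pairs.

**Effect classification.** For each pair, write dz_dis = z_dis − z_ref (the
disease shift) and dz_trt = z_trt − z_ref (the residual shift under
treatment). The grand difference dz_dis − dz_trt = z_dis − z_trt is
back-transformed to the r scale and thresholded: |·| ≤ 0.1 no effect, then
small/moderate/large at 0.3 and 0.5. Direction:

- **correction** — treated sits on the disease side of the reference but
  closer to it (|dz_trt| < |dz_dis|, signs agree);
- **exacerbation** — treated sits at least as far away on the same side;
- **overcorrection** — treated crossed to the opposite side of the reference,
  with extent taken from the overshoot |tanh(dz_trt)| rather than the grand
  difference (the grand difference conflates the corrected disease shift with
  the overshoot).

A crossing counts as overcorrection only when the overshoot clears the same
0.1 dead band used for no-effect calls: a treated coefficient statistically
indistinguishable from the reference is a correction. Without this dead band
a fully corrected pair (z_trt ≈ z_ref) would be labelled overcorrection on
roughly half of random samples, since the sign of dz_trt is then a coin flip.
An alternative reading of "overcorrection" — the treated coefficient moves
*past the disease value* on the same side, rather than past the reference —
is selectable (`overcorrection_mode="beyond_disease"`); it reclassifies what
the default calls strong same-side exacerbations.

Scores: corrections +1/+2/+3 and exacerbations −1/−2/−3 by extent,
overcorrections +0.5/+1.0/+1.5 (half credit: the disease effect was removed
but the treatment overshot), no effect 0. The overall score is the sum over
all pairs; with the sign convention above, positive totals mean net
restoration of the reference profile. Pairs with missing correlations are
reported as unclassifiable with score 0, never dropped silently.

## Group statistics: fixed effects in place of a mixed model

Technical replicates are modelled as exchangeable within subject. Averaging
them and fitting a fixed-effects linear model to subject means gives exactly
the mixed-model (random subject intercept) fixed-effect estimates when the
design is balanced — the package checks balance and warns when the shortcut
is only approximate. Per-effect statistics are Gaussian deviance differences,
χ² = n·ln(RSS_reduced/RSS_full) with df equal to the columns dropped,
which matches 2Δ(log-likelihood) for normal errors with estimated scale;
this is mildly anticonservative at small n (a property test measures the
pipeline's familywise error under a global null at the study's fixed family
size m = 11 and requires it to stay at or below the nominal level within
Monte-Carlo error). Effect R² is incremental, (RSS_reduced − RSS_full)/TSS.
The BH step-up is implemented directly (adj_(i) = min_{j≥i} p_(j)·m/j) so the
family size m may exceed the number of p-values, as when a study fixes a
global family across assays.

## Nonlinear fits

**First-order efflux.** F(t) = f_inf + (f₀ − f_inf)e^(−kt), bounded k ≥ 0,
0 ≤ f_inf ≤ f₀, initialized from the log-linear regression of ln F on t
(which is exact for noise-free, zero-plateau data and avoids the k = 0 local
minimum). `plateau_mode="fixed_zero"` (default) pins f_inf = 0 — pure
first-order efflux; `"free"` accommodates traces that saturate above
background. A best fit at the k = 0 boundary is flagged (`boundary=True`)
rather than raised, since non-decaying traces are a legitimate outcome. The
standard error of k comes from the curvature of the least-squares objective.

**4PL calibration.** y = d + (a − d)/(1 + (x/c)^b), initialized with a and d
at the response extremes (a at the low-dose end), c at the geometric mean of
positive doses, b = 1. The fitted parameters are canonicalized through the
mirror identity (a, b, d) → (d, −b, a) so a always reports the zero-dose
response. Inversion is closed-form and restricted to the open response range;
readings at or beyond the asymptotes raise a quantification-limit error
naming the limits — samples are censored, never extrapolated. Flat response
sets raise a convergence error carrying the last parameter state.

**ALT activity.** The canonical computation is the two-point form over the
0–5 min window, as the kit formula prescribes; a regression mode over all
reads is available (flagged non-canonical) for noisy single reads.

## Units and conventions

- Creatinine clearance is computed in µL/min (the formula divides by minutes,
  default collection time 1440 min); an explicit, logged ×60 presentation
  conversion yields µL/h for comparison with reports that print that unit.
  The µL/h magnitudes in the motivating study are implausibly small for mouse
  physiology; the package reproduces the formula as printed and surfaces the
  conversion rather than hiding it.
- Fold changes are max-over-min ratios with a higher/lower direction flag, so
  they are symmetric under argument exchange.
- Y-maze "entries" are transitions into an arm; the initial placement into
  the start arm is not an event, and the first recorded entry of the
  retrieval trial decides forced alternation. Center-zone time is excluded
  from dwell-percentage denominators.

## The synthetic cohort

The generator stands in for the study's unavailable raw data. Defaults are
the study's conditions: three groups of n = 15, seven endpoints whose group
means and SDs mirror the published summaries (SD = SEM·√15), three technical
replicates per subject with noise sd = 0.2 × subject SD (a typical technical
CV; the source states no replicate counts, so both are configurable), and
first-order traces at the published rate presets (0.08 / 0.26 / 0.18 /
0.58 min⁻¹) on a 0–255 imaging scale with noise sd 5. Traces default to 13
frames at 2-min intervals: at that density the fitted k's bias stays below
5% across k ∈ [0.05, 0.6] under noise sd ≤ 10, whereas 5-min sampling leaves
too few informative points at the fastest rates (the first frame already
decays 20-fold at k = 0.6).

Subjects are multivariate Gaussian — matching the parametric assumptions of
the downstream tests — with the target correlation imposed through an
eigenvalue factorization, so the *population* correlation equals the target
exactly. The published study prints no per-group correlation matrices, so the
planted structure is a design choice: single-factor loadings in which
oxidative-stress endpoints load positively and creatinine clearance
negatively, strongest in the disease group (pairwise r up to ≈0.5) and
intermediate under treatment. Single-factor matrices are PSD by construction.
Negative generated concentrations are truncated at zero with a logged count;
for endpoints whose mean sits only ~2.5 SD above zero this truncation
slightly perturbs means and correlations — recovery tests therefore use
means far from zero.

What the generator does **not** emulate: non-Gaussian tails and skewness of
real assay read-outs, heteroscedastic replicate noise, plate and batch
effects, missingness, litter/cage clustering, and any pharmacokinetics of the
treatment. Passing tests therefore demonstrate that the estimators and
classifiers recover known structure under the stated sampling model, not that
the biological conclusions of any particular study are correct.

## Scale of the shipped checks

Simulation-backed tests use sizes chosen to make pass/fail margins several
sampling SDs wide: Steiger calibration at 2000 null replicates; planted
classification recovery over 200 runs at n = 1000/group with the planted
values ≥3 SD from every category boundary; planted-correlation recovery at
n = 10⁴, where the 0.05 tolerance is a ~5 SD bound on the maximum over all
63 pair deviations (at n = 2000 the same tolerance would fail on a large
fraction of seeds purely by sampling noise); familywise-error control over
400 null replicates of the full aggregate→ANOVA→BH pipeline.

## Known limitations

- The Steiger statistic ignores within-matrix dependence among correlation
  pairs; it is calibrated for weakly correlated panels.
- The χ²-by-deviance ANOVA is asymptotic; at n = 15/group its raw per-test
  size runs slightly above nominal (the BH step and family size keep the
  familywise rate controlled).
- The extent thresholds (0.1/0.3/0.5 on the back-transformed grand
  difference) and the score grid are conventions inherited from the method's
  original application, not estimated quantities; at n = 15 the sampling SD
  of a single grand difference (~0.29 on the z scale) is comparable to the
  bin widths, so per-pair classifications are noisy and only the aggregate
  score is a stable summary.
- Classification treats the three group correlations as known values; no
  uncertainty propagates into the category calls.
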