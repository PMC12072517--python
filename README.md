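# oxprofile

Outcome profiling for three-group preclinical treatment studies.

Many mouse studies compare a healthy reference strain, a disease model, and
the disease model under treatment across a panel of biochemical and
behavioural endpoints — for example a transgenic amyloid model (5xFAD) with
and without an antioxidant diet, read out through oxidative-stress markers
(MDA, 4-HNE per mg protein), blood–brain-barrier leakage (capillary efflux
kinetics, plasma S100β), renal function (creatinine clearance) and Y-maze
performance. `oxprofile` implements the full quantitative path from raw assay
reads to a study-level treatment score, for analysts who want each published
number to be reproducible from tidy input tables.

## What it computes

**Assay arithmetic** (`oxprofile.assays`) — kinetic ALT activity
[((A₀ − A₅)/5 min) · V_total] / (ε · V_sample) with ε = 4.11 mM⁻¹; creatinine
clearance (U_cr · V)/(P_cr · t); four-parameter logistic calibration
y = d + (a − d)/(1 + (x/c)^b) with closed-form inversion and explicit
quantification limits; protein normalization, max/min fold changes, and
diet-to-dose / body-surface-area dose conversions.

**Efflux kinetics** (`oxprofile.kinetics`) — bounded nonlinear least squares
for F(t) = f_inf + (f₀ − f_inf)·e^(−kt) on luminal fluorescence traces
(plateau fixed at 0 or free), per-group rate tables with SEM and ratios, and
inhibitor-sensitive (transporter-specific) luminal signal.

**Y-maze scoring** (`oxprofile.ymaze`) — percent entries and percent dwell
time per arm, and the cohort forced-alternation percentage (fraction of mice
entering the previously blocked novel arm first).

**Group statistics** (`oxprofile.groupstats`) — technical-replicate
aggregation (exact mixed-model equivalent under balance), fixed-effects ANOVA
with likelihood-ratio χ² per effect, Benjamini–Hochberg FDR with an optional
fixed family size, and Welch pairwise contrasts of group means.

**Correlation profiling** (`oxprofile.profiles`) — the study-level analysis.
Within each group, all p(p−1)/2 endpoint-pair correlations form a profile.
Profiles are compared by a Steiger-type statistic
χ² = Σ_{i<j} (z_A − z_B)² / (1/(n_A−3) + 1/(n_B−3)) on Fisher-transformed
coefficients (df = p(p−1)/2), summarized as Euclidean distances in z space
with a neighbor-joining unrooted tree, and each pair's treatment effect is
classified from the grand difference
(z_dis − z_ref) − (z_trt − z_ref) = z_dis − z_trt: back-transformed and binned
at 0.1/0.3/0.5 into none/small/moderate/large, with direction correction
(treated moved back toward reference), exacerbation (moved further away) or
overcorrection (crossed past the reference), scored on a
−3 … +3 grid whose sum is the overall treatment score.

**Synthetic data** (`oxprofile.synthetic`) — a seeded generator for every
input: multivariate-Gaussian subjects with planted correlation structure and
technical replicates, first-order decay traces at published rate presets,
4PL calibration plates, and Y-maze event logs.

## Worked example

```sh
python examples/correlation_profiling.py
```

```
Matrix comparisons (Steiger chi-square on Fisher-z differences):
  WT vs 5xFAD: chi2(21) = 38.69, p = 0.011 (BH-adjusted 0.032)
  WT vs 5xFAD+NAC: chi2(21) = 33.84, p = 0.038 (BH-adjusted 0.048)
  5xFAD vs 5xFAD+NAC: chi2(21) = 32.83, p = 0.048 (BH-adjusted 0.048)

Euclidean distances between groups in Fisher-z space:
              WT  5xFAD  5xFAD+NAC
WT         0.000  2.539      2.375
5xFAD      2.539  0.000      2.339
5xFAD+NAC  2.375  2.339      0.000
Neighbor-joining tree: (WT:1.2875...,5xFAD:1.2517...,5xFAD+NAC:1.0873...);

Treatment-effect classification over all endpoint pairs:
     direction   extent  count
    correction    small      8
overcorrection moderate      4
overcorrection    small      3
overcorrection    large      2
  exacerbation    small      1
  exacerbation moderate      1
    correction moderate      1
     no_effect     none      1

Overall score: +15.5 (positive = net movement of the disease profile back toward reference)
```

The Steiger rows test whether two groups share a population correlation
matrix over the 21 endpoint pairs. The distances quantify how far apart whole
profiles sit in Fisher-z space (here simulated at n = 15/group, so sampling
noise dominates); the tree shows the same three distances as branch lengths.
The classification table tallies, pair by pair, whether the treated group's
correlation moved back toward the reference (correction), further away
(exacerbation), or past it (overcorrection), and the overall score totals the
per-pair scores — positive when treatment, on net, restores the reference
profile.

The other scripts in `examples/` demonstrate each stage (simulation, assay
arithmetic, efflux kinetics, Y-maze scoring, group statistics, and the
end-to-end pipeline). A thin CLI wraps the same functions:
`oxprofile simulate | assay | kinetics | ymaze | stats | profile | run`.

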