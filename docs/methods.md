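# Methods

This note records the statistical procedures, the synthetic-data model
behind the test suite, and the numerical and design choices that were
genuinely open.

## Statistical procedures

**Spearman correlation with asymptotic-t p.** Ties receive average ranks;
rho is the Pearson correlation of the rank vectors and the two-sided
p-value comes from `t = rho·√((n−2)/(1−rho²))` on n−2 degrees of freedom,
matching the convention of R's `cor.test`. |rho| = 1 reports p = 0; a
constant vector makes rho undefined and is returned as missing (NaN),
never raised. Benjamini–Hochberg adjustment is the standard step-up with
monotone enforcement and a cap at 1; note it is *not* idempotent
(re-adjusting multiplies by m/rank again), so adjusted values are treated
as terminal.

**Distance correlation.** The standard (biased) Székely sample estimator
from double-centered pairwise distance matrices. It is positively biased
under independence at finite n: for independent uniforms at n = 200 the
null 95th percentile is ≈ 0.157 (400-draw Monte Carlo). Screening
decisions are therefore never made on dc alone but on its excess over the
dc-versus-SC trend.

**Nonlinearity flagging.** The trend of dc as a function of SC across all
miRNAs is fitted by least-squares cubic B-spline regression with 8
coefficients (interior knots at SC quantiles) — a regression-spline
equivalent of a smoothing spline with 8 effective degrees of freedom,
which the Python stack lacks as a penalized primitive. Because the curve
is meant to track the bulk monotone relation while the flagged points are
exactly the outliers above it, the fit uses two rounds of bisquare
reweighting (scale 6×MAD of residuals). Residual distance is the minimal
Euclidean distance to the curve sampled at 512 equispaced SC values; the
0.02 threshold is read as strictly greater, only points above the curve
are flagged, and flags are restricted to miRNAs altered with age
(BH-adjusted age p < 0.05). Direction is the sign of SC.

**Arm shifts.** Fractions are formed on the linear scale after de-logging
with base 2 (configurable). The criterion "correlation p-value of at
least 0.05" is implemented as p ≤ 0.05: a significance filter, which is
the only reading consistent with the other three criteria selecting
strong, large-range, discordant trends. The fraction-range criterion
defaults to raw per-sample extremes; a per-age-mean variant is available
because single outlier samples otherwise dominate the range.

**Effect sizes.** Cohen's d with pooled sample SD (ddof = 1 variances);
positive d means higher in disease. Windows are inclusive integer ranges
[s, s+9]; a sample contributes to up to ten windows. Controls are always
the healthy group, never pooled other diseases. The min-20 rule produces
missing values, never imputation.

**SOM.** Sequential Kohonen training: codebooks initialized from randomly
drawn data rows, one random row per presentation, best-matching unit by
Euclidean distance, Gaussian neighborhood on the hexagonal plane
embedding (odd-row offset). The learning rate decays linearly 0.05→0.01
over the 10,000 presentations; the neighborhood radius decays linearly
3.0→0.5 (the grid's half-diagonal down to sub-cell, so training ends
nearly winner-take-all). Training with a fixed seed is bit-reproducible.
"Highest expressed" means highest median across all samples. Young/old
strata are [30, 60) and [60, 80): age 60 belongs to old. Condition
clustering uses per-cell mean-effect vectors (complete linkage,
Euclidean), with empty cells carried as 0 in the clustering input but
reported as missing in heat maps.

**Running-sum enrichment.** Steps are +(n−k) for members and −k otherwise
so every curve closes at zero and the statistic is comparable across
category sizes; the statistic is the two-sided maximum |partial sum|. The
exact p-value exploits that the partial sum after i steps with h hits is
`h·n − i·k`, reducing survival ("never reached ±q") to a property of the
lattice point (i, h); a Pascal-type DP with Python integers counts
surviving paths in O(n·k) with no floating-point loss. A V-shaped curve
(negative extremum) has members concentrated at the age-increasing end of
the list, a pyramid at the age-decreasing end.

**Core network.** Filter order matters and is: (a) strong evidence,
(b)/(c) quantile membership, (d) targeting count computed *within the
candidate set remaining after (a)–(c)*, then (e) the trajectory
correlation. Counting targeting within candidates (not the full
interaction database) matches the filter's stated purpose of avoiding
sparsely-targeted proteins in the network being built. The window grid
for trajectory correlations is 40 starts (30…69) while the disease
sliding-window analysis uses 41 (30…70); the two analyses are defined
that way independently and each keeps its own grid. Trajectory Spearman
uses pairwise-complete windows. The "less stringent" mode skips (d).

**Trajectory clusters.** Per-miRNA curves are df = 3 spline fits
(quadratic B-spline basis) on healthy samples only; disease marks use
disjoint 5-year bins anchored at age 30 with a two-sided Wilcoxon test at
an unadjusted alpha of 0.05 — deliberately unadjusted, as a per-bin
descriptive mark rather than an inferential claim.

## The synthetic cohort

The generator emulates the statistical structure the stages assume, not
array technology. Per-miRNA baselines are gamma-distributed on the log2
scale (a few dominant miRNAs, a long tail). Ages are uniform integers on
30–79; group proportions follow the cohort composition the analysis is
designed for (HC 30%, PD 21%, HD 14%, NTLD 13%, LC 12%, OD 9%). Gaussian
noise with SD 1.0 (log2 units) is the default; no missing values are ever
generated, and real-data users must pre-impute.

Planted classes, mutually exclusive by default:

| class | default fraction | signal |
|---|---|---|
| age_up/down_linear | 20% + 20% | slope calibrated to a target \|SC\| drawn per-miRNA from U(0.2, 0.4) — a continuous spectrum with mean 0.3 |
| age_nonlinear_up/down | 1% + 3.5% | quadratic (or logistic) shape, amplitude 2.5×noise SD, orthogonalized against age within the sampled cohort, plus a monotone tilt targeting \|SC\| ≈ 0.2 |
| sex_only | 5% | sex offset of Cohen's d 0.6 |
| disease_only | 5% | group offset whose d decays linearly from 0.8 at age 30 by 80% across the range (U-shaped for PD) |

The slope→SC calibration uses the bivariate-normal relation
r = 2·sin(π·SC/6); for the nonlinear tilt the noise scale is widened by
the curvature's variance contribution, since curvature dilutes rank
correlation like extra noise. The orthogonalization step removes the
linear component the quadratic otherwise acquires when the sampled age
distribution is not exactly symmetric — without it the class-mean SC
drifts with the cohort's age skew. The nonlinear classes carry a solid
monotone tilt on purpose: flagged-nonlinear miRNAs are by construction a
subset of the age-altered set, so a literally tilt-free quadratic could
never be flagged under the altered-with-age restriction.

Arm pairs share a per-sample total (log2 noise SD 0.3) split by a 5′
fraction; switched pairs drift the mean fraction linearly in age by the
switch magnitude (direction alternating), non-switched pairs hold it
constant, and per-sample fraction noise (SD 0.05) is added on top.

Proteins are log10-scale with Gaussian noise (SD 0.3). True regulations
wire hub proteins (≥ 9 targeting miRNAs each) to the empirically most
age-decreasing planted miRNAs, so the pipeline's own bottom-quantile
selection recovers them; the hub trend scales with |coupling| (age-flat
at coupling 0, the null control). Decoy strong-evidence edges point at
age-flat proteins; weak/predicted rows are random. Compound presence is
Bernoulli (base rate 0.35) with 2× bias of age-up miRNAs toward CD19/serum
and age-down toward CD15/RBC.

**What passing tests show — and do not.** Recovery tests demonstrate that
each stage detects exactly the structure it claims to detect, at
realistic effect sizes and cohort scales, with controlled false-positive
behavior. They do not certify performance on real arrays: the generator
has no batch or probe effects, no correlated miRNA families, no
missingness, Gaussian noise, and planted classes that are cleanly
disjoint. Real-data effect estimates will be noisier and the
correlation-cluster boundaries less crisp.

## Problem sizes

Default analysis scale is 800 samples × 1000 miRNAs. Recovery suites run
at n = 500 (association, nonlinearity, arm shifts) and n = 4000
(sliding-window shape, where per-window case counts of ≥ 60 are needed
for |d| > 0.5 counting to be signal- rather than noise-dominated — at 20
cases per window the d standard error of ≈ 0.26 drowns the planted decay;
the analysis is designed for cohorts with hundreds of cases per window).
Network recovery uses 10 seeds at 800 × 1000 with 500 proteins; the exact
p-value is verified against full enumeration for all n ≤ 12 and against
10⁴ permutations at (n = 50, k = 10).

## Known limitations

- The dc trend spline assumes most miRNAs are monotone-or-null; a cohort
  where nonlinear trajectories dominate would bend the baseline upward
  and lose sensitivity (the bisquare reweighting only resists minority
  contamination).
- The exact enrichment p-value conditions on category size k and list
  length n; it does not model inter-miRNA correlation.
- The SOM occupancy and clustering depend on the random presentation
  order; only the seed-fixed run is reproducible, and cross-seed
  stability should be checked on real data.
- Arm-shift criterion 3 with raw per-sample extremes is sensitive to
  outlier samples; the per-age-mean variant is provided but not default.
- The pipeline assumes an already-normalized log-scale matrix; no
  normalization, batch correction or missing-value handling is included.
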