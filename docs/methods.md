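# Methods

`metasieve` quantifies what happens when a research synthesis scores and
selects reported effects by their statistical significance. It implements
the machinery needed to make that critique quantitative: the at-least-one
vote-count score and its expectation, the deterministic effect-size floors
a one-sided filter imposes, a three-level random-effects meta-analysis of
all reported effects, selection-theory summaries (Type M/S error), and the
proportion of effects beyond a threshold. A synthetic-literature generator
provides data with the statistical structure the analysis assumes, so the
whole pipeline is testable end to end.

## Working scale and primitive statistics

All pooling happens on the Fisher z scale, `z = arctanh(r)`, with known
sampling variance `v = 1/(n - 3)`. Significance of a single correlation is
recomputed from `(r, n)` via the exact central-t reference,
`t = r sqrt(n-2)/sqrt(1-r^2)` with `n-2` degrees of freedom; confidence
intervals use the standard Fisher-z normal construction. Reported r-scale
quantities are always `tanh` of z-scale quantities; correlations are never
averaged on the raw scale inside the model (the significance filter's
"simple average of r" is implemented as such because that is the procedure
under critique).

## The filter and its score

The filter policy has two strict thresholds on the one-sided positive
p-value: significant (`p < 0.05`), marginal (`0.05 <= p < 0.10`); any
non-positive correlation is non-significant by the directional rule. A
p-value of exactly 0.05 is therefore marginal, not significant. The
scoring and averaging unit is the (paper, experiment, measure) group;
multi-experiment papers count as separate groups.

The at-least-one score is 1 if any effect in the group is significant, 0.5
if none is significant but some is marginal, and 0 otherwise. Its
expectation for k independent effects with powers `d05`, `d10` at the two
levels is

    E[score] = [1 - (1-d05)^k] + 0.5 [(1-d05)^k - (1-d10)^k],

which rises monotonically in k for *any* true effect — including zero and
negative effects, where the powers degrade to the alpha levels and the
score still climbs toward 1. That is the formal sense in which the score
carries no information about effect size.

The "guaranteed minimum" is the critical correlation
`r_c = t_c / sqrt(t_c^2 + n - 2)` with `t_c` the one-sided central-t
quantile: no retained effect, and hence no filtered group mean, can fall
below the smallest marginal `r_c` among its members.

## Power conventions

Four methods compute the probability that a sample correlation clears
`r_c`: a Fisher-z normal approximation (normal critical value on the z
scale, so the null returns alpha exactly), a noncentral-t approximation
with noncentrality `rho sqrt(n)/sqrt(1-rho^2)` (the default), exact
numerical integration of the sampling density of r, and exact
bivariate-normal Monte Carlo. At `rho = 0.29, n = 24` these give 39.1%,
41.8% and 40.3% (exact) respectively — conventions legitimately differ by
one to two percentage points at small n, with the two approximations
straddling the exact value (gap up to ~0.07 by `|rho| = 0.5` at `n = 20`).
The Monte Carlo method is the arbiter in tests; the default is the
noncentral-t convention.

## Three-level model

For effect j in cluster i (cluster = paper, or paper-experiment for
multi-experiment papers):

    z_ij = mu + u_i + w_ij + e_ij,
    u_i ~ N(0, tau1^2),  w_ij ~ N(0, tau2^2),  e_ij ~ N(0, v_ij).

Variance components are estimated by REML. The cluster covariance
`tau1^2 J + diag(tau2^2 + v)` is inverted by a rank-one update, so each
objective evaluation is linear in the number of effects; the profile over
`(tau1^2, tau2^2)` is minimized by bounded L-BFGS-B from three starting
points (a moment split, a flatter split, and the boundary), keeping the
best, with non-negativity enforced by the bounds and objective tolerance
1e-8. All-identical data returns tau = 0 without error; clusters of size 1
are allowed (with one effect per cluster the tau1/tau2 split is not
identified, and a component can be pinned via `fix_tau1`/`fix_tau2`).

Inference on `mu` uses CR2 cluster-robust variance: adjustment matrices
`A_j` solving `A_j B_j A_j = V_j` with `B_j = V_j - 1 1'/S`
(`S = sum_j 1'V_j^{-1} 1`), which for the intercept-only generalized
least-squares fit is the exact block form of the usual
`(I-H) Phi (I-H)'` working-model target, computed via a symmetric
pseudo-inverse square root. Satterthwaite degrees of freedom come from
`tr(G)^2/tr(G^2)` with `G = diag(c_j' V_j c_j) - a a'/S`, the covariance
of the per-cluster score contributions under the working model; df never
exceeds clusters − 1. The implementation is verified against a dense
brute-force construction and, during development, matched `metafor`'s
`rma.mv` REML point estimates to seven decimals.

The prediction interval is `mu ± t_df sqrt(tau1^2 + tau2^2 + se^2)` with
df = clusters − 2 (the standard convention; configurable) and the robust
SE. I² is `100 tau^2/(tau^2 + v_typ)` with `v_typ` the Higgins–Thompson
typical sampling variance from the inverse-variance weights.

The working sampling covariance between same-paper effects is absorbed by
`tau2` plus robust SEs rather than an imputed correlation matrix; sources
rarely report the information needed for more.

## Selection theory

On the z scale the filtered mean at a single truncation point is the
lower-truncated normal mean `mu + sd phi(a)/(1-Phi(a))`, computed via a
log-space Mills ratio. `simulate_selection` draws exact bivariate-normal
sample correlations (sharp truncation boundaries make the z-scale
approximation visibly biased, so the exact law is the default), applies
the classifier, and summarizes retention, the retained mean, Type M
(retained mean over truth) and Type S (wrong-sign fraction, identically 0
for a positive-direction filter at positive truth — a property of the
filter, not of the world).

## Threshold proportions

Calibrated per-effect estimates shrink each observed z toward the pooled
mean, `theta = mu + sqrt(tau^2/(tau^2+v)) (z - mu)`; the fraction of
calibrated estimates below `arctanh(q_r)` estimates the proportion of true
effects below a threshold stated on the r scale. A parametric normal
version and the raw count of observed effects are reported alongside,
since printed proportions in the literature are often ambiguous between
conventions. Bootstrap intervals resample clusters with replacement
(effects within papers are dependent), refit the model on each resample,
and take percentile quantiles; default 1000 replicates, fully seeded.

## Synthetic literatures

The generator draws, per paper, one measure label
(SAGAT/SPAM/EndOfTrial, weights 0.5/0.2/0.3 — a plausible mix, not a
claim of fidelity), a group size k from a shifted negative binomial
(size 0.5, mean 241/38 ≈ 6.34; median 3 — matching the reported medians
with a heavy right tail), and per-effect sample sizes from a discretized
lognormal with median 24, log-scale sigma 0.65, truncated to [4, 200]
(small-sample-dominated with occasional large studies, as is typical of
this literature). True effects follow the three-level model at
`mu_z = 0.30, tau1 = 0.21, tau2 = 0.11`; observed correlations are exact
bivariate-normal sample correlations at `rho = tanh(true z)`. The ghost
filter drops (or flags) each non-significant effect with a set
probability, never touching significant ones.

What the generator does *not* emulate: skewness or excess small effects in
the real effect distribution, overfit or team-level results, covariates,
and the empirical joint distribution of (k, N) beyond the summary
statistics above. Two consequences are visible in the reproduction
numbers: the proportion of effects below the overall filtered mean comes
out near 80% (a Gaussian truth with pooled mean 0.29 and total tau 0.24
cannot place 92% of effects below 0.46 — that figure reflects the shape
of the real data), and I² lands near 57–61% rather than ~71% because I²
depends on the full sample-size distribution, of which only the median is
reproduced. Passing tests therefore demonstrate correctness of the
machinery under the assumed model, not distributional fidelity to any
particular deposited dataset.

## Reproduction problem sizes

The acceptance script reports desk-scale quantities analytically and
dataset-scale quantities as medians over 25 simulated literatures
(~240 effects each). The test suite's recovery and coverage harness uses
500 literatures (medians taken over the first 200 for recovery), Monte
Carlo scoring uses 1e5 paper-groups, and power Monte Carlo up to 4e5
draws — sizes at which the binomial/MC standard errors are comfortably
below the tolerances asserted.

## Determinism

Every stochastic routine takes a seed and flows all randomness through one
`numpy` generator. Report bundles embed the input's SHA-256, the seed and
the package version rather than a wall-clock timestamp, so identical input
and configuration produce byte-identical JSON.

## Known limitations

- The bootstrap is percentile-only (no BCa); coverage of the threshold
  proportion CI is not separately calibrated.
- The constant working-correlation option for sampling errors is not
  implemented; dependence is handled by tau2 plus CR2 robust SEs.
- Effect-size conversion from other statistics (d, F, chi-square) is out
  of scope; inputs are correlations.
- With very small cluster counts (< ~10) the Satterthwaite df can be
  small and intervals wide; that is by design, not a defect.
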