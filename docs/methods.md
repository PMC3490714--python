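# Methods

This note documents the statistical machinery behind starchnet: the
models and their assumptions, the defaults that matter, what the
synthetic-data generators do and do not emulate, and the numerical
choices made where the design was genuinely open.

## Time-course significance testing

Each gene's profile over the diurnal course is tested against the null of
no temporal change. The alternative model is a natural cubic spline of
time with `df` basis dimensions (default 3) plus an intercept; knots sit
at quantiles of the distinct sampling times and the basis has zero second
derivatives beyond the boundary knots (the truncated-power construction).
Arrays are placed on a single 24-h axis: hours-in-darkness as given,
hours-in-light offset by the dark-period length.

The two fits are compared by

    F = ((RSS0 - RSS1)/df) / (RSS1/(n - df - 1)),

with F = +inf when the spline fit is exact and the flat fit is not, and
F = 0 for zero-variance genes (which get p = 1 rather than an error, so
all-constant inputs flow through). P-values are computed by permuting
array labels, identically across genes within each permutation:
p = (1 + #{F_perm >= F_obs}) / (1 + n_perm), so the smallest attainable
p is 1/(1 + n_perm). Permutation is the default because n is ~10 and
residual normality is not guaranteed; parametric F(df, n-df-1) p-values
are available via `mode="parametric"`.

Multiple testing uses Storey q-values with the single-lambda plug-in
pi0 = #{p > 0.5} / (m/2), clamped to (0, 1]; passing `pi0=1` recovers
Benjamini–Hochberg. Genes pass at q <= 0.01 by default.

A caveat worth knowing: a smooth spline alternative has limited power
against profiles whose only feature is a one-sample transient (the C/D
shapes below). The synthetic suite makes this conservatism visible; it is
a property of the spline alternative, not a defect of the permutation
scheme.

## Clustering and light/dark response groups

Profiles are standardized per gene (mean 0, sd 1; zero-variance genes
become zero vectors and are flagged) and clustered with k-means
(k-means++ initialization, 10 restarts, seed-controlled; default k = 30).
Standardization is the default because group membership should reflect
shape, not amplitude.

Each cluster centroid is assigned one of four diurnal response groups by
an explicit rule (the historical practice of eyeballing cluster panels is
replaced by quantitative defaults):

* let c = Pearson correlation of the centroid with the light indicator
  (light = 1, dark = 0) and d = the standardized centroid change across
  the dark-to-light transition (first light array minus last dark array,
  in centroid-sd units);
* A if c <= -tau (dark-induced), B if c >= tau (light-induced);
* otherwise C if d > delta (positive transition transient), else D.

Defaults tau = 0.5, delta = 0.5. The label is invariant to adding a
constant to the centroid and to positive rescaling. A perfectly flat
centroid is labeled D (no step, no light response).

## Small-sample graphical Gaussian model

An edge in a GGM means nonzero partial correlation between two genes
given all others. With p genes >> n arrays the sample covariance is
singular, so the sample correlation R is shrunk toward the identity,

    R* = (1 - lambda) R + lambda I,

with the analytic Schäfer–Strimmer intensity
lambda = sum Var(r_ij) / sum r_ij^2 over distinct pairs, clamped to
[0, 1]; Var(r_ij) is the unbiased estimate from standardized
cross-products. Partial correlations come from the standardized inverse
of R*: pcor_ij = -s_ij / sqrt(s_ii s_jj). The closed-form three-variable
identity pr_xy.z = (r_xy - r_xz r_yz)/sqrt((1-r_xz^2)(1-r_yz^2)) is used
as a permanent cross-oracle in the tests: both routes must agree to
1e-10 on random 3x3 instances.

Note that lambda saturates at 1 on data with no correlation structure at
small n; all partial correlations are then exactly zero and every pair
gets p = 1. This is the correct conservative limit, not an error.

### Edge significance

Observed partial correlations are modeled as the two-component mixture

    f(r) = eta0 f0(r; kappa) + (1 - eta0) fA(r),

where f0(r; kappa) = (1-r^2)^((kappa-3)/2) Gamma(kappa/2) /
(sqrt(pi) Gamma((kappa-1)/2)) is the null density of a partial
correlation with kappa effective degrees of freedom — equivalently
(r+1)/2 ~ Beta((kappa-1)/2, (kappa-1)/2), so kappa = 3 is the uniform
density on [-1, 1] and the null sd is approximately 1/sqrt(kappa).

The default fit is an empirical-null, censored (central-matching)
estimate: kappa is fitted by truncated maximum likelihood on the central
75% of |r| — where genuine edges contribute little — and eta0 follows by
matching the observed central mass to the null's mass there. The
alternative full-mixture maximum likelihood with a uniform fA
(`method="ml"`) is also provided, but when genuine edges concentrate at
moderate |r| rather than spreading over [-1, 1], the diffuse-alternative
likelihood prefers to absorb them into a widened null, which costs
substantial power; the censored fit avoids this failure mode and is the
approach the established empirical-null tooling in this area uses. The
kappa search grid is log-spaced over [3, max(2000, 10/var(r))] with 200
points (the adaptive ceiling matters after strong shrinkage, where the
observed spread can imply kappa in the tens of thousands); ties prefer
larger kappa, the more conservative null.

Two-sided p-values are p = 2(1 - F0(|pcor|; kappa)) via the Beta CDF,
q-values use the same Storey transform as the time-course stage, and
edges are the pairs with q <= 0.05 (default). Self-pairs are never
tested. With p = 2 genes the partial correlation equals the marginal
correlation and no mixture can be fitted; that degenerate case raises.

## Network topology

The selected edges form a simple undirected graph with signed edges
(sign of the partial correlation) and role-annotated nodes. Clock genes
count as regulators for edge typing, giving three types —
regulator–regulator, regulator–target, target–target — whose counts sum
to the edge total. The hub is the maximum-degree node (ties broken
lexicographically for the canonical hub; all tied nodes reported). The
first-neighbor subnetwork around a seed set is the induced subgraph on
seeds plus their direct neighbors, keeping edgeless seeds as isolated
nodes; extraction is idempotent. Edge overlap between two networks is
reported per type as |E1 ∩ E2| / |E1| with the reference graph stated.

## Candidate-regulator ranking

Regulator–target edges are refined against a condition-independent
co-expression compendium. For each target, regulators are sorted by
correlation with descending competition ranks (ties share the smaller
rank) overall, among regulators, and within the regulator's family.
A candidate passes the co-expression cutoff iff

    corr > mean + t_{conf, n-1} * sd

over the population of regulator–target correlations for that target
(treated as normal; confidence default 0.975). The population statistics
exclude the candidate's own value (leave-one-out), which keeps the
nominal 2.5% tail exact for null candidates; with the candidate included
the cutoff becomes mildly conservative. The population is the regulator
set, not all genes (configurable upstream by what the compendium
contains).

The temporal precedence filter estimates the signed circular lag between
regulator and target profiles by cross-correlation on the shared diurnal
grid (the shorter signed direction around the 24-h cycle) and passes the
candidate iff the regulator peaks at or before the target. Flat profiles
pass with a warning. Circular cross-correlation was chosen over the raw
profile argmax because a 10-point grid plateaus easily.

Binding-site support joins by (regulator family, target): Y/N from the
table, NA when the pair is absent. Final candidates must pass both the
co-expression cutoff and precedence; binding support is evidence, never
a requirement. The two filters commute.

## Morphometrics

Circularity = 4 pi area / perimeter^2, clamped at 1 (the isoperimetric
bound; measurement round-off can land a hair above it). Mann–Whitney U
uses midranks for ties; the exact two-sided p is
P(|U - n_x n_y / 2| >= observed) by full enumeration of label
assignments, used automatically when the pooled size is at most 12;
larger samples use the normal approximation with tie and continuity
corrections. Both are reported because which variant historical analyses
used is often unstated. Relative mean ranks (group means of pooled
midranks) accompany every test as the effect summary, and granule counts
are summarized per line as normalized histograms, windowed shares, and
the mean chloroplast area at each count.

## Synthetic data: what it emulates, and what it does not

`make_sparse_ggm` builds a precision matrix Omega = I - M, where M holds
the desired partial correlations (random signs, requested magnitude) on
a random sparse support, so the planted partial correlations are exact
by construction. If the smallest eigenvalue of Omega falls below 0.05
the off-diagonal block is scaled down (diluting the magnitude, tracked
in `true_pcor`); a dilution past half the requested magnitude raises as
infeasible. Residuals are multivariate normal with this dependence and
unit marginal variances.

`simulate_diurnal_matrix` adds group mean shapes on the study grid
(1, 2, 4, 8, 12 h in darkness, then in light; 10 arrays, optionally
replicated): A = high in darkness, B = high in light, C/D = flat with a
±1 transient at the first post-transition sample. The transient is
confined to one sample so the C/D shapes stay essentially uncorrelated
with the phase indicator — their defining feature. Defaults: amplitude
1.0 and residual sd 0.25, i.e. strongly regulated genes at a typical
log2-scale noise level, with an effect-to-noise ratio of 4.

`make_compendium` plants regulator–target correlations ~ N(0.5, 0.15)
among N(0, 0.15) decoys (40 per target by default).
`make_morphology` draws chloroplast cross-sections as random ellipses
(log-normal size, Ramanujan's second perimeter approximation) with the
mutant line's area scaled to 0.7 and a more elongated axis ratio, and
line-specific granule-count distributions concentrating wild-type mass
on 1–4 granules and mutant mass on 2–5.

What passing tests on these generators shows: correct calibration and
recovery **under the model** — Gaussian residuals, exact planted
sparsity, noiseless group shapes. What they do not show: robustness to
heavy-tailed expression noise, probe-level artifacts, normalization
residue, amplitude heterogeneity within groups, or non-stationary
diurnal waveforms. Real-data edge counts therefore cannot be compared
against these simulations, only the procedure's operating
characteristics.

## Numerical and scale choices

* All randomness flows through `numpy.random.default_rng(seed)`; every
  generator is a pure function of (parameters, seed), and the CLI's
  `--seed` makes repeated runs byte-identical.
* Simulation sizes in the statistical suite (50 null replicates at
  p = 30 / n = 20; 20 seeds for edge recovery at p = 20; 200 seeds for
  ranking; m = 5000 for mixture recovery) were chosen so binomial /
  sampling error is small relative to the margins being tested while the
  whole suite stays interactive (~10 s).
* Degenerate inputs are first-class: zero-variance genes (flat p = 1 in
  DE, zero vectors in clustering, explicit drop-or-raise in correlation),
  lambda = 1 shrinkage (all-null network), empty networks (valid empty
  files), missing compendium pairs (warned and skipped), flat profiles in
  the precedence filter (pass with warning).

## Known limitations

* The spline F-test is conservative against single-sample transients
  (see above).
* The censored mixture fit assumes genuine edges are a minority outside
  the central bulk; networks where most pairs are truly connected would
  bias kappa upward and lose power.
* The precedence filter resolves lag only to the sampling grid, which is
  uneven (1, 2, 4, 8, 12 h); sub-grid timing differences are invisible.
* Partial correlations measure conditional linear association;
  directionality and causality are outside the model.
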