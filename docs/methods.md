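# Methods

## The problem

Microbiome count tables carry technical variation in library size (total
reads per sample) that must be removed before differential-abundance
testing. Many normalizations exist — rarefaction, total sum scaling
(TSS), cumulative sum scaling (CSS), the centered log-ratio transform
(CLR) — and each implicitly assumes a different relationship between a
taxon and the outcome. Any of them yields a *valid* test, but the one
with the best power depends on the unknown truth and can differ across
taxa. `omninorm` runs the chosen association test under several
normalizations at once and aggregates the per-normalization p-values for
each taxon into one omnibus p-value, so the analyst does not have to
pick.

## The omnibus combiner

For taxon k let p_{j,k} be the p-value under normalization j,
j = 1…J. The Cauchy combination statistic is

    T_k = (1/J) Σ_j tan{(0.5 − p_{j,k}) π},

which is approximately standard Cauchy under the null for *arbitrary*
dependence among the p_{j,k} — essential here, since the J analyses
re-use the same data. The omnibus p-value is p_k = 1/2 − arctan(T_k)/π.
Because a single component near 1 forces the plain combination to 1,
the pipeline uses the truncated variant: each p_{j,k} is capped at
1 − ε (ε = 0.01 by default) before combining, bounding p_k away
from 1. Truncation deliberately distorts the extreme upper tail of the
null distribution of p_k (its CDF sits ~0.02 above the diagonal at
level 0.95); significance calls at any usable α are unaffected, and the
small-p tail is calibrated to Monte-Carlo accuracy.

Numerical guards: tan{(0.5 − p)π} is evaluated as 1/(πp) for
p < 1e-15; the survival function uses the tail form 1/(πT) for
|T| > 1e15; exact-zero inputs are floored at 1e-300 with a warning.
Weights other than uniform 1/J are supported but unused by the CLI.

Per-taxon omnibus p-values are converted to Benjamini–Hochberg q-values;
the shipped default false-discovery-rate target is 20%.

## Normalizations

All five strategies are per-sample transforms:

- **none** — raw counts.
- **rarefaction** — one multivariate-hypergeometric subsample per sample
  to a common depth (default: the minimum library size), seeded;
  `rarefy_average(k)` (mean of k draws) exists for building smooth
  starting data but is not part of the testing pipeline.
- **tss** — counts divided by library size; rows sum to 1.
- **css** — counts divided by the sample's cumulative sum up to a cutoff
  quantile of its *nonzero* counts. The cutoff is the lower
  nearest-rank empirical quantile (value at position ⌈q·m⌉ of the m
  sorted nonzero counts) at level 0.5 by default; the adaptive cutoff
  search of the original CSS method is intentionally not implemented —
  a fixed, configurable quantile is deterministic and testable. The
  result is rescaled by the median of the per-sample sums (or a fixed
  constant).
- **clr** — log(x + c) centered by the sample's mean log, with
  pseudocount c = 0.5 by default (additive smoothing is the common
  convention for zeros; the choice is configurable). Rows sum to 0.

## Association tests

Normalized abundance is the *response*; the outcome of interest v and
optional covariates Z are predictors.

**linear** — OLS of y on (1, v, Z), two-sided t-test on the v
coefficient. Degenerate responses (constant y) return p = 1 so the
p-value matrix stays rectangular.

**qrank** — at each quantile level τ in a grid (default
{0.1, 0.25, 0.5, 0.75, 0.9}) the null quantile regression of y on
(1, Z) yields regression rank scores a_i(τ) ∈ [0, 1] — the dual LP
solution, computed analytically for intercept-only designs and by
linear programming (HiGHS) otherwise. The score test statistic is

    S_τ = v*' (a(τ) − (1 − τ)),   S_τ² / {τ(1−τ) ‖v*‖²} ~ χ²₁,

with v* the outcome residualized against the null design. For
continuous data a_i(τ) is the indicator form τ − 1{y_i ≤ fitted
quantile}; the dual's fractional scores at ties are what keep the test
calibrated on zero-inflated, heavily tied counts (the indicator
shortcut measured 7–8× the nominal size at α = 0.01 in our null
benchmark; the dual version is slightly conservative instead, because
τ(1−τ) over-states the score variance inside a point mass). The per-τ
p-values are combined with the *untruncated* Cauchy combination —
internal components are clipped into (1e-300, 1 − 1e-12) first, since
discrete data can make a χ² statistic exactly zero.

**zinq** — two parts: a likelihood-ratio test of v in the logistic
model for presence logit P(y > 0) ~ 1 + v + Z, plus the qrank per-τ
p-values computed on the strictly positive subsample; all components
are Cauchy-combined. If presence is constant the zero part is dropped
(all-positive y reduces exactly to qrank on the full data); with fewer
than 10 positive observations the positive part is dropped; with no
usable component the test returns p = 1 with a warning. Under CLR —
which has no zeros — presence is taken from the raw counts and the
positive part uses the CLR values of the present samples.

**krv** — community-level test between a microbiome kernel K and a
genotype kernel L: KRV = tr(K̃L̃)/√(tr(K̃K̃)·tr(L̃L̃)) with K̃, L̃
double-centered. K is the Bray–Curtis dissimilarity converted by Gower
double-centering (K = −½HD²H) with negative eigenvalues truncated to
zero; CLR input is rejected because Bray–Curtis requires nonnegative
abundances. L defaults to a linear kernel on per-SNP standardized
genotypes, PSD-corrected the same way. The p-value is by permutation
(default 999; (1 + #{≥ observed})/(1 + n_perm)), chosen over the
Pearson-III moment approximation for its exact finite-sample
exchangeability and absence of analytic edge cases; `krv_exhaustive`
enumerates all permutations for n ≤ 8.

## Synthetic benchmark designs

The generators exist so the whole pipeline can be validated with no
external data. They emulate the *statistical structure* of real
16S/metagenomic studies, not any particular cohort.

**Two-group (single differentially abundant taxon).** The focal taxon
is zero-inflated negative-binomial per group (defaults: 300
samples/group, 30% structural zeros, positive-part means 5 vs 50,
dispersion 1 — a strongly differential, heavily overdispersed genus). A
mixing proportion δ redraws ⌊δn⌋ samples of each group from the other
group's distribution; δ = 0.5 makes the groups identical, so power
collapses to size. Because every normalization is degenerate on a
one-taxon table (TSS ≡ 1, CLR ≡ 0), the table also carries 20 null
background taxa (NB mean 30) that give samples realistic, variable
library sizes; a study that samples each normalization's empirical
distribution directly from real data does not need this, a count-level
generator does.

**Two-part quantile (covariate-adjusted).** Presence
D ~ Bernoulli(expit(γ'x)) with x = (1, outcome, age, activity, diet);
given D = 1 the count is the conditional quantile Q(u|x) at u ~ U(0,1),
linearly interpolated over a τ-grid of 0.01…0.99 and rounded, floored
at 1 so presence implies a positive count (the rounding/zero collision
is otherwise undefined). Default coefficient processes: lognormal(3, 1)
quantile function as the intercept, constant covariate coefficients —
constants keep every conditional quantile function monotone, which the
generator verifies per sample and enforces with an error. The null sets
the outcome coefficients of both parts to zero. Covariates are
parametric by default (binary outcome, age ~ N(40, 5), standardized
activity and diet scores) or resampled with replacement from
user-supplied pools.

**Dirichlet-multinomial with a genetic effect.** Composition per sample
~ Dirichlet(α), counts ~ Multinomial(library, composition); the default
α has log-normal-decay rank abundances (σ = 2) with total concentration
50 over 100 OTUs — the overdispersion magnitude typical of
upper-respiratory 16S tables — and libraries ~ NB(mean 1000). Genotypes
are independent Binomial(2, MAF) per SNP (MAF default 0.3, bounded
below at 0.05 as in causal-common-SNP selection); linkage structure is
not simulated — a documented fidelity gap that does not affect KRV's
validity, which rests on exchangeability. Under the alternative the
counts of the ηth–20th most common OTUs (η default 14, ranked by total
abundance in the generated table) are multiplied by f_i = 1 + 1.7·g_i
and rounded.

**Rejection-rate estimation.** `estimate_rejection_rate` runs
generator → pipeline per replicate with counter-derived sub-seeds
(`SeedSequence(master, spawn_key=(i,))`), so every replicate is
independent and individually replayable, and reports per-method rates
with MC-SE = √(r(1−r)/n).

## Problem sizes and tolerances

The shipped checks run the designs at desk scale: 150–2000 replicates
per design (the omnibus pipeline per replicate), KRV at n = 100 samples
× 100 OTUs with 199 permutations inside Monte-Carlo loops. Size checks
assert |rate − α| ≤ 3·MC-SE; power-ordering checks allow 2·MC-SE.
Exactness checks (Cauchy identities, CSS worked example, exhaustive KRV
enumeration) are at 1e-10–1e-12.

## Known limitations

- The two-group and two-part generators are parametric stand-ins; they
  reproduce zero-inflation, overdispersion and covariate structure but
  not the empirical distribution of any real cohort, so power numbers
  are comparable across normalizations within a run, not across
  studies. Passing tests demonstrate calibration and ordering
  properties, not the power values of any published table.
- CSS uses a fixed cutoff quantile, not the original adaptive search.
- The BH procedure assumes the usual positive-dependence conditions;
  the omnibus p-values inherit whatever dependence the taxa carry.
- KRV covariate adjustment is not implemented; genotype kernels other
  than the standardized linear kernel are left to the caller (any PSD
  matrix is accepted).
- BIOM binary/HDF5 is not parsed; convert with
  `biom convert -i table.biom -o table.tsv --to-tsv` and read with
  `orientation="taxa_in_rows"`.
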