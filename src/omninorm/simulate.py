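"""Synthetic-data generators and the rejection-rate estimator.

Three generators mirror the statistical structure of the benchmark
designs used to validate the omnibus pipeline:

* :func:`gen_two_group` — a focal taxon with zero-inflated
  negative-binomial abundances in two outcome groups, optionally mixed
  by a proportion delta (delta = 0.5 makes the groups identical), plus
  null background taxa so that library sizes vary and normalizations are
  non-degenerate.
* :func:`gen_two_part_quantile` — a focal taxon from a covariate-
  dependent two-part model: logistic presence, then a conditional
  quantile process sampled by the inverse-CDF method.
* :func:`gen_dm_genetic` — a Dirichlet-multinomial OTU table with an
  optional genotype-driven multiplicative effect on a window of the
  most common OTUs, for the community-level kernel test.

:func:`estimate_rejection_rate` runs a full normalize-test-combine
pipeline over replicates with independently spawned sub-seeds and
reports empirical rejection rates with Monte-Carlo standard errors.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from omninorm.data_model import CountMatrix, SampleMetadata
from omninorm.normalize import NormalizationParams, apply_all
from omninorm.assoc_tests import (
    TauGrid,
    bray_curtis_kernel,
    krv_test,
    linear_genotype_kernel,
    linear_test,
    qrank_test,
    zinq_test,
)
from omninorm.omnibus import truncated_cauchy_combine


def _child_seed_sequence(master_seed: int, index: int) -> np.random.SeedSequence:
    """Counter-based sub-seed: replicate i is replayable from (seed, i)."""
    return np.random.SeedSequence(master_seed, spawn_key=(index,))


# ---------------------------------------------------------------------------
# Setting-1-style: two-group zero-inflated abundances
# ---------------------------------------------------------------------------


@dataclass
class TwoGroupSpec:
    """Two-group zero-inflated negative-binomial design for one focal taxon.

    delta is the mixing proportion: floor(delta * n) samples of each
    group are redrawn from the other group's distribution, so delta = 0.5
    makes the two groups distributionally identical. Background taxa are
    null (same distribution in both groups) and exist to give samples
    realistic, variable library sizes.
    """

    n_per_group: int = 300
    delta: float = 0.0
    pi0: tuple = (0.3, 0.3)            # zero-inflation probability per group
    nb_mean: tuple = (5.0, 50.0)       # positive-part NB mean per group
    nb_dispersion: tuple = (1.0, 1.0)  # NB size parameter per group
    n_background: int = 20
    background_mean: float = 30.0
    background_dispersion: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.delta <= 0.5):
            raise ValueError("delta must lie in [0, 0.5]")
        if any(not (0.0 <= p < 1.0) for p in self.pi0):
            raise ValueError("pi0 must lie in [0, 1)")


def _zinb(rng: np.random.Generator, n: int, pi0: float, mean: float, size: float) -> np.ndarray:
    zeros = rng.random(n) < pi0
    p_nb = size / (size + mean)
    counts = rng.negative_binomial(size, p_nb, n)
    counts[zeros] = 0
    return counts


def gen_two_group(spec: TwoGroupSpec) -> tuple[CountMatrix, SampleMetadata]:
    """Generate a two-group single-focal-taxon table with null background."""
    rng = np.random.default_rng(spec.seed)
    n = spec.n_per_group
    group = np.repeat([0, 1], n)
    # effective generating group after mixing: floor(delta*n) of each
    # label are redrawn from the other group's distribution
    eff = group.copy()
    n_mix = int(np.floor(spec.delta * n))
    if n_mix > 0:
        for g in (0, 1):
            idx = np.nonzero(group == g)[0]
            swap = rng.choice(idx, size=n_mix, replace=False)
            eff[swap] = 1 - g
    focal = np.empty(2 * n, dtype=np.int64)
    for g in (0, 1):
        sel = eff == g
        focal[sel] = _zinb(
            rng, int(sel.sum()), spec.pi0[g], spec.nb_mean[g], spec.nb_dispersion[g]
        )
    cols = [focal]
    taxon_ids = ["focal"]
    if spec.n_background > 0:
        p_nb = spec.background_dispersion / (spec.background_dispersion + spec.background_mean)
        bg = rng.negative_binomial(
            spec.background_dispersion, p_nb, size=(2 * n, spec.n_background)
        )
        cols.append(bg)
        taxon_ids += [f"bg_{j}" for j in range(1, spec.n_background + 1)]
    values = np.column_stack(cols)
    # guard against the (vanishingly rare) all-zero sample
    empty = values.sum(axis=1) == 0
    if np.any(empty):
        values[empty, 0] += 1
    sample_ids = [f"s{i}" for i in range(2 * n)]
    X = CountMatrix(values, sample_ids, taxon_ids)
    meta = SampleMetadata(sample_ids, group.astype(float), None, outcome_name="group")
    return X, meta


# ---------------------------------------------------------------------------
# Setting-2-style: covariate-dependent two-part quantile process
# ---------------------------------------------------------------------------


def _default_tau_grid() -> np.ndarray:
    return np.round(np.arange(0.01, 1.0, 0.01), 2)


def _default_beta_matrix(tau_grid: np.ndarray, effect: float) -> np.ndarray:
    """Default quantile-process coefficients on the tau grid.

    The intercept process is the lognormal(3, 1) quantile function (a
    right-skewed count scale typical of genus abundances); covariate
    coefficients are constant in tau, which keeps every conditional
    quantile function monotone as long as the intercept process is.
    Column order: intercept, outcome, age, activity, diet.
    """
    from scipy import stats

    beta = np.zeros((tau_grid.size, 5))
    beta[:, 0] = stats.lognorm.ppf(tau_grid, s=1.0, scale=np.exp(3.0))
    beta[:, 1] = effect
    beta[:, 2] = 0.05
    beta[:, 3] = 1.0
    beta[:, 4] = 0.5
    return beta


@dataclass
class TwoPartQuantileSpec:
    """Two-part (presence + conditional-quantile) count generator.

    gamma are the logistic presence coefficients and beta the quantile-
    process coefficients evaluated on tau_grid, both ordered (intercept,
    outcome, age, physical activity, diet score). Setting effect=False
    zeroes the outcome coefficients in both parts (the null). Covariates
    come from parametric defaults or user-supplied resampling pools.
    """

    n: int = 500
    effect: bool = False
    gamma: np.ndarray | None = None
    beta: np.ndarray | None = None
    tau_grid: np.ndarray | None = None
    gamma_effect: float = 0.5   # outcome coefficient in the presence model
    beta_effect: float = 6.0    # outcome coefficient in the quantile process
    covariate_pools: dict | None = None
    n_background: int = 20
    background_mean: float = 30.0
    background_dispersion: float = 1.0
    seed: int = 0

    def resolve(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        tau = self.tau_grid if self.tau_grid is not None else _default_tau_grid()
        tau = np.asarray(tau, dtype=float)
        if np.any(np.diff(tau) <= 0) or tau.min() <= 0 or tau.max() >= 1:
            raise ValueError("tau_grid must be strictly increasing inside (0, 1)")
        g_eff = self.gamma_effect if self.effect else 0.0
        b_eff = self.beta_effect if self.effect else 0.0
        gamma = (
            np.asarray(self.gamma, float)
            if self.gamma is not None
            else np.array([-0.5, g_eff, 0.02, 0.3, 0.2])
        )
        beta = (
            np.asarray(self.beta, float)
            if self.beta is not None
            else _default_beta_matrix(tau, b_eff)
        )
        if beta.shape != (tau.size, gamma.size):
            raise ValueError("beta must have shape (len(tau_grid), len(gamma))")
        return tau, gamma, beta


def _draw_covariates(spec: TwoPartQuantileSpec, rng: np.random.Generator) -> np.ndarray:
    """Outcome + covariates, columns (outcome, age, activity, diet)."""
    n = spec.n
    if spec.covariate_pools is not None:
        pools = spec.covariate_pools
        cols = [
            rng.choice(np.asarray(pools[name], float), size=n, replace=True)
            for name in ("outcome", "age", "activity", "diet")
        ]
        return np.column_stack(cols)
    outcome = rng.binomial(1, 0.5, n).astype(float)
    age = rng.normal(40.0, 5.0, n)
    activity = rng.normal(0.0, 1.0, n)
    diet = rng.normal(0.0, 1.0, n)
    return np.column_stack([outcome, age, activity, diet])


def gen_two_part_quantile(spec: TwoPartQuantileSpec) -> tuple[CountMatrix, SampleMetadata]:
    """Simulate a focal taxon from the two-part quantile model.

    Presence D ~ Bernoulli(expit(gamma' x)); given presence, the count is
    Q(u | x) for u ~ U(0, 1) by linear interpolation of the quantile
    process over the tau grid, rounded to the nearest integer and floored
    at 1 so that D = 1 always implies a positive count.
    """
    tau, gamma, beta = spec.resolve()
    rng = np.random.default_rng(spec.seed)
    Xcov = _draw_covariates(spec, rng)
    design = np.column_stack([np.ones(spec.n), Xcov])
    # conditional quantile values for every sample on the full grid
    Q = design @ beta.T  # (n, len(tau))
    bad = np.nonzero(np.any(np.diff(Q, axis=1) < -1e-9, axis=1))[0]
    if bad.size:
        raise ValueError(
            f"non-monotone conditional quantile function for covariate row(s) {bad[:5].tolist()}"
        )
    D = rng.random(spec.n) < expit(design @ gamma)
    u = rng.random(spec.n)
    y_cont = np.array(
        [np.interp(u[i], tau, Q[i]) for i in range(spec.n)]
    )
    focal = np.where(D, np.maximum(np.rint(y_cont), 1.0), 0.0).astype(np.int64)
    focal = np.maximum(focal, 0)
    cols = [focal]
    taxon_ids = ["focal"]
    if spec.n_background > 0:
        p_nb = spec.background_dispersion / (spec.background_dispersion + spec.background_mean)
        bg = rng.negative_binomial(
            spec.background_dispersion, p_nb, size=(spec.n, spec.n_background)
        )
        cols.append(bg)
        taxon_ids += [f"bg_{j}" for j in range(1, spec.n_background + 1)]
    values = np.column_stack(cols)
    empty = values.sum(axis=1) == 0
    if np.any(empty):
        values[empty, 0] += 1
    sample_ids = [f"s{i}" for i in range(spec.n)]
    X = CountMatrix(values, sample_ids, taxon_ids)
    meta = SampleMetadata(
        sample_ids,
        Xcov[:, 0],
        Xcov[:, 1:],
        outcome_name="outcome",
        covariate_names=["age", "activity", "diet"],
    )
    return X, meta


# ---------------------------------------------------------------------------
# Setting-3-style: Dirichlet-multinomial OTU table with a genetic effect
# ---------------------------------------------------------------------------


def _default_alpha(p_otu: int, total_concentration: float = 50.0, sigma: float = 2.0) -> np.ndarray:
    """Synthetic concentration vector with log-normal-decay abundances.

    Rank-abundance weights exp(sigma * z_r) with z_r the standard-normal
    quantiles of the rank midpoints, normalized and scaled to the given
    total concentration (which controls over-dispersion).
    """
    from scipy import stats

    ranks = (np.arange(1, p_otu + 1) - 0.5) / p_otu
    w = np.exp(sigma * stats.norm.ppf(1.0 - ranks))
    w /= w.sum()
    return w * total_concentration


@dataclass
class DMGeneticSpec:
    """Dirichlet-multinomial OTU table with an optional genotype effect.

    Under the alternative, the counts of the eta-th through 20th most
    common OTUs (ranked by total abundance over the generated table) are
    multiplied by f_i = 1 + effect_slope * g_i, with g_i the sample's
    genotype at the causal SNP (column 0 of the genotype matrix).
    """

    n: int = 300
    p_otu: int = 100
    alpha: np.ndarray | None = None
    library_mean: float = 1000.0
    library_dispersion: float = 5.0
    maf: float = 0.3
    n_snps: int = 20
    effect: bool = False
    eta: int = 14
    effect_slope: float = 1.7
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.05 <= self.maf <= 0.5):
            raise ValueError("maf must lie in [0.05, 0.5]")
        if not (1 <= self.eta <= 20):
            raise ValueError("eta must lie in [1, 20]")
        if self.alpha is not None:
            self.alpha = np.asarray(self.alpha, dtype=float)
            if np.any(self.alpha <= 0):
                raise ValueError("alpha must be strictly positive")


def gen_dm_genetic(spec: DMGeneticSpec) -> tuple[CountMatrix, np.ndarray, SampleMetadata]:
    """Generate (counts, genotypes, metadata) for the community-level test.

    Per sample: composition ~ Dirichlet(alpha), counts ~ Multinomial
    (library, composition) with library drawn from a negative binomial
    (redrawn if zero); genotypes are independent Binomial(2, MAF).
    """
    rng = np.random.default_rng(spec.seed)
    alpha = spec.alpha if spec.alpha is not None else _default_alpha(spec.p_otu)
    p_otu = alpha.size
    size = spec.library_dispersion
    p_nb = size / (size + spec.library_mean)
    libs = rng.negative_binomial(size, p_nb, spec.n)
    while np.any(libs <= 0):
        redo = libs <= 0
        libs[redo] = rng.negative_binomial(size, p_nb, int(redo.sum()))
    comps = rng.dirichlet(alpha, size=spec.n)
    counts = np.empty((spec.n, p_otu), dtype=np.int64)
    for i in range(spec.n):
        counts[i] = rng.multinomial(libs[i], comps[i])
    G = rng.binomial(2, spec.maf, size=(spec.n, spec.n_snps)).astype(float)
    if spec.effect:
        order = np.argsort(counts.sum(axis=0))[::-1]  # most common first
        window = order[spec.eta - 1 : 20]
        f = 1.0 + spec.effect_slope * G[:, 0]
        counts[:, window] = np.rint(counts[:, window] * f[:, None]).astype(np.int64)
    sample_ids = [f"s{i}" for i in range(spec.n)]
    taxon_ids = [f"otu_{j}" for j in range(1, p_otu + 1)]
    X = CountMatrix(counts, sample_ids, taxon_ids)
    meta = SampleMetadata(sample_ids, G[:, 0], None, outcome_name="genotype")
    return X, G, meta


# ---------------------------------------------------------------------------
# rejection-rate estimation
# ---------------------------------------------------------------------------


@dataclass
class SimulationSummary:
    """Empirical rejection rates per method with Monte-Carlo error."""

    n_reps: int
    alpha: float
    rates: dict = field(default_factory=dict)
    mc_se: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        methods = list(self.rates)
        return pd.DataFrame(
            {
                "method": methods,
                "rejection_rate": [self.rates[m] for m in methods],
                "mc_se": [self.mc_se[m] for m in methods],
                "n_reps": self.n_reps,
                "alpha": self.alpha,
            }
        )


def estimate_rejection_rate(
    generator: Callable[[np.random.SeedSequence], object],
    pipeline: Callable[[object, np.random.SeedSequence], dict],
    n_reps: int,
    alpha: float,
    seed: int = 0,
) -> SimulationSummary:
    """Empirical rejection rate of a pipeline over independent replicates.

    Parameters
    ----------
    generator : callable(seed_sequence) -> data
        Draws one replicate dataset.
    pipeline : callable(data, seed_sequence) -> dict[str, float]
        Maps a dataset to p-values keyed by method name (typically the
        normalizations plus "omnibus").
    n_reps : number of replicates (>= 100)
    alpha : significance level
    seed : master seed; replicate i uses the counter-derived sub-seed
        SeedSequence(seed, spawn_key=(i,)) and is individually replayable.
    """
    if n_reps < 100:
        raise ValueError("n_reps must be at least 100")
    counts: dict[str, int] = {}
    for i in range(n_reps):
        ss = _child_seed_sequence(seed, i)
        gen_ss, pipe_ss = ss.spawn(2)
        try:
            data = generator(gen_ss)
            pvals = pipeline(data, pipe_ss)
        except Exception as exc:
            raise RuntimeError(
                f"replicate {i} failed (sub-seed spawn_key=({i},) of master {seed}): {exc}"
            ) from exc
        for m, p in pvals.items():
            counts[m] = counts.get(m, 0) + (1 if p <= alpha else 0)
    rates = {m: c / n_reps for m, c in counts.items()}
    mc_se = {m: float(np.sqrt(r * (1 - r) / n_reps)) for m, r in rates.items()}
    return SimulationSummary(n_reps=n_reps, alpha=alpha, rates=rates, mc_se=mc_se)


# ---------------------------------------------------------------------------
# ready-made pipelines used by the CLI and the benchmark scripts
# ---------------------------------------------------------------------------


def _seed_int(ss: np.random.SeedSequence) -> int:
    return int(ss.generate_state(1, dtype=np.uint32)[0])


def taxonwise_pipeline(
    methods: Sequence[str] = ("none", "rarefaction", "tss", "css", "clr"),
    test: str = "linear",
    taus: TauGrid | None = None,
    epsilon: float = 0.01,
) -> Callable:
    """Pipeline testing the focal taxon under each normalization.

    Returns a callable (data, seed_sequence) -> dict of p-values per
    normalization plus the truncated-Cauchy omnibus p-value. The
    rarefaction draw is seeded from the replicate sub-seed.
    """

    def run(data: tuple[CountMatrix, SampleMetadata], ss: np.random.SeedSequence) -> dict:
        X, meta = data
        params = NormalizationParams(rarefaction_seed=_seed_int(ss))
        normalized = apply_all(X, methods, params)
        v, Z = meta.outcome, meta.covariates
        out: dict[str, float] = {}
        for nm in normalized:
            y = nm.values[:, 0]
            if test == "linear":
                res = linear_test(y, v, Z)
            elif test == "qrank":
                res = qrank_test(y, v, Z, taus)
            elif test == "zinq":
                if nm.method == "clr":
                    from omninorm.assoc_tests import _zinq_on_clr

                    res = _zinq_on_clr(X.values[:, 0], y, v, Z, taus, "focal")
                else:
                    res = zinq_test(y, v, Z, taus)
            else:
                raise ValueError(f"unknown test {test!r}")
            out[nm.method] = res.p_value
        out["omnibus"] = truncated_cauchy_combine(list(out.values()), epsilon=epsilon)
        return out

    return run


def krv_pipeline(
    methods: Sequence[str] = ("none", "rarefaction", "tss", "css"),
    n_perm: int = 999,
    epsilon: float = 0.01,
) -> Callable:
    """Community-level pipeline: Bray-Curtis kernel per normalization
    against a linear genotype kernel, KRV permutation test, omnibus."""

    def run(data: tuple[CountMatrix, np.ndarray, SampleMetadata], ss: np.random.SeedSequence) -> dict:
        X, G, _meta = data
        base = _seed_int(ss)
        params = NormalizationParams(rarefaction_seed=base)
        normalized = apply_all(X, methods, params)
        L = linear_genotype_kernel(G)
        out: dict[str, float] = {}
        for idx, nm in enumerate(normalized):
            K = bray_curtis_kernel(nm)
            res = krv_test(K, L, n_perm=n_perm, seed=base + idx + 1)
            out[nm.method] = res.p_value
        out["omnibus"] = truncated_cauchy_combine(list(out.values()), epsilon=epsilon)
        return out

    return run
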