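"""Per-taxon and community-level association tests.

Each per-taxon test regresses a normalized abundance vector y on the
outcome of interest v (plus optional covariates Z) and returns a p-value
for the outcome:

``linear_test``
    ordinary least squares with a t-test on the outcome coefficient.
``qrank_test``
    quantile-regression rank-score test across a grid of quantile
    levels, combined with the Cauchy combination test. Robust to the
    heavy tails and skew of microbiome abundances; ignores the zero mass.
``zinq_test``
    two-part zero-inflated quantile test: a logistic likelihood-ratio
    test on presence/absence plus rank-score tests on the strictly
    positive subsample, all Cauchy-combined.

``krv_test`` is the community-level kernel RV coefficient test of
association between two multivariate views (e.g. a Bray-Curtis
microbiome kernel against a genotype kernel), with a permutation null.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats
from scipy.spatial.distance import pdist, squareform

from omninorm.data_model import CountMatrix, SampleMetadata
from omninorm.normalize import NormalizationParams, NormalizedMatrix, apply_all
from omninorm.omnibus import PValueMatrix, cauchy_combine

logger = logging.getLogger(__name__)

#: internal component p-values are clipped into the open unit interval
#: before Cauchy combination (ties in discrete data can yield exact 0/1)
_P_CLIP = (1e-300, 1.0 - 1e-12)


class DegenerateDataError(ValueError):
    pass


@dataclass
class TaxonTestResult:
    """Outcome of one association test on one taxon."""

    taxon_id: str
    p_value: float
    statistic: float
    test_name: str
    n_used: int


@dataclass
class TauGrid:
    """Ordered quantile levels for the rank-score tests."""

    levels: tuple = (0.1, 0.25, 0.5, 0.75, 0.9)

    def __post_init__(self) -> None:
        lv = tuple(float(t) for t in self.levels)
        if not lv:
            raise ValueError("empty quantile grid")
        if any(not (0 < t < 1) for t in lv):
            raise ValueError("quantile levels must lie in (0, 1)")
        if any(b <= a for a, b in zip(lv, lv[1:])):
            raise ValueError("quantile levels must be strictly increasing")
        self.levels = lv


def _design(v: np.ndarray, Z: np.ndarray | None) -> np.ndarray:
    cols = [np.ones_like(v), v]
    if Z is not None and Z.size:
        cols.append(Z)
    return np.column_stack(cols)


def _null_design(n: int, Z: np.ndarray | None) -> np.ndarray:
    if Z is None or Z.size == 0:
        return np.ones((n, 1))
    return np.column_stack([np.ones(n), Z])


def _check_rank(Xd: np.ndarray) -> None:
    if np.linalg.matrix_rank(Xd) < Xd.shape[1]:
        # identify which columns are linearly dependent on the ones before them
        bad = []
        for j in range(1, Xd.shape[1]):
            if np.linalg.matrix_rank(Xd[:, : j + 1]) < j + 1:
                bad.append(j)
        raise np.linalg.LinAlgError(f"rank-deficient design; collinear column indices {bad}")


def linear_test(
    y: np.ndarray,
    v: np.ndarray,
    Z: np.ndarray | None = None,
    taxon_id: str = "",
) -> TaxonTestResult:
    """OLS of y on (intercept, outcome, covariates); two-sided t-test on
    the outcome coefficient.

    A constant response returns p = 1 (no evidence), a perfect fit p = 0.
    """
    y = np.asarray(y, dtype=float)
    v = np.asarray(v, dtype=float)
    n = y.size
    if np.ptp(y) == 0:
        return TaxonTestResult(taxon_id, 1.0, 0.0, "linear", n)
    Xd = _design(v, Z)
    _check_rank(Xd)
    k = Xd.shape[1]
    df = n - k
    if df <= 0:
        raise DegenerateDataError(f"too few samples (n={n}) for {k} design columns")
    beta, _, _, _ = np.linalg.lstsq(Xd, y, rcond=None)
    resid = y - Xd @ beta
    rss = float(resid @ resid)
    XtX_inv = np.linalg.inv(Xd.T @ Xd)
    sigma2 = rss / df
    se = np.sqrt(sigma2 * XtX_inv[1, 1])
    if se == 0.0:
        p = 0.0 if beta[1] != 0 else 1.0
        t = np.inf if beta[1] != 0 else 0.0
    else:
        t = beta[1] / se
        p = 2.0 * stats.t.sf(abs(t), df)
    return TaxonTestResult(taxon_id, float(p), float(t), "linear", n)


def _regression_rank_scores(y: np.ndarray, W: np.ndarray, tau: float) -> np.ndarray:
    """Regression rank scores a_i(tau) in [0, 1] of the null design W.

    These are the dual solution of the null quantile regression:
    maximize y'a subject to W'a = (1 - tau) W'1 and 0 <= a <= 1.
    For continuous data a_i is 1 above the fitted quantile plane and 0
    below; observations tied with the plane get fractional values, which
    keeps the rank-score test calibrated for discrete, zero-inflated
    abundances. Intercept-only designs are solved analytically.
    """
    n = y.size
    if W.shape[1] == 1:
        q = np.quantile(y, tau, method="inverted_cdf")
        above = y > q
        below = y < q
        tied = ~above & ~below
        n_tied = int(tied.sum())
        a = np.zeros(n)
        a[above] = 1.0
        if n_tied:
            remaining = n * (1.0 - tau) - float(above.sum())
            a[tied] = min(max(remaining / n_tied, 0.0), 1.0)
        return a
    from scipy.optimize import linprog

    res = linprog(
        c=-y,
        A_eq=W.T,
        b_eq=(1.0 - tau) * W.sum(axis=0),
        bounds=(0.0, 1.0),
        method="highs",
    )
    if not res.success:
        raise DegenerateDataError(f"rank-score dual infeasible at tau={tau}: {res.message}")
    return np.clip(res.x, 0.0, 1.0)


def _rank_score_pvalues(
    y: np.ndarray,
    v: np.ndarray,
    Z: np.ndarray | None,
    taus: Sequence[float],
) -> list[float]:
    """Per-quantile-level rank-score chi-square(1) p-values.

    At level tau the score is b_i = a_i(tau) - (1 - tau), where a_i are
    the regression rank scores of the null design (for continuous data
    this equals tau - 1{y_i <= fitted null quantile}); the statistic is
    (v*' b)^2 / (tau (1 - tau) ||v*||^2) with v* the outcome
    residualized against the null design.
    """
    n = y.size
    W = _null_design(n, Z)
    # residualize the outcome against the null design once
    WtW_inv = np.linalg.pinv(W.T @ W)
    v_star = v - W @ (WtW_inv @ (W.T @ v))
    vv = float(v_star @ v_star)
    if vv <= 0:
        raise DegenerateDataError("outcome is collinear with the null design")
    pvals = []
    for tau in taus:
        try:
            a = _regression_rank_scores(y, W, tau)
        except Exception as exc:  # degenerate fit at this level
            logger.warning("dropping quantile level %.3g: %s", tau, exc)
            continue
        b = a - (1.0 - tau)
        S = float(v_star @ b)
        var = tau * (1.0 - tau) * vv
        stat = S * S / var
        pvals.append(float(stats.chi2.sf(stat, df=1)))
    if not pvals:
        raise DegenerateDataError("all quantile levels failed")
    return pvals


def qrank_test(
    y: np.ndarray,
    v: np.ndarray,
    Z: np.ndarray | None = None,
    taus: TauGrid | None = None,
    taxon_id: str = "",
) -> TaxonTestResult:
    """Quantile rank-score test across a grid of levels, Cauchy-combined.

    Ignores zero inflation: the full response vector enters every level.
    """
    y = np.asarray(y, dtype=float)
    v = np.asarray(v, dtype=float)
    taus = taus or TauGrid()
    if np.ptp(y) == 0:
        return TaxonTestResult(taxon_id, 1.0, 0.0, "qrank", y.size)
    pvals = _rank_score_pvalues(y, v, Z, taus.levels)
    pvals = np.clip(pvals, *_P_CLIP)
    p = cauchy_combine(pvals)
    T = np.mean(np.tan((0.5 - pvals) * np.pi))
    return TaxonTestResult(taxon_id, p, float(T), "qrank", y.size)


def _logistic_lr_pvalue(D: np.ndarray, v: np.ndarray, Z: np.ndarray | None) -> float:
    """Likelihood-ratio p-value for the outcome in logit P(D=1)."""
    import statsmodels.api as sm

    W0 = _null_design(D.size, Z)
    W1 = _design(v, Z)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        ll0 = sm.Logit(D, W0).fit(disp=0, maxiter=100).llf
        ll1 = sm.Logit(D, W1).fit(disp=0, maxiter=100).llf
    lr = max(2.0 * (ll1 - ll0), 0.0)
    return float(stats.chi2.sf(lr, df=1))


_MIN_POSITIVE = 10  # below this, the positive-part rank-score test is skipped


def zinq_test(
    y: np.ndarray,
    v: np.ndarray,
    Z: np.ndarray | None = None,
    taus: TauGrid | None = None,
    taxon_id: str = "",
) -> TaxonTestResult:
    """Two-part zero-inflated quantile test.

    Part 1 tests the outcome in a logistic model for presence
    (y > 0); part 2 runs the rank-score test at each quantile level on
    the strictly positive subsample. All component p-values are combined
    with the Cauchy combination test. When presence is constant the
    zero part is dropped; with fewer than 10 positive observations the
    positive part is dropped.
    """
    y = np.asarray(y, dtype=float)
    v = np.asarray(v, dtype=float)
    if np.any(y < 0):
        raise ValueError("zinq_test requires a nonnegative response")
    taus = taus or TauGrid()
    n = y.size
    D = (y > 0).astype(float)
    n_pos = int(D.sum())
    components: list[float] = []

    if n_pos == 0:
        warnings.warn("response is all zero; returning p = 1", RuntimeWarning, stacklevel=2)
        return TaxonTestResult(taxon_id, 1.0, 0.0, "zinq", n)

    if 0 < n_pos < n:
        components.append(_logistic_lr_pvalue(D, v, Z))

    if n_pos >= _MIN_POSITIVE:
        pos = y > 0
        Zp = Z[pos] if Z is not None and Z.size else None
        if np.ptp(v[pos]) > 0 and np.ptp(y[pos]) > 0:
            try:
                components.extend(_rank_score_pvalues(y[pos], v[pos], Zp, taus.levels))
            except DegenerateDataError as exc:
                logger.warning("positive part skipped: %s", exc)
    elif n_pos < n:
        logger.warning(
            "only %d positive observations; positive part skipped", n_pos
        )

    if not components:
        warnings.warn("no testable component; returning p = 1", RuntimeWarning, stacklevel=2)
        return TaxonTestResult(taxon_id, 1.0, 0.0, "zinq", n)
    comp = np.clip(components, *_P_CLIP)
    p = cauchy_combine(comp)
    T = np.mean(np.tan((0.5 - comp) * np.pi))
    return TaxonTestResult(taxon_id, p, float(T), "zinq", n)


# ---------------------------------------------------------------------------
# community-level kernel RV coefficient test
# ---------------------------------------------------------------------------


@dataclass
class KernelPair:
    """A microbiome kernel K and a genotype kernel L on the same samples."""

    K: np.ndarray
    L: np.ndarray

    def __post_init__(self) -> None:
        for name, M in (("K", self.K), ("L", self.L)):
            M = np.asarray(M, dtype=float)
            if M.ndim != 2 or M.shape[0] != M.shape[1]:
                raise ValueError(f"{name} must be square")
            if not np.allclose(M, M.T, atol=1e-10):
                raise ValueError(f"{name} is not symmetric")
        if self.K.shape != self.L.shape:
            raise ValueError("K and L must have the same shape")


def _psd_truncate(K: np.ndarray) -> np.ndarray:
    """Clip negative eigenvalues to zero (Gower correction)."""
    vals, vecs = np.linalg.eigh(K)
    if vals.min() >= 0:
        return K
    vals = np.clip(vals, 0.0, None)
    K = (vecs * vals) @ vecs.T
    return (K + K.T) / 2.0


def bray_curtis_kernel(M: NormalizedMatrix | np.ndarray) -> np.ndarray:
    """Bray-Curtis dissimilarity converted to a PSD kernel.

    D_ij = sum_k |m_ik - m_jk| / sum_k (m_ik + m_jk);
    K = -(1/2) H D^2 H (Gower double-centering, entrywise squares),
    followed by truncation of negative eigenvalues. Requires nonnegative
    input, so CLR-transformed matrices are rejected.
    """
    values = M.values if isinstance(M, NormalizedMatrix) else np.asarray(M, dtype=float)
    if np.any(values < 0):
        method = M.method if isinstance(M, NormalizedMatrix) else "input"
        raise ValueError(
            f"Bray-Curtis requires nonnegative abundances; {method} produced negatives"
        )
    D = squareform(pdist(values, metric="braycurtis"))
    D = np.nan_to_num(D, nan=0.0)  # pairs of all-zero samples have no dissimilarity
    n = D.shape[0]
    H = np.eye(n) - np.ones((n, n)) / n
    K = -0.5 * H @ (D**2) @ H
    K = (K + K.T) / 2.0
    return _psd_truncate(K)


def linear_genotype_kernel(G: np.ndarray) -> np.ndarray:
    """Linear kernel on a genotype matrix standardized per SNP."""
    G = np.asarray(G, dtype=float)
    mu = G.mean(axis=0)
    sd = G.std(axis=0)
    sd[sd == 0] = 1.0
    Gs = (G - mu) / sd
    K = Gs @ Gs.T / Gs.shape[1]
    return _psd_truncate((K + K.T) / 2.0)


def _double_center(K: np.ndarray) -> np.ndarray:
    n = K.shape[0]
    H = np.eye(n) - np.ones((n, n)) / n
    return H @ K @ H


def _krv_statistic(Kc: np.ndarray, Lc: np.ndarray) -> float:
    num = float(np.sum(Kc * Lc))
    den = np.sqrt(float(np.sum(Kc * Kc)) * float(np.sum(Lc * Lc)))
    if den == 0.0:
        raise DegenerateDataError("constant kernel: zero trace after centering")
    return num / den


def krv_test(
    K: np.ndarray,
    L: np.ndarray,
    n_perm: int = 999,
    seed: int = 0,
    taxon_id: str = "community",
) -> TaxonTestResult:
    """Kernel RV coefficient test with a permutation null.

    KRV = trace(Kc Lc) / sqrt(trace(Kc Kc) trace(Lc Lc)) with Kc, Lc the
    double-centered kernels; the p-value counts simultaneous row/column
    permutations of L with a statistic at least as large as observed,
    p = (1 + #{KRV_perm >= KRV}) / (1 + n_perm).
    """
    pair = KernelPair(np.asarray(K, float), np.asarray(L, float))
    if n_perm < 99:
        raise ValueError("n_perm must be at least 99")
    Kc = _double_center(pair.K)
    Lc = _double_center(pair.L)
    observed = _krv_statistic(Kc, Lc)
    rng = np.random.default_rng(seed)
    n = Kc.shape[0]
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        Lp = Lc[np.ix_(perm, perm)]
        if _krv_statistic(Kc, Lp) >= observed - 1e-12:
            count += 1
    p = (1 + count) / (1 + n_perm)
    return TaxonTestResult(taxon_id, float(p), float(observed), "krv", n)


def krv_exhaustive(K: np.ndarray, L: np.ndarray) -> TaxonTestResult:
    """KRV p-value by enumerating every sample permutation (tiny n only)."""
    from itertools import permutations

    pair = KernelPair(np.asarray(K, float), np.asarray(L, float))
    Kc = _double_center(pair.K)
    Lc = _double_center(pair.L)
    observed = _krv_statistic(Kc, Lc)
    n = Kc.shape[0]
    if n > 8:
        raise ValueError("exhaustive enumeration is limited to n <= 8")
    count = 0
    total = 0
    for perm in permutations(range(n)):
        Lp = Lc[np.ix_(perm, perm)]
        if _krv_statistic(Kc, Lp) >= observed - 1e-12:
            count += 1
        total += 1
    return TaxonTestResult("community", count / total, float(observed), "krv_exhaustive", n)


# ---------------------------------------------------------------------------
# taxon-wise driver across normalizations
# ---------------------------------------------------------------------------

_TESTS = {
    "linear": lambda y, v, Z, taus, tid: linear_test(y, v, Z, taxon_id=tid),
    "qrank": qrank_test,
    "zinq": zinq_test,
}


def run_taxonwise(
    X: CountMatrix,
    meta: SampleMetadata,
    methods: Sequence[str],
    test: str = "zinq",
    norm_params: NormalizationParams | None = None,
    taus: TauGrid | None = None,
) -> PValueMatrix:
    """Test every taxon under every normalization.

    Returns the J-by-p matrix of p-values with rows labeled by
    normalization method and columns by taxon ID. A taxon whose test
    fails under some normalization gets p = 1 there (with a warning), so
    the matrix stays rectangular for the omnibus step.
    """
    if test not in _TESTS:
        raise ValueError(f"unknown test {test!r}; choose from {sorted(_TESTS)}")
    if list(meta.sample_ids) != list(X.sample_ids):
        raise ValueError("counts and metadata are not aligned; call data_model.align first")
    normalized = apply_all(X, methods, norm_params)
    v = meta.outcome
    Z = meta.covariates
    P = np.ones((len(methods), X.n_taxa))
    for j, nm in enumerate(normalized):
        for k, tid in enumerate(X.taxon_ids):
            y = nm.values[:, k]
            try:
                if test == "linear":
                    res = linear_test(y, v, Z, taxon_id=tid)
                elif test == "qrank":
                    res = qrank_test(y, v, Z, taus, taxon_id=tid)
                else:
                    if nm.method == "clr":
                        # CLR output is signed; the two-part model needs a
                        # zero-preserving scale, so presence is taken from
                        # the raw counts and magnitudes from the transform
                        res = _zinq_on_clr(X.values[:, k], y, v, Z, taus, tid)
                    else:
                        res = zinq_test(y, v, Z, taus, taxon_id=tid)
                P[j, k] = res.p_value
            except Exception as exc:
                logger.warning(
                    "test failed for taxon %s under %s: %s; using p = 1",
                    tid, nm.method, exc,
                )
                P[j, k] = 1.0
    return PValueMatrix(P, [nm.method for nm in normalized], list(X.taxon_ids))


def _zinq_on_clr(
    raw: np.ndarray,
    y_clr: np.ndarray,
    v: np.ndarray,
    Z: np.ndarray | None,
    taus: TauGrid | None,
    taxon_id: str,
) -> TaxonTestResult:
    """ZINQ for CLR-normalized data: presence from raw counts, quantile
    part on the CLR values of the present subsample."""
    taus = taus or TauGrid()
    D = (np.asarray(raw, float) > 0).astype(float)
    n = D.size
    n_pos = int(D.sum())
    components: list[float] = []
    if n_pos == 0:
        return TaxonTestResult(taxon_id, 1.0, 0.0, "zinq", n)
    if 0 < n_pos < n:
        components.append(_logistic_lr_pvalue(D, v, Z))
    if n_pos >= _MIN_POSITIVE:
        pos = D > 0
        Zp = Z[pos] if Z is not None and Z.size else None
        if np.ptp(v[pos]) > 0 and np.ptp(y_clr[pos]) > 0:
            try:
                components.extend(_rank_score_pvalues(y_clr[pos], v[pos], Zp, taus.levels))
            except DegenerateDataError:
                pass
    if not components:
        return TaxonTestResult(taxon_id, 1.0, 0.0, "zinq", n)
    comp = np.clip(components, *_P_CLIP)
    p = cauchy_combine(comp)
    return TaxonTestResult(taxon_id, p, float(np.mean(np.tan((0.5 - comp) * np.pi))), "zinq", n)
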