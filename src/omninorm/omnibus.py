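"""Cauchy combination of p-values across normalizations, plus BH-FDR.

The Cauchy combination test (CCT) maps each p-value to a standard Cauchy
quantile, T = sum_j w_j * tan((0.5 - p_j) * pi), and reads the combined
p-value off the Cauchy survival function, p = 0.5 - arctan(T)/pi. T is
approximately standard Cauchy under the null for arbitrary dependence
among the component p-values, which is what makes it safe to combine
tests of the same taxon under correlated normalizations.

A single component p-value at or near 1 drives the plain CCT to 1; the
truncated variant caps each p_j at 1 - epsilon (default epsilon = 0.01)
before combining, bounding the combined p away from 1.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: below this, tan((0.5 - p) * pi) is evaluated by its small-p expansion
_TINY_P = 1e-15
#: above this |T|, the combined p uses the Cauchy tail form
_HUGE_T = 1e15
#: exact zeros from component tests are floored here before combining
_ZERO_FLOOR = 1e-300


@dataclass
class PValueMatrix:
    """J-by-p matrix of per-normalization, per-taxon p-values."""

    values: np.ndarray
    method_labels: list[str]
    taxon_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("p-value matrix must be 2-dimensional")
        J, p = self.values.shape
        if J < 1:
            raise ValueError("need at least one normalization row")
        if len(self.method_labels) != J or len(self.taxon_ids) != p:
            raise ValueError("labels do not match matrix shape")
        if np.any(self.values < 0) or np.any(self.values > 1):
            raise ValueError("p-values outside [0, 1]")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.method_labels, columns=self.taxon_ids)


@dataclass
class OmnibusResult:
    """Combined per-taxon p-values with BH q-values and per-method detail."""

    taxon_ids: list[str]
    statistic: np.ndarray
    p_omnibus: np.ndarray
    per_method: pd.DataFrame  # taxa in rows, methods in columns
    q_omnibus: np.ndarray
    epsilon: float
    weights: np.ndarray


def _tan_terms(p: np.ndarray) -> np.ndarray:
    """tan((0.5 - p) * pi) with a stable small-p branch.

    For p below ~1e-15 the argument is indistinguishable from pi/2 in
    double precision; tan((0.5 - p) * pi) = 1/tan(pi * p) ~ 1/(pi * p).
    """
    terms = np.empty_like(p)
    small = p < _TINY_P
    terms[small] = 1.0 / (np.pi * p[small])
    terms[~small] = np.tan((0.5 - p[~small]) * np.pi)
    return terms


def _cauchy_sf(T: float) -> float:
    """Standard Cauchy survival function with stable tails."""
    if T > _HUGE_T:
        return 1.0 / (np.pi * T)
    if T < -_HUGE_T:
        return 1.0 - 1.0 / (np.pi * (-T))
    return 0.5 - np.arctan(T) / np.pi


def _check_weights(weights, J: int) -> np.ndarray:
    if weights is None:
        return np.full(J, 1.0 / J)
    w = np.asarray(weights, dtype=float)
    if w.shape != (J,) or np.any(w < 0) or abs(w.sum() - 1.0) > 1e-9:
        raise ValueError("weights must be nonnegative and sum to 1")
    return w


def cauchy_combine(p, weights=None) -> float:
    """Combine p-values with the (untruncated) Cauchy combination test.

    Parameters
    ----------
    p : array-like of p-values, each strictly inside (0, 1)
    weights : optional nonnegative weights summing to 1 (default uniform)

    Returns
    -------
    float
        Combined p-value 0.5 - arctan(T)/pi where
        T = sum_j w_j * tan((0.5 - p_j) * pi).
    """
    p = np.atleast_1d(np.asarray(p, dtype=float))
    if np.any(p <= 0) or np.any(p >= 1):
        raise ValueError("cauchy_combine requires p-values strictly inside (0, 1)")
    w = _check_weights(weights, p.size)
    T = float(np.dot(w, _tan_terms(p)))
    return float(np.clip(_cauchy_sf(T), 0.0, 1.0))


def truncated_cauchy_combine(p, epsilon: float = 0.01, weights=None) -> float:
    """Cauchy combination with each p-value capped at 1 - epsilon.

    Component p-values equal to 1 are admissible; the combined p-value
    cannot exceed 1 - epsilon when all components are at 1.
    """
    if not (0 < epsilon < 0.5):
        raise ValueError("epsilon must lie in (0, 0.5)")
    p = np.atleast_1d(np.asarray(p, dtype=float))
    if np.any(p < 0) or np.any(p > 1):
        raise ValueError("p-values outside [0, 1]")
    return cauchy_combine(np.minimum(p, 1.0 - epsilon), weights=weights)


def _cauchy_statistic(p, epsilon: float, weights) -> float:
    p = np.minimum(np.atleast_1d(np.asarray(p, dtype=float)), 1.0 - epsilon)
    w = _check_weights(weights, p.size)
    return float(np.dot(w, _tan_terms(p)))


def combine_matrix(P: PValueMatrix, epsilon: float = 0.01, weights=None) -> OmnibusResult:
    """Column-wise truncated Cauchy combination of a p-value matrix.

    Exact-zero component p-values are floored at 1e-300 with a warning
    before combining.
    """
    vals = P.values.copy()
    if np.any(vals == 0):
        warnings.warn(
            "exact-zero p-values floored at 1e-300 before Cauchy combination",
            RuntimeWarning,
            stacklevel=2,
        )
        vals[vals == 0] = _ZERO_FLOOR
    J, n_tax = vals.shape
    w = _check_weights(weights, J)
    stat = np.array([_cauchy_statistic(vals[:, k], epsilon, w) for k in range(n_tax)])
    p_omni = np.array(
        [truncated_cauchy_combine(vals[:, k], epsilon, w) for k in range(n_tax)]
    )
    q = bh_adjust(p_omni)
    per_method = pd.DataFrame(vals.T, index=P.taxon_ids, columns=P.method_labels)
    return OmnibusResult(
        taxon_ids=list(P.taxon_ids),
        statistic=stat,
        p_omnibus=p_omni,
        per_method=per_method,
        q_omnibus=q,
        epsilon=epsilon,
        weights=w,
    )


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values.

    q_(i) = min_{j >= i} m * p_(j) / j over the sorted p-values, mapped
    back to the input order; q >= p elementwise and q is monotone in p.
    """
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(p < 0) or np.any(p > 1):
        raise ValueError("p-values outside [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q
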