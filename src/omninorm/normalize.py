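"""Library-size normalizations for count tables.

Five strategies, all per-sample transforms of a :class:`CountMatrix`:

``none``
    identity (raw counts).
``rarefaction``
    subsample each sample without replacement to a common depth
    (multivariate hypergeometric draw).
``tss``
    total sum scaling: divide by library size, giving relative abundances.
``css``
    cumulative sum scaling: divide by the sum of the sample's counts up
    to a cutoff quantile of its nonzero counts, damping dominant taxa.
``clr``
    centered log-ratio: log counts (plus pseudocount) centered by the
    sample's mean log count.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence, Union

import numpy as np

from omninorm.data_model import CountMatrix

METHODS = ("none", "rarefaction", "tss", "css", "clr")


class NormalizationError(ValueError):
    pass


class ConfigurationError(ValueError):
    pass


@dataclass
class NormalizationParams:
    """Tunable parameters of the normalization strategies.

    rarefaction_depth : positive int or "min_library"
        Common depth; "min_library" resolves to the smallest library size.
    rarefaction_seed : int
        Seed for the subsampling draw.
    css_quantile : float in (0, 1)
        Cutoff level for the cumulative sum; the per-sample cutoff is the
        lower nearest-rank empirical quantile of the nonzero counts.
    css_scale : "median_s" or a positive number
        Rescaling constant applied after division by the cumulative sum:
        the median of the per-sample sums (default) or a fixed value.
    clr_pseudocount : positive float
        Added to every cell before taking logs.
    """

    rarefaction_depth: Union[int, str] = "min_library"
    rarefaction_seed: int = 0
    css_quantile: float = 0.5
    css_scale: Union[str, float] = "median_s"
    clr_pseudocount: float = 0.5

    def __post_init__(self) -> None:
        if not (0 < self.css_quantile < 1):
            raise ConfigurationError("css_quantile must lie in (0, 1)")
        if self.clr_pseudocount <= 0:
            raise ConfigurationError("clr_pseudocount must be positive")
        if isinstance(self.rarefaction_depth, str) and self.rarefaction_depth != "min_library":
            raise ConfigurationError(
                f"rarefaction_depth must be an integer or 'min_library', "
                f"got {self.rarefaction_depth!r}"
            )


@dataclass
class NormalizedMatrix:
    """Real-valued sample-by-taxon matrix tagged with its normalization."""

    values: np.ndarray
    sample_ids: list[str]
    taxon_ids: list[str]
    method: str
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.method not in METHODS:
            raise ConfigurationError(f"unknown normalization method {self.method!r}")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]


def _from_counts(X: CountMatrix, values, method, params) -> NormalizedMatrix:
    return NormalizedMatrix(values, list(X.sample_ids), list(X.taxon_ids), method, params)


def identity(X: CountMatrix) -> NormalizedMatrix:
    """The 'none' strategy: raw counts as floats."""
    return _from_counts(X, X.values.astype(float), "none", {})


def rarefy(X: CountMatrix, depth: Union[int, str] = "min_library", seed: int = 0) -> NormalizedMatrix:
    """Subsample each sample without replacement to a common depth.

    Each row of the result sums exactly to ``depth`` and every entry is
    bounded by the raw count (a multivariate hypergeometric draw).
    """
    libs = X.library_sizes
    if depth == "min_library":
        depth = int(libs.min())
    depth = int(depth)
    if depth <= 0:
        raise NormalizationError("rarefaction depth must be positive")
    short = libs < depth
    if np.any(short):
        offenders = [X.sample_ids[i] for i in np.nonzero(short)[0]]
        raise NormalizationError(
            f"library size below rarefaction depth {depth} for samples: {offenders}"
        )
    rng = np.random.default_rng(seed)
    out = np.empty_like(X.values)
    for i in range(X.n_samples):
        out[i] = rng.multivariate_hypergeometric(X.values[i], depth)
    return _from_counts(X, out.astype(float), "rarefaction", {"depth": depth, "seed": seed})


def tss(X: CountMatrix) -> NormalizedMatrix:
    """Total sum scaling: each row divided by its library size."""
    libs = X.library_sizes
    if np.any(libs == 0):
        offenders = [X.sample_ids[i] for i in np.nonzero(libs == 0)[0]]
        raise NormalizationError(f"zero library size for samples: {offenders}")
    return _from_counts(X, X.values / libs[:, None], "tss", {})


def _nearest_rank_lower_quantile(sorted_vals: np.ndarray, q: float) -> float:
    # lower nearest-rank: value at position ceil(q*m) of the sorted list (1-based)
    m = sorted_vals.size
    k = max(int(np.ceil(q * m)), 1)
    return float(sorted_vals[k - 1])


def css(
    X: CountMatrix,
    quantile: float = 0.5,
    scale: Union[str, float] = "median_s",
) -> NormalizedMatrix:
    """Cumulative sum scaling.

    For sample i, let q_i be the ``quantile``-level lower nearest-rank
    quantile of its nonzero counts and s_i the sum of counts no greater
    than q_i (s_i > 0 always: the smallest nonzero count is included).
    The output is x_ij / s_i * C, with C the median of the s_i (default)
    or a fixed constant.
    """
    if not (0 < quantile < 1):
        raise ConfigurationError("css quantile must lie in (0, 1)")
    n = X.n_samples
    s = np.empty(n)
    for i in range(n):
        nonzero = np.sort(X.values[i][X.values[i] > 0])
        if nonzero.size == 0:
            raise NormalizationError(f"sample {X.sample_ids[i]!r} is all zero")
        q_i = _nearest_rank_lower_quantile(nonzero, quantile)
        s[i] = X.values[i][X.values[i] <= q_i].sum()
    C = float(np.median(s)) if scale == "median_s" else float(scale)
    out = X.values / s[:, None] * C
    return _from_counts(X, out, "css", {"quantile": quantile, "scale": scale, "C": C})


def clr(X: CountMatrix, pseudocount: float = 0.5) -> NormalizedMatrix:
    """Centered log-ratio transform with additive pseudocount.

    output_ij = log(x_ij + c) - mean_j' log(x_ij' + c); rows sum to zero.
    """
    if pseudocount <= 0:
        raise ConfigurationError("clr pseudocount must be positive")
    logs = np.log(X.values + pseudocount)
    out = logs - logs.mean(axis=1, keepdims=True)
    return _from_counts(X, out, "clr", {"pseudocount": pseudocount})


def apply_all(
    X: CountMatrix,
    methods: Sequence[str],
    params: NormalizationParams | None = None,
) -> list[NormalizedMatrix]:
    """Apply an ordered list of normalizations to one count table.

    The rarefaction seed is fixed by ``params`` so a full pipeline run is
    reproducible.
    """
    if not methods:
        raise ConfigurationError("empty normalization list")
    params = params or NormalizationParams()
    out = []
    for m in methods:
        if m == "none":
            out.append(identity(X))
        elif m == "rarefaction":
            out.append(rarefy(X, params.rarefaction_depth, params.rarefaction_seed))
        elif m == "tss":
            out.append(tss(X))
        elif m == "css":
            out.append(css(X, params.css_quantile, params.css_scale))
        elif m == "clr":
            out.append(clr(X, params.clr_pseudocount))
        else:
            raise ConfigurationError(f"unknown normalization method {m!r}")
    return out


def rarefy_average(X: CountMatrix, k: int, depth: Union[int, str] = "min_library", seed: int = 0) -> NormalizedMatrix:
    """Average of k independent rarefactions (smoother starting data for
    simulation fits; not part of the analysis pipeline)."""
    if k < 1:
        raise ConfigurationError("k must be >= 1")
    acc = None
    for j in range(k):
        r = rarefy(X, depth, seed + j)
        acc = r.values if acc is None else acc + r.values
    return _from_counts(X, acc / k, "rarefaction", {"depth": depth, "seed": seed, "averaged": k})
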