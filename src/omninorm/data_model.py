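"""Core data containers and tabular I/O.

Count tables, sample metadata and result tables are plain TSV files;
in memory they are thin dataclasses wrapping numpy arrays with sample
and taxon identifiers. All alignment between counts and metadata is by
sample ID, never by row order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


class FormatError(ValueError):
    """Malformed input table (duplicate IDs, bad header...)."""


class ValidationError(ValueError):
    """A cell or column violates a data invariant."""


class AlignmentError(ValueError):
    """Counts and metadata share no sample IDs."""


class DegenerateDesignError(ValueError):
    """The outcome carries no information (constant across samples)."""


@dataclass
class CountMatrix:
    """Raw sample-by-taxon read counts.

    Attributes
    ----------
    values : (n, p) int ndarray
        Nonnegative read counts, samples in rows.
    sample_ids : list of n unique strings
    taxon_ids : list of p unique strings
    """

    values: np.ndarray
    sample_ids: list[str]
    taxon_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise ValidationError("count matrix must be 2-dimensional")
        if not np.issubdtype(self.values.dtype, np.integer):
            if not np.all(np.equal(np.mod(self.values, 1), 0)):
                raise ValidationError("count matrix contains non-integer entries")
            self.values = self.values.astype(np.int64)
        if np.any(self.values < 0):
            i, j = np.argwhere(self.values < 0)[0]
            raise ValidationError(
                f"negative count at sample {self.sample_ids[i]!r}, "
                f"taxon {self.taxon_ids[j]!r}"
            )
        n, p = self.values.shape
        if n < 2:
            raise ValidationError(f"need at least 2 samples, got {n}")
        if p < 1:
            raise ValidationError("need at least 1 taxon")
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.taxon_ids = [str(t) for t in self.taxon_ids]
        if len(self.sample_ids) != n or len(self.taxon_ids) != p:
            raise ValidationError("ID lists do not match matrix shape")
        if len(set(self.sample_ids)) != n:
            raise FormatError("duplicate sample IDs")
        if len(set(self.taxon_ids)) != p:
            raise FormatError("duplicate taxon IDs")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_taxa(self) -> int:
        return self.values.shape[1]

    @property
    def library_sizes(self) -> np.ndarray:
        """Total read count per sample (row sums)."""
        return self.values.sum(axis=1)

    def drop_empty_samples(self) -> "CountMatrix":
        """Remove samples with zero library size, warning if any."""
        keep = self.library_sizes > 0
        n_drop = int((~keep).sum())
        if n_drop == 0:
            return self
        logger.warning("dropping %d sample(s) with zero library size", n_drop)
        return CountMatrix(
            self.values[keep],
            [s for s, k in zip(self.sample_ids, keep) if k],
            list(self.taxon_ids),
        )

    def subset_samples(self, ids: Sequence[str]) -> "CountMatrix":
        index = {s: i for i, s in enumerate(self.sample_ids)}
        rows = [index[s] for s in ids]
        return CountMatrix(self.values[rows], list(ids), list(self.taxon_ids))


@dataclass
class SampleMetadata:
    """Per-sample outcome and optional covariates, keyed by sample ID."""

    sample_ids: list[str]
    outcome: np.ndarray
    covariates: np.ndarray | None = None
    outcome_name: str = "outcome"
    covariate_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.outcome = np.asarray(self.outcome, dtype=float)
        n = len(self.sample_ids)
        if self.outcome.shape != (n,):
            raise ValidationError("outcome length does not match sample IDs")
        if len(set(self.sample_ids)) != n:
            raise FormatError("duplicate sample IDs in metadata")
        if np.unique(self.outcome).size < 2:
            raise DegenerateDesignError(
                f"outcome {self.outcome_name!r} is constant across samples"
            )
        if self.covariates is not None:
            self.covariates = np.asarray(self.covariates, dtype=float)
            if self.covariates.ndim == 1:
                self.covariates = self.covariates[:, None]
            if self.covariates.shape[0] != n:
                raise ValidationError("covariate rows do not match sample IDs")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_covariates(self) -> int:
        return 0 if self.covariates is None else self.covariates.shape[1]

    def subset_samples(self, ids: Sequence[str]) -> "SampleMetadata":
        index = {s: i for i, s in enumerate(self.sample_ids)}
        rows = [index[s] for s in ids]
        return SampleMetadata(
            list(ids),
            self.outcome[rows],
            None if self.covariates is None else self.covariates[rows],
            self.outcome_name,
            list(self.covariate_names),
        )


@dataclass
class ResultTable:
    """Per-taxon p-values, omnibus p, BH q-values and significance calls."""

    taxon_ids: list[str]
    per_method_p: pd.DataFrame  # taxa in rows, one column per normalization
    p_omnibus: np.ndarray
    q_omnibus: np.ndarray
    fdr: float
    significant: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.p_omnibus = np.asarray(self.p_omnibus, dtype=float)
        self.q_omnibus = np.asarray(self.q_omnibus, dtype=float)
        for name, arr in (("p", self.p_omnibus), ("q", self.q_omnibus)):
            if arr.size and (arr.min() < 0 or arr.max() > 1):
                raise ValidationError(f"omnibus {name}-values outside [0, 1]")
        self.significant = self.q_omnibus <= self.fdr

    def to_frame(self) -> pd.DataFrame:
        df = self.per_method_p.copy()
        df.columns = [f"p_{m}" for m in df.columns]
        df.insert(0, "taxon_id", self.taxon_ids)
        df["p_omnibus"] = self.p_omnibus
        df["q_omnibus"] = self.q_omnibus
        df["significant"] = self.significant
        return df.reset_index(drop=True)


def read_count_table(path, orientation: str = "samples_in_rows") -> CountMatrix:
    """Read a TSV count table into a :class:`CountMatrix`.

    Parameters
    ----------
    path : path-like
        TSV with one header row of IDs and one leading ID column.
    orientation : {"samples_in_rows", "taxa_in_rows"}
        ``taxa_in_rows`` (the BIOM-style TSV layout) is transposed on read.
    """
    if orientation not in ("samples_in_rows", "taxa_in_rows"):
        raise ValueError(f"unknown orientation {orientation!r}")
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.has_duplicates or df.columns.has_duplicates:
        raise FormatError(f"duplicate IDs in count table {path}")
    if orientation == "taxa_in_rows":
        df = df.T
    values = df.to_numpy()
    if not np.issubdtype(values.dtype, np.number):
        bad = df.columns[[not np.issubdtype(t, np.number) for t in df.dtypes]]
        raise ValidationError(f"non-numeric count column(s): {list(bad)}")
    if np.any(values < 0):
        i, j = np.argwhere(values < 0)[0]
        raise ValidationError(
            f"negative count at row {df.index[i]!r}, column {df.columns[j]!r}"
        )
    if not np.all(np.equal(np.mod(values, 1), 0)):
        i, j = np.argwhere(np.mod(values, 1) != 0)[0]
        raise ValidationError(
            f"non-integer count at row {df.index[i]!r}, column {df.columns[j]!r}"
        )
    return CountMatrix(values.astype(np.int64), list(df.index), list(df.columns))


def read_metadata(
    path,
    outcome_col: str,
    covariate_cols: Sequence[str] = (),
) -> SampleMetadata:
    """Read a TSV metadata table; rows with missing entries are dropped."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    missing = [c for c in [outcome_col, *covariate_cols] if c not in df.columns]
    if missing:
        raise FormatError(f"metadata columns not found: {missing}")
    sub = df[[outcome_col, *covariate_cols]]
    complete = sub.notna().all(axis=1)
    n_drop = int((~complete).sum())
    if n_drop:
        logger.warning("dropped %d metadata row(s) with missing values", n_drop)
    sub = sub[complete]
    cov = sub[list(covariate_cols)].to_numpy(dtype=float) if covariate_cols else None
    return SampleMetadata(
        list(sub.index),
        sub[outcome_col].to_numpy(dtype=float),
        cov,
        outcome_name=outcome_col,
        covariate_names=list(covariate_cols),
    )


def align(counts: CountMatrix, meta: SampleMetadata) -> tuple[CountMatrix, SampleMetadata]:
    """Intersect counts and metadata on sample ID (count-table order)."""
    meta_ids = set(meta.sample_ids)
    shared = [s for s in counts.sample_ids if s in meta_ids]
    if not shared:
        raise AlignmentError("no overlapping sample IDs between counts and metadata")
    n_drop = (counts.n_samples - len(shared)) + (meta.n_samples - len(shared))
    if n_drop:
        logger.warning("alignment dropped %d unmatched sample(s)", n_drop)
    return counts.subset_samples(shared), meta.subset_samples(shared)


def write_results(res: ResultTable, path) -> None:
    """Write a :class:`ResultTable` as TSV.

    Columns: taxon_id, p_<method> per normalization, p_omnibus,
    q_omnibus, significant.
    """
    res.to_frame().to_csv(path, sep="\t", index=False)
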