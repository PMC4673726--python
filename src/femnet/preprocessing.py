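"""Matrix preprocessing: expression normalisation, probe filtering/imputation,
and promoter-priority collapse of probe-level methylation to gene level.

Expression matrices arrive as non-negative gene-normalised counts; zeros are
replaced by the global minimum positive value, the matrix is log2-transformed,
and columns are quantile-normalised so every sample shares one empirical
distribution.  Methylation beta matrices are filtered for probe missingness
and the remaining gaps filled by k-nearest-probe averaging.  Gene-level
methylation uses the promoter region hierarchy TSS200 > 1st exon > TSS1500;
gene-body probes are never used (they are poorly predictive of expression and
typically change in the opposite direction).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

PROMOTER_PRIORITY = ("TSS200", "FirstExon", "TSS1500")


def _quantile_reference(X: np.ndarray) -> np.ndarray:
    """Row-wise mean of the column-sorted matrix (the target distribution)."""
    return np.sort(X, axis=0).mean(axis=1)


def _map_to_reference(col: np.ndarray, ref: np.ndarray) -> np.ndarray:
    """Replace a column's values by reference quantiles; ties get the mean of
    the reference values at the tied sorted positions."""
    order = np.argsort(col, kind="mergesort")
    sorted_vals = col[order]
    out = np.empty_like(ref)
    # runs of equal values share the averaged reference value
    boundaries = np.flatnonzero(np.diff(sorted_vals) != 0) + 1
    starts = np.concatenate(([0], boundaries))
    stops = np.concatenate((boundaries, [len(col)]))
    for a, b in zip(starts, stops):
        out[order[a:b]] = ref[a:b].mean()
    return out


class QuantileNormalizer(BaseEstimator, TransformerMixin):
    """Column-wise quantile normalisation (limma-style ``normalizeQuantiles``).

    ``fit`` learns the reference distribution (mean of column-sorted values);
    ``transform`` maps each column's ranks onto it, averaging the reference
    values over tied ranks.
    """

    def fit(self, X: pd.DataFrame, y=None) -> "QuantileNormalizer":
        arr = np.asarray(X, dtype=float)
        if arr.ndim != 2 or arr.size == 0:
            raise ValueError("expected a non-empty 2-D matrix")
        self.reference_ = _quantile_reference(arr)
        self.n_features_in_ = arr.shape[0]
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        arr = np.asarray(X, dtype=float)
        if arr.shape[0] != self.reference_.shape[0]:
            raise ValueError("row count differs from the fitted reference")
        out = np.column_stack(
            [_map_to_reference(arr[:, j], self.reference_) for j in range(arr.shape[1])]
        )
        if isinstance(X, pd.DataFrame):
            return pd.DataFrame(out, index=X.index, columns=X.columns)
        return out


def preprocess_expression(raw: pd.DataFrame) -> pd.DataFrame:
    """Zero-substitute, log2-transform and quantile-normalise expression.

    Zeros are replaced by the global minimum non-zero positive value before
    the log2 transform regularises the dynamic range.
    """
    arr = np.asarray(raw, dtype=float)
    if np.isnan(arr).any():
        raise ValueError("expression matrix contains missing values")
    if (arr < 0).any():
        raise ValueError("expression matrix contains negative values")
    positive = arr[arr > 0]
    if positive.size == 0:
        raise ValueError("expression matrix is all zero")
    arr = np.where(arr == 0, positive.min(), arr)
    logged = np.log2(arr)
    qn = QuantileNormalizer().fit(logged)
    out = qn.transform(logged)
    return pd.DataFrame(out, index=raw.index, columns=raw.columns)


class ProbeKNNImputer(BaseEstimator, TransformerMixin):
    """Row-wise (probe-wise) filtering and k-nearest-probe imputation.

    Probes missing in more than ``max_missing_frac`` of samples are dropped;
    each remaining missing entry is filled with the mean of the values, at
    that sample, of the ``k`` nearest probes (Euclidean distance over shared
    non-missing samples, scaled by the number of shared samples).
    """

    def __init__(self, max_missing_frac: float = 0.5, k: int = 5):
        self.max_missing_frac = max_missing_frac
        self.k = k

    def fit(self, X: pd.DataFrame, y=None) -> "ProbeKNNImputer":
        if not 0 < self.max_missing_frac <= 1:
            raise ValueError("max_missing_frac must be in (0, 1]")
        if self.k < 1:
            raise ValueError("k must be >= 1")
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        self.fit(X)
        arr = np.asarray(X, dtype=float)
        miss_frac = np.isnan(arr).mean(axis=1)
        keep = miss_frac <= self.max_missing_frac
        if not keep.any():
            raise ValueError("missingness filter removed every probe")
        self.n_dropped_ = int((~keep).sum())
        arr = arr[keep]
        index = X.index[keep] if isinstance(X, pd.DataFrame) else np.arange(arr.shape[0])[keep]
        if np.isnan(arr).any():
            arr = self._impute(arr)
        if isinstance(X, pd.DataFrame):
            return pd.DataFrame(arr, index=index, columns=X.columns)
        return arr

    def _impute(self, arr: np.ndarray) -> np.ndarray:
        k = min(self.k, arr.shape[0] - 1)
        out = arr.copy()
        missing_rows = np.flatnonzero(np.isnan(arr).any(axis=1))
        for i in missing_rows:
            row = arr[i]
            obs_i = ~np.isnan(row)
            diff = arr - row  # nan wherever either is missing
            shared = ~np.isnan(diff)
            n_shared = shared.sum(axis=1)
            with np.errstate(invalid="ignore"):
                d2 = np.nansum(diff**2, axis=1) / np.maximum(n_shared, 1)
            d2[i] = np.inf
            d2[n_shared == 0] = np.inf
            order = np.argsort(d2, kind="mergesort")
            neighbours = order[np.isfinite(d2[order])][:k]
            for j in np.flatnonzero(~obs_i):
                vals = arr[neighbours, j]
                vals = vals[~np.isnan(vals)]
                if vals.size:
                    out[i, j] = vals.mean()
                else:  # no neighbour observed here: fall back to the row mean
                    out[i, j] = np.nanmean(row)
        return out


def filter_and_impute(
    beta: pd.DataFrame, max_missing_frac: float = 0.5, k: int = 5
) -> pd.DataFrame:
    """Drop probes missing in more than ``max_missing_frac`` of samples and
    k-NN-impute the rest.  Returns a complete matrix with values in [0, 1]."""
    vals = np.asarray(beta, dtype=float)
    with np.errstate(invalid="ignore"):
        if np.nanmin(vals) < 0 or np.nanmax(vals) > 1:
            raise ValueError("beta values must lie in [0, 1]")
    return ProbeKNNImputer(max_missing_frac=max_missing_frac, k=k).fit_transform(beta)


def summarize_gene_methylation(
    beta: pd.DataFrame, annot: pd.DataFrame
) -> pd.DataFrame:
    """Collapse probe-level betas to one value per gene.

    A gene's value is the mean over its TSS200 probes; genes without TSS200
    probes fall back to 1st-exon probes, then to TSS1500.  Body probes never
    contribute, and genes covered only by Body probes are absent from the
    output.
    """
    if len(annot) == 0:
        raise ValueError("empty probe annotation")
    annot = annot[annot["probe_id"].isin(beta.index)]
    pieces = []
    claimed: set[str] = set()
    for region in PROMOTER_PRIORITY:
        sub = annot[(annot["region"] == region) & ~annot["gene"].isin(claimed)]
        if len(sub) == 0:
            continue
        vals = beta.loc[sub["probe_id"].to_numpy()]
        vals.index = sub["gene"].to_numpy()
        pieces.append(vals.groupby(level=0).mean())
        claimed.update(sub["gene"])
    if not pieces:
        raise ValueError("no promoter-region probes found")
    out = pd.concat(pieces).sort_index()
    out.index.name = "gene"
    return out


def _warn(msg: str) -> None:
    warnings.warn(msg, stacklevel=3)
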