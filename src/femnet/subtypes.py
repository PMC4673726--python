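"""Integrative two-cluster subtyping: joint clustering stand-in, gene-centred
cluster centroids, and Spearman nearest-centroid classification.

The joint latent-variable clustering used on the real cohorts is deliberately
not reimplemented here; ``joint_cluster_standin`` gives a simple deterministic
stand-in (per-gene standardised methylation and expression stacked and
k-means clustered) and every downstream step accepts any externally produced
partition.  The committed computation is the centroid layer: per data type,
genes are centred to mean zero across the training samples and averaged per
cluster; independent samples are centred with their own means and assigned to
the centroid with the largest Spearman rank correlation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.base import BaseEstimator
from sklearn.cluster import KMeans
from sklearn.metrics import adjusted_rand_score


def _standardize_rows(X: pd.DataFrame) -> pd.DataFrame:
    mu = X.mean(axis=1)
    sd = X.std(axis=1, ddof=1)
    sd = sd.where(sd > 0, 1.0)
    return X.sub(mu, axis=0).div(sd, axis=0)


def joint_cluster_standin(
    D: pd.DataFrame,
    R: pd.DataFrame,
    k: int = 2,
    random_state: int = 0,
    n_init: int = 20,
) -> pd.Series:
    """Cluster matched samples on row-standardised D and R stacked feature-wise.

    Deterministic for a fixed ``random_state`` (k-means with ``n_init``
    restarts).  Returns sample_id -> integer cluster label (0..k-1).
    """
    samples = D.columns.intersection(R.columns)
    if len(samples) < k:
        raise ValueError("k exceeds the number of matched samples")
    if k < 2:
        raise ValueError("k must be >= 2")
    feats = pd.concat(
        [_standardize_rows(D[samples]), _standardize_rows(R[samples])], axis=0
    )
    km = KMeans(n_clusters=k, n_init=n_init, random_state=random_state)
    labels = km.fit_predict(feats.to_numpy().T)
    return pd.Series(labels, index=samples, name="cluster")


@dataclass
class ClusterCentroids:
    """Gene-centred per-cluster mean profiles for both data types."""

    D: pd.DataFrame  # genes x clusters
    R: pd.DataFrame
    genes: list[str]
    clusters: list

    def for_type(self, data_type: str) -> pd.DataFrame:
        if data_type not in ("D", "R"):
            raise ValueError("data_type must be 'D' or 'R'")
        return self.D if data_type == "D" else self.R


def build_centroids(
    D: pd.DataFrame, R: pd.DataFrame, partition: pd.Series, genes: list[str]
) -> ClusterCentroids:
    """Average gene-centred values per cluster, separately for each data type.

    Each gene is first centred to mean zero across the training samples; the
    centroid of a cluster is the mean of the centred values over its members.
    """
    samples = [s for s in partition.index if s in D.columns and s in R.columns]
    part = partition.loc[samples]
    clusters = sorted(partition.unique())  # a cluster losing all samples is an error
    out = {}
    for tag, X in (("D", D), ("R", R)):
        missing = [g for g in genes if g not in X.index]
        if missing:
            raise ValueError(f"genes absent from the {tag} matrix: {missing[:5]}")
        sub = X.loc[genes, samples]
        centred = sub.sub(sub.mean(axis=1), axis=0)
        cols = {}
        for c in clusters:
            members = part.index[part == c]
            if len(members) == 0:
                raise ValueError(f"cluster {c!r} is empty")
            cols[c] = centred[members].mean(axis=1)
        out[tag] = pd.DataFrame(cols)
    return ClusterCentroids(out["D"], out["R"], list(genes), clusters)


def center_genes(X: pd.DataFrame) -> pd.DataFrame:
    """Centre every gene to mean zero across the samples of ``X``.

    This is the preprocessing step applied to an independent data set before
    nearest-centroid classification: it removes per-gene baselines (e.g.
    promoter methylation levels) so the sample profile reflects deviation
    structure rather than gene-level location.
    """
    return X.sub(X.mean(axis=1), axis=0)


def classify_nearest_centroid(
    samples: pd.DataFrame,
    centroids: ClusterCentroids,
    data_type: str = "R",
    center: bool = True,
) -> pd.DataFrame:
    """Assign each sample to the centroid with maximal Spearman correlation.

    With ``center=True`` (default) genes are first centred to mean zero
    within ``samples`` via :func:`center_genes` — the documented two-step
    procedure for independent cohorts.  The classifier core itself compares
    within-sample ranks against centroid ranks, so given a fixed input
    representation it is exactly invariant under strictly monotone
    per-sample transformations.  Returns a frame with the label, the winning
    correlation and flags for ties and constant (unclassifiable) samples.
    """
    cent = centroids.for_type(data_type)
    genes = [g for g in centroids.genes if g in samples.index]
    if len(genes) < 3:
        raise ValueError("need at least 3 centroid genes in the sample matrix")
    sub = samples.loc[genes]
    constant = (sub.nunique(axis=0) <= 1)  # flat profile: rank-free
    if center:
        sub = center_genes(sub)
    cent = cent.loc[genes]
    cent_ranks = np.column_stack([rankdata(cent[c]) for c in cent.columns])
    cent_ranks = (cent_ranks - cent_ranks.mean(axis=0)) / cent_ranks.std(axis=0)
    rows = []
    for s in sub.columns:
        vec = sub[s].to_numpy()
        if constant[s]:
            rows.append({"sample_id": s, "cluster": None, "correlation": np.nan,
                         "tie": False, "unclassifiable": True})
            continue
        r = rankdata(vec)
        r = (r - r.mean()) / r.std()
        corr = r @ cent_ranks / len(genes)
        best = float(corr.max())
        winners = [c for c, v in zip(cent.columns, corr) if v >= best - 1e-12]
        rows.append({
            "sample_id": s,
            "cluster": winners[0],
            "correlation": best,
            "tie": len(winners) > 1,
            "unclassifiable": False,
        })
    out = pd.DataFrame(rows).set_index("sample_id")
    if out["tie"].any():
        warnings.warn("tied centroid correlations broken by cluster order", stacklevel=2)
    return out


def adjusted_rand_index(p1: pd.Series, p2: pd.Series) -> float:
    """Permutation-model adjusted Rand index between two sample partitions."""
    common = p1.index.intersection(p2.index)
    if len(common) == 0:
        raise ValueError("partitions share no samples")
    return float(adjusted_rand_score(p1.loc[common], p2.loc[common]))


class NearestCentroidSubtyper(BaseEstimator):
    """Sklearn-style wrapper: fit centroids from a training partition, predict
    cluster labels for new samples by Spearman nearest centroid."""

    def __init__(self, data_type: str = "R"):
        self.data_type = data_type

    def fit(
        self, D: pd.DataFrame, R: pd.DataFrame, partition: pd.Series,
        genes: list[str] | None = None,
    ) -> "NearestCentroidSubtyper":
        if genes is None:
            genes = list(D.index.intersection(R.index))
        self.centroids_ = build_centroids(D, R, partition, genes)
        return self

    def predict(self, X: pd.DataFrame, center: bool = True) -> pd.Series:
        table = classify_nearest_centroid(X, self.centroids_, self.data_type, center=center)
        return table["cluster"]

    def predict_table(self, X: pd.DataFrame) -> pd.DataFrame:
        return classify_nearest_centroid(X, self.centroids_, self.data_type)
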