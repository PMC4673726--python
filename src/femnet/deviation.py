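"""Per-sample deviation scoring against the normal reference, and the
coordination vs mutual-exclusivity permutation test.

Each gene's methylation and expression are standardised against the mean and
standard deviation estimated over normal samples, giving per-tumour
Z-statistics Z_D and Z_R.  Because the two data types have different
intrinsic spreads, the expression Z is rescaled by

    alpha = sd(all Z_D entries) / sd(all Z_R entries),

computed over ALL genes and tumour samples, not just module genes.  The
module deviation score for sample s is the mean of |Z_D - alpha * Z_R| over
the module's eligible genes — those significant at both the methylation and
expression level whose statistics are anti-correlated (hypermethylated and
underexpressed, or hypomethylated and overexpressed).

For the coordination question each module gets a binary genes x tumours
matrix: entry 1 when both per-sample Gaussian p-values fall below a relaxed
threshold (default 0.1) and the deviation directions match the gene's
cohort-level anti-correlative pattern.  Coordinated deregulation means
different genes flag the same tumours, i.e. a small mean Manhattan distance
between rows; the permutation null shuffles samples independently within
each row (preserving row sums exactly).
"""

from __future__ import annotations

import warnings
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.base import BaseEstimator

from .discovery import FemModule


class NormalReference:
    """Per-gene mean/sd for one data type, estimated over normal samples."""

    def __init__(self, mu: pd.Series, sd: pd.Series, floored: pd.Series):
        self.mu = mu
        self.sd = sd
        self.floored = floored

    @property
    def genes(self) -> pd.Index:
        return self.mu.index


def fit_normal_reference(matrix: pd.DataFrame, phen: pd.DataFrame) -> NormalReference:
    """Estimate the per-gene normal-tissue mean and sd for one data type.

    Requires at least 3 normal samples; zero standard deviations are floored
    to the smallest positive sd observed and flagged.
    """
    normals = phen.loc[phen["group"] == "normal", "sample_id"]
    normals = [s for s in normals if s in matrix.columns]
    if len(normals) < 3:
        raise ValueError("need at least 3 normal samples")
    sub = matrix[normals]
    mu = sub.mean(axis=1)
    sd = sub.std(axis=1, ddof=1)
    floored = sd <= 0
    if floored.any():
        positive = sd[sd > 0]
        if positive.empty:
            raise ValueError("all genes have zero variance in normals")
        sd = sd.where(~floored, positive.min())
        warnings.warn(f"{int(floored.sum())} zero-sd genes floored", stacklevel=2)
    return NormalReference(mu, sd, floored)


def z_statistics(X: pd.DataFrame, ref: NormalReference) -> pd.DataFrame:
    """Elementwise Z = (X - mu) / sigma; genes absent from the reference are
    dropped with a warning."""
    covered = X.index.intersection(ref.genes)
    if len(covered) < len(X.index):
        warnings.warn(
            f"{len(X.index) - len(covered)} genes not in reference dropped", stacklevel=2
        )
    sub = X.loc[covered]
    return sub.sub(ref.mu[covered], axis=0).div(ref.sd[covered], axis=0)


def scaling_factor(Z_D: pd.DataFrame, Z_R: pd.DataFrame) -> float:
    """alpha = sd of all Z_D entries / sd of all Z_R entries."""
    sd_D = float(np.std(np.asarray(Z_D, dtype=float).ravel(), ddof=1))
    sd_R = float(np.std(np.asarray(Z_R, dtype=float).ravel(), ddof=1))
    if sd_R == 0:
        raise ValueError("expression Z-statistics have zero spread")
    return sd_D / sd_R


def eligible_genes(
    module: FemModule, stats: pd.DataFrame, alpha_sig: float = 0.05
) -> list[str]:
    """Module genes significant at both levels with anti-correlated statistics."""
    genes = [g for g in module.members if g in stats.index]
    sub = stats.loc[genes]
    ok = (
        (sub["p_D"] < alpha_sig)
        & (sub["p_R"] < alpha_sig)
        & (sub["t_D"] * sub["t_R"] < 0)
    )
    return list(sub.index[ok])


def fem_score(
    module: FemModule,
    stats: pd.DataFrame,
    Z_D: pd.DataFrame,
    Z_R: pd.DataFrame,
    alpha: float,
    alpha_sig: float = 0.05,
) -> pd.Series | None:
    """Per-sample module deviation score, mean over eligible genes of
    |Z_D - alpha * Z_R|; ``None`` (with a warning) when no gene is eligible."""
    genes = [g for g in eligible_genes(module, stats, alpha_sig) if g in Z_D.index and g in Z_R.index]
    if not genes:
        warnings.warn(f"module {module.seed}: no eligible genes; skipped", stacklevel=2)
        return None
    samples = Z_D.columns.intersection(Z_R.columns)
    diff = (Z_D.loc[genes, samples] - alpha * Z_R.loc[genes, samples]).abs()
    score = diff.mean(axis=0)
    score.name = module.seed
    return score


def binary_deviation_matrix(
    module: FemModule,
    Z_D: pd.DataFrame,
    Z_R: pd.DataFrame,
    stats: pd.DataFrame,
    p_threshold: float = 0.1,
    alpha_sig: float = 0.05,
) -> pd.DataFrame:
    """Binary genes x tumours deviation matrix for one module.

    Entry 1 iff both two-sided Gaussian p-values (from |Z_D| and |Z_R|) are
    below ``p_threshold`` AND the sample's deviation directions reproduce the
    gene's cohort-level anti-correlative pattern (sign(Z) == sign(t) for both
    data types).
    """
    if not 0 < p_threshold < 1:
        raise ValueError("p_threshold must be in (0, 1)")
    genes = [g for g in eligible_genes(module, stats, alpha_sig) if g in Z_D.index and g in Z_R.index]
    samples = Z_D.columns.intersection(Z_R.columns)
    zd = Z_D.loc[genes, samples].to_numpy(dtype=float)
    zr = Z_R.loc[genes, samples].to_numpy(dtype=float)
    p_d = 2.0 * sps.norm.sf(np.abs(zd))
    p_r = 2.0 * sps.norm.sf(np.abs(zr))
    sign_d = np.sign(stats.loc[genes, "t_D"]).to_numpy()[:, None]
    sign_r = np.sign(stats.loc[genes, "t_R"]).to_numpy()[:, None]
    hit = (
        (p_d < p_threshold)
        & (p_r < p_threshold)
        & (np.sign(zd) == sign_d)
        & (np.sign(zr) == sign_r)
    )
    return pd.DataFrame(hit.astype(int), index=genes, columns=samples)


def mean_manhattan(binmat: pd.DataFrame) -> float:
    """Mean Manhattan distance over all unordered row pairs."""
    arr = np.asarray(binmat, dtype=float)
    if arr.shape[0] < 2:
        raise ValueError("need at least 2 rows")
    return _mean_mhd(arr)


def _mean_mhd(arr: np.ndarray) -> float:
    # binary rows: |a - b|_1 = r_a + r_b - 2 a.b, summed over unordered pairs
    m = arr.shape[0]
    rowsums = arr.sum(axis=1)
    gram = arr @ arr.T
    total = 0.0
    for i, j in combinations(range(m), 2):
        total += rowsums[i] + rowsums[j] - 2.0 * gram[i, j]
    return total / (m * (m - 1) / 2)


def coordination_test(
    binmat: pd.DataFrame,
    n_perm: int = 1000,
    alternative: str = "coordinated",
    rng: np.random.Generator | None = None,
) -> dict:
    """Within-row permutation test of the mean Manhattan distance.

    ``alternative='coordinated'`` (default) is lower-tail: coordination means
    rows flag the same samples, so the observed distance is smaller than
    under row-independence.  ``'exclusive'`` tests the upper tail.  Rows are
    shuffled independently, preserving each row's sum exactly.  Constant
    matrices (all 0 or all 1) have a degenerate null and report p = 1.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if alternative not in ("coordinated", "exclusive"):
        raise ValueError("alternative must be 'coordinated' or 'exclusive'")
    rng = np.random.default_rng(rng)
    arr = np.asarray(binmat, dtype=float)
    if arr.shape[0] < 2:
        raise ValueError("need at least 2 rows")
    observed = _mean_mhd(arr)
    vals = arr.ravel()
    if np.all(vals == vals[0]):
        return {
            "observed_mhd": observed,
            "null_mean": observed,
            "p_value": 1.0,
            "degenerate": True,
        }
    null = np.empty(n_perm)
    for b in range(n_perm):
        null[b] = _mean_mhd(rng.permuted(arr, axis=1))
    tol = 1e-12
    if alternative == "coordinated":
        exceed = int(np.sum(null <= observed + tol))
    else:
        exceed = int(np.sum(null >= observed - tol))
    return {
        "observed_mhd": observed,
        "null_mean": float(null.mean()),
        "p_value": (1 + exceed) / (1 + n_perm),
        "degenerate": False,
    }


class DeviationScorer(BaseEstimator):
    """Fit the normal reference and derive Z-statistics, alpha and module
    deviation scores for tumour samples.

    ``fit(D, R, phen)`` estimates the per-gene normal reference for both data
    types and alpha over all tumour samples; ``score_modules(modules, stats)``
    returns the module x sample score table, and ``binary_matrix`` /
    ``coordination`` expose the per-module coordination machinery.
    """

    def __init__(self, alpha_sig: float = 0.05, p_threshold: float = 0.1):
        self.alpha_sig = alpha_sig
        self.p_threshold = p_threshold

    def fit(self, D: pd.DataFrame, R: pd.DataFrame, phen: pd.DataFrame) -> "DeviationScorer":
        self.ref_D_ = fit_normal_reference(D, phen)
        self.ref_R_ = fit_normal_reference(R, phen)
        tumours = [
            s for s in phen.loc[phen["group"] == "tumour", "sample_id"]
            if s in D.columns and s in R.columns
        ]
        if not tumours:
            raise ValueError("no tumour samples with both data types")
        self.tumours_ = tumours
        self.Z_D_ = z_statistics(D[tumours], self.ref_D_)
        self.Z_R_ = z_statistics(R[tumours], self.ref_R_)
        self.alpha_ = scaling_factor(self.Z_D_, self.Z_R_)
        return self

    def score_modules(self, modules: list[FemModule], stats: pd.DataFrame) -> pd.DataFrame:
        scores = []
        for mod in modules:
            s = fem_score(mod, stats, self.Z_D_, self.Z_R_, self.alpha_, self.alpha_sig)
            if s is not None:
                scores.append(s)
        return pd.DataFrame(scores)

    def score_samples(
        self, module: FemModule, stats: pd.DataFrame, D: pd.DataFrame, R: pd.DataFrame
    ) -> pd.Series | None:
        """Score arbitrary samples (e.g. normals) against the fitted reference."""
        zd = z_statistics(D, self.ref_D_)
        zr = z_statistics(R, self.ref_R_)
        return fem_score(module, stats, zd, zr, self.alpha_, self.alpha_sig)

    def binary_matrix(self, module: FemModule, stats: pd.DataFrame) -> pd.DataFrame:
        return binary_deviation_matrix(
            module, self.Z_D_, self.Z_R_, stats, self.p_threshold, self.alpha_sig
        )

    def coordination(
        self,
        module: FemModule,
        stats: pd.DataFrame,
        n_perm: int = 1000,
        rng: np.random.Generator | None = None,
    ) -> dict:
        binmat = self.binary_matrix(module, stats)
        if binmat.shape[0] < 2:
            return {"observed_mhd": np.nan, "null_mean": np.nan, "p_value": np.nan,
                    "degenerate": True}
        return coordination_test(binmat, n_perm=n_perm, rng=rng)
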