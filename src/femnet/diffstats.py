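"""Per-gene differential statistics with empirical-Bayes variance moderation.

Two-group (normal vs tumour) moderated t-statistics in the limma style: the
per-gene pooled variance is shrunk towards a prior variance whose scale and
prior degrees of freedom are estimated by the method of moments on the log
sample variances, and the t-statistic is referred to a t distribution with
the augmented degrees of freedom.  This stabilises the variance estimates of
individual genes, which matters most for methylation data where many genes
have small residual variance.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import special, stats
from sklearn.base import BaseEstimator


def trigamma_inverse(y: float, n_iter: int = 50) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration.

    Monotone decreasing target; the iteration below (on 1/x, effectively)
    converges for any positive y.
    """
    if y <= 0:
        return np.inf
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(n_iter):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x += dif
        if abs(dif) < 1e-10 * x:
            break
    return float(x)


def fit_f_dist(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Moment estimates (prior df d0, prior variance s0^2) for scaled-F
    distributed sample variances, via the log-variance moments."""
    s2 = np.asarray(s2, dtype=float)
    ok = s2 > 0
    z = np.log(s2[ok])
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    emean = e.mean()
    n = e.size
    if n < 2:
        return np.inf, float(np.exp(emean))
    evar = ((e - emean) ** 2).sum() / (n - 1) - special.polygamma(1, df / 2.0)
    if evar > 0:
        d0 = 2.0 * trigamma_inverse(evar)
        s02 = np.exp(emean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0))
    else:
        # no excess spread in the log variances: complete shrinkage to the
        # common variance (the arithmetic mean of the sample variances)
        d0 = np.inf
        s02 = float(np.mean(s2[ok]))
    return float(d0), float(s02)


class ModeratedTTest(BaseEstimator):
    """Two-group moderated t-test over a genes x samples matrix.

    Parameters
    ----------
    prior_df : float or None
        Prior degrees of freedom d0.  ``None`` (default) estimates d0 and the
        prior variance by the method of moments on log sample variances;
        ``0`` reduces to the ordinary pooled two-sample t-test.
    var_floor : bool
        Replace zero pooled variances by the smallest positive pooled
        variance before moderation (the affected genes are flagged in
        ``degenerate_``).

    Fitted attributes (all aligned to the input gene index): ``t_``, ``p_``,
    ``mean_diff_``, ``s2_post_``, plus scalars ``df_prior_``, ``s2_prior_``,
    ``df_residual_``.
    """

    def __init__(self, prior_df: float | None = None, var_floor: bool = True):
        self.prior_df = prior_df
        self.var_floor = var_floor

    def fit(self, X: pd.DataFrame, y) -> "ModeratedTTest":
        """``X``: genes x samples matrix; ``y``: per-sample group labels with
        exactly two levels; the difference is level2 - level1 where the
        levels are ('normal', 'tumour') when present, else sorted order."""
        arr = np.asarray(X, dtype=float)
        y = np.asarray(y)
        levels = _group_levels(y)
        g1 = arr[:, y == levels[0]]
        g2 = arr[:, y == levels[1]]
        n1, n2 = g1.shape[1], g2.shape[1]
        if n1 < 2 or n2 < 2:
            raise ValueError("need at least 2 samples per group")
        if not np.isfinite(arr).all():
            raise ValueError("matrix contains non-finite values")
        diff = g2.mean(axis=1) - g1.mean(axis=1)
        df_resid = n1 + n2 - 2
        s2 = ((g1.var(axis=1, ddof=1) * (n1 - 1)) + (g2.var(axis=1, ddof=1) * (n2 - 1))) / df_resid

        degenerate = s2 <= 0
        if degenerate.any():
            if not self.var_floor or not (~degenerate).any():
                raise ValueError("zero-variance genes with no positive variance to floor to")
            s2 = np.where(degenerate, s2[~degenerate].min(), s2)
            warnings.warn(f"{int(degenerate.sum())} zero-variance genes floored", stacklevel=2)

        if self.prior_df is None:
            d0, s02 = fit_f_dist(s2, df_resid)
        else:
            d0 = float(self.prior_df)
            s02 = float(fit_f_dist(s2, df_resid)[1]) if d0 > 0 else 0.0
        if np.isinf(d0):
            s2_post = np.full_like(s2, s02)
        elif d0 == 0:
            s2_post = s2
        else:
            s2_post = (d0 * s02 + df_resid * s2) / (d0 + df_resid)

        c = np.sqrt(1.0 / n1 + 1.0 / n2)
        t = diff / (np.sqrt(s2_post) * c)
        # total df capped at the pooled residual df across all genes
        df_total = min(df_resid + d0, df_resid * len(s2))
        p = 2.0 * stats.t.sf(np.abs(t), df=df_total)

        index = X.index if isinstance(X, pd.DataFrame) else pd.RangeIndex(arr.shape[0])
        self.groups_ = (levels[0], levels[1])
        self.t_ = pd.Series(t, index=index, name="t")
        self.p_ = pd.Series(p, index=index, name="p")
        self.mean_diff_ = pd.Series(diff, index=index, name="mean_diff")
        self.s2_post_ = pd.Series(s2_post, index=index, name="s2_post")
        self.degenerate_ = pd.Series(degenerate, index=index, name="degenerate")
        self.df_prior_ = d0
        self.s2_prior_ = s02
        self.df_residual_ = float(df_resid)
        return self

    @property
    def stats_(self) -> pd.DataFrame:
        return pd.DataFrame({"t": self.t_, "p": self.p_})


def _group_levels(y: np.ndarray) -> tuple:
    levels = sorted(set(map(str, y)))
    if len(levels) != 2:
        raise ValueError(f"expected exactly 2 groups, got {levels}")
    if set(levels) == {"normal", "tumour"}:
        return ("normal", "tumour")
    return tuple(levels)


def moderated_t(
    matrix: pd.DataFrame, phen: pd.DataFrame, prior_df: float | None = None
) -> pd.DataFrame:
    """Per-gene moderated t and two-sided p for tumour minus normal.

    ``phen`` must carry ``sample_id`` and ``group`` columns; only samples
    present in both the matrix and the phenotype table are used.
    """
    common = [s for s in matrix.columns if s in set(phen["sample_id"])]
    groups = phen.set_index("sample_id").loc[common, "group"].to_numpy()
    model = ModeratedTTest(prior_df=prior_df).fit(matrix[common], groups)
    return model.stats_


def scale_statistics(stats_D: pd.DataFrame, stats_R: pd.DataFrame) -> pd.DataFrame:
    """Rescale the mRNA t-statistics so both data types have equal spread.

    t_R is multiplied by sd(t_D)/sd(t_R) computed over the genes common to
    both statistic vectors; p-values are unchanged.
    """
    common = stats_D.index.intersection(stats_R.index)
    if len(common) < 2:
        raise ValueError("need at least 2 common genes to scale")
    sd_D = stats_D.loc[common, "t"].std(ddof=1)
    sd_R = stats_R.loc[common, "t"].std(ddof=1)
    if sd_R == 0:
        raise ValueError("mRNA statistics have zero spread")
    out = stats_R.copy()
    out["t"] = out["t"] * (sd_D / sd_R)
    return out


def combine_stats(stats_D: pd.DataFrame, stats_R: pd.DataFrame) -> pd.DataFrame:
    """Join methylation and expression statistics over their common genes into
    one frame with columns t_D, p_D, t_R, p_R."""
    common = stats_D.index.intersection(stats_R.index)
    if len(common) == 0:
        raise ValueError("no genes shared between the two statistic sets")
    return pd.DataFrame(
        {
            "t_D": stats_D.loc[common, "t"],
            "p_D": stats_D.loc[common, "p"],
            "t_R": stats_R.loc[common, "t"],
            "p_R": stats_R.loc[common, "p"],
        }
    )
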