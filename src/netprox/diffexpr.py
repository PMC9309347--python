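"""Two-group differential expression with empirical-Bayes moderated t-tests.

The model is the standard microarray one: log2 intensities are quantile
normalized across arrays, each gene gets a two-sample linear contrast
(log fold change, pooled residual variance s2 on df = n_A + n_B - 2), and the
gene-wise variances are shrunk toward an empirical-Bayes prior. The prior is
the scaled inverse-chi-square with hyperparameters (d0, s0sq), fitted by
method of moments on log s2 via digamma/trigamma identities; the posterior
variance

    s2_post = (d0 * s0sq + df * s2) / (d0 + df)

yields a moderated t-statistic referred to a t distribution with d0 + df
degrees of freedom (normal in the infinite-d0 limit). P-values are adjusted
by Benjamini-Hochberg, and the disease signature is the set of genes with
adjusted p strictly below 0.01 and |log2 FC| strictly above 0.25.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats
from sklearn.base import BaseEstimator
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)


@dataclass
class PriorEstimate:
    """Hyperparameters of the scaled inverse-chi-square variance prior."""

    d0: float    # prior degrees of freedom; math.inf when log-variances have no excess spread
    s0sq: float  # prior (location) variance, > 0

    @property
    def is_infinite(self) -> bool:
        return math.isinf(self.d0)


@dataclass
class FilterParams:
    """Signature filter thresholds; both inequalities are strict."""

    p_adj_max: float = 0.01
    lfc_min: float = 0.25

    def __post_init__(self):
        if self.p_adj_max <= 0 or self.lfc_min <= 0:
            raise ValueError("filter thresholds must be positive")


def quantile_normalize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Force every sample (column) onto the common mean quantile profile.

    Each column's sorted values are replaced by the row-wise mean of all
    sorted columns; ties share the mean of their rank span. Gene and sample
    ordering are preserved.
    """
    if matrix.shape[1] < 2:
        raise ValueError("quantile normalization needs >= 2 samples")
    values = matrix.to_numpy(dtype=float)
    n = values.shape[0]
    mean_profile = np.sort(values, axis=0).mean(axis=1)
    out = np.empty_like(values)
    positions = np.arange(1, n + 1, dtype=float)
    for j in range(values.shape[1]):
        ranks = stats.rankdata(values[:, j], method="average")
        out[:, j] = np.interp(ranks, positions, mean_profile)
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


def fit_groups(matrix: pd.DataFrame, groups: pd.Series) -> pd.DataFrame:
    """Per-gene two-sample contrast: logfc, pooled variance s2 and df.

    ``logfc`` is mean(second group) - mean(first group), the group order
    taken from the sample sheet's first appearances. Genes with zero
    within-group variance in both groups are retained with s2 = 0 and
    flagged in the ``zero_variance`` column.
    """
    groups = groups.reindex(matrix.columns)
    if groups.isna().any():
        missing = list(matrix.columns[groups.isna()])
        raise ValueError(f"samples missing from sheet: {missing}")
    labels = list(dict.fromkeys(groups))
    if len(labels) != 2:
        raise ValueError(f"exactly two groups required, got {labels}")
    a, b = labels
    xa = matrix.loc[:, groups == a].to_numpy(dtype=float)
    xb = matrix.loc[:, groups == b].to_numpy(dtype=float)
    na, nb = xa.shape[1], xb.shape[1]
    if na < 2 or nb < 2:
        raise ValueError("each group needs >= 2 samples")

    logfc = xb.mean(axis=1) - xa.mean(axis=1)
    ss = ((xa - xa.mean(axis=1, keepdims=True)) ** 2).sum(axis=1) + (
        (xb - xb.mean(axis=1, keepdims=True)) ** 2
    ).sum(axis=1)
    df = na + nb - 2
    s2 = ss / df
    return pd.DataFrame(
        {
            "logfc": logfc,
            "s2": s2,
            "df": float(df),
            "n_a": na,
            "n_b": nb,
            "zero_variance": s2 == 0.0,
        },
        index=matrix.index,
    )


def _trigamma_inverse(x: float) -> float:
    # Newton iteration on the monotone map y -> trigamma(y); the usual
    # asymptotic guesses bracket the solution well.
    if x <= 0:
        raise ValueError("trigamma inverse needs a positive argument")
    if x > 1e7:
        return 1.0 / math.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(75):
        tri = float(special.polygamma(1, y))
        step = tri * (1.0 - tri / x) / float(special.polygamma(2, y))
        y += step
        if abs(step) < 1e-10 * y:
            break
    return y


def estimate_prior(s2: np.ndarray, df: np.ndarray | float) -> PriorEstimate:
    """Method-of-moments fit of (d0, s0sq) on the log residual variances.

    Under the scaled inverse-chi-square prior, e = log s2 - digamma(df/2)
    + log(df/2) has mean log s0sq - digamma(d0/2) + log(d0/2) and variance
    trigamma(df/2) + trigamma(d0/2); matching the sample moments gives the
    estimates. When the sample spread of e does not exceed the sampling
    contribution trigamma(df/2), d0 is flagged infinite and s0sq is the
    bias-corrected geometric mean of s2.
    """
    s2 = np.asarray(s2, dtype=float)
    df = np.broadcast_to(np.asarray(df, dtype=float), s2.shape)
    ok = (s2 > 0) & (df > 0) & np.isfinite(s2)
    if not ok.any():
        raise ValueError("cannot estimate the variance prior: all variances are zero")
    if ok.sum() < 10:
        raise ValueError(
            f"cannot estimate the variance prior: only {int(ok.sum())} positive "
            "variances (>= 10 required)"
        )
    s2, df = s2[ok], df[ok]
    e = np.log(s2) - special.digamma(df / 2.0) + np.log(df / 2.0)
    emean = float(e.mean())
    evar = float(e.var(ddof=1))
    excess = evar - float(special.polygamma(1, df / 2.0).mean())
    if excess <= 0:
        return PriorEstimate(d0=math.inf, s0sq=float(np.exp(emean)))
    d0 = 2.0 * _trigamma_inverse(excess)
    s0sq = float(np.exp(emean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    return PriorEstimate(d0=d0, s0sq=s0sq)


def moderated_t(
    logfc: np.ndarray,
    s2: np.ndarray,
    df: np.ndarray | float,
    prior: PriorEstimate,
    n_a: int,
    n_b: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Moderated t-statistics and two-sided p-values for a two-group contrast.

    d0 = 0 recovers the ordinary pooled t-test; d0 = inf replaces every
    gene's variance by s0sq and refers t to the normal. Genes whose posterior
    variance is exactly zero get t = +-inf and p = 0.
    """
    logfc = np.asarray(logfc, dtype=float)
    s2 = np.asarray(s2, dtype=float)
    df = np.broadcast_to(np.asarray(df, dtype=float), s2.shape).astype(float)
    if prior.s0sq <= 0 and not prior.is_infinite and prior.d0 > 0:
        raise ValueError("prior s0sq must be positive")
    if prior.is_infinite:
        s2_post = np.full_like(s2, prior.s0sq)
        df_total = np.full_like(s2, np.inf)
    else:
        s2_post = (prior.d0 * prior.s0sq + df * s2) / (prior.d0 + df)
        df_total = prior.d0 + df
    se2 = s2_post * (1.0 / n_a + 1.0 / n_b)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = logfc / np.sqrt(se2)
    zero = se2 == 0.0
    if zero.any():
        t[zero] = np.where(logfc[zero] >= 0, np.inf, -np.inf)
        logger.warning("%d genes have zero posterior variance; p set to 0", zero.sum())
    p = 2.0 * stats.t.sf(np.abs(t), df_total)
    p[zero] = 0.0
    return t, p


def bh_adjust(p_raw: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in the input order."""
    p = np.asarray(p_raw, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def filter_signature(results: pd.DataFrame, params: FilterParams | None = None) -> list[str]:
    """Genes passing the signature filter, ordered by (p_adj, gene id).

    Both cuts are strict: p_adj < p_adj_max and |logfc| > lfc_min.
    """
    params = params or FilterParams()
    passing = results[
        (results["p_adj"] < params.p_adj_max)
        & (results["logfc"].abs() > params.lfc_min)
    ]
    if "gene" in passing.columns:
        return list(passing.sort_values(["p_adj", "gene"], kind="mergesort")["gene"])
    passing = passing.copy()
    passing["_id"] = passing.index.astype(str)
    return list(passing.sort_values(["p_adj", "_id"], kind="mergesort").index)


class ModeratedTTest(BaseEstimator):
    """Sklearn-style estimator for the full moderated-t pipeline.

    ``fit(X, y)`` takes a samples x genes matrix (array or DataFrame; gene
    names come from DataFrame columns) and per-sample group labels. Fitted
    attributes: ``prior_`` (the empirical-Bayes hyperparameters),
    ``results_`` (per-gene table with logFC, t, raw and adjusted p, pass
    flag) and ``signature_`` (ordered list of passing gene ids).

    Parameters
    ----------
    normalize : quantile-normalize the samples before fitting.
    p_adj_max, lfc_min : strict signature-filter thresholds.
    shrink : set False to skip moderation (d0 = 0, ordinary pooled t).
    """

    def __init__(self, normalize: bool = True, p_adj_max: float = 0.01,
                 lfc_min: float = 0.25, shrink: bool = True):
        self.normalize = normalize
        self.p_adj_max = p_adj_max
        self.lfc_min = lfc_min
        self.shrink = shrink

    def fit(self, X, y):
        if isinstance(X, pd.DataFrame):
            genes = [str(g) for g in X.columns]
            samples = [str(s) for s in X.index]
            values = X.to_numpy(dtype=float)
        else:
            values = np.asarray(X, dtype=float)
            if values.ndim != 2:
                raise ValueError("X must be a 2-d samples x genes matrix")
            genes = [f"G{i + 1:06d}" for i in range(values.shape[1])]
            samples = [f"S{i + 1:03d}" for i in range(values.shape[0])]
        y = np.asarray(y)
        if y.shape[0] != values.shape[0]:
            raise ValueError("y must hold one group label per sample (row of X)")
        if np.isnan(values).any():
            keep = ~np.isnan(values).any(axis=0)
            logger.warning("dropping %d genes with missing values", (~keep).sum())
            values, genes = values[:, keep], [g for g, k in zip(genes, keep) if k]

        matrix = pd.DataFrame(values.T, index=genes, columns=samples)
        groups = pd.Series([str(v) for v in y], index=samples)
        if self.normalize:
            matrix = quantile_normalize(matrix)
        fits = fit_groups(matrix, groups)
        if self.shrink:
            self.prior_ = estimate_prior(fits["s2"].to_numpy(), fits["df"].to_numpy())
        else:
            self.prior_ = PriorEstimate(d0=0.0, s0sq=1.0)
        t, p = moderated_t(
            fits["logfc"].to_numpy(), fits["s2"].to_numpy(), fits["df"].to_numpy(),
            self.prior_, int(fits["n_a"].iloc[0]), int(fits["n_b"].iloc[0]),
        )
        p_adj = bh_adjust(p)
        results = pd.DataFrame(
            {
                "gene": genes,
                "logfc": fits["logfc"].to_numpy(),
                "s2": fits["s2"].to_numpy(),
                "df": fits["df"].to_numpy(),
                "t_mod": t,
                "p_raw": p,
                "p_adj": p_adj,
            }
        )
        params = FilterParams(p_adj_max=self.p_adj_max, lfc_min=self.lfc_min)
        results["passes"] = (results["p_adj"] < params.p_adj_max) & (
            results["logfc"].abs() > params.lfc_min
        )
        self.results_ = results
        self.signature_ = filter_signature(results, params)
        self.groups_ = list(dict.fromkeys(groups))
        return self

    def transform(self, X=None):
        """Return the per-gene results table of the fitted contrast."""
        if not hasattr(self, "results_"):
            raise ValueError("ModeratedTTest is not fitted yet")
        return self.results_


def run_diffexpr(
    matrix: pd.DataFrame,
    groups: pd.Series,
    params: FilterParams | None = None,
    normalize: bool = True,
) -> tuple[pd.DataFrame, list[str], PriorEstimate]:
    """Convenience wrapper: genes x samples in, (results, signature, prior) out."""
    params = params or FilterParams()
    est = ModeratedTTest(
        normalize=normalize, p_adj_max=params.p_adj_max, lfc_min=params.lfc_min
    ).fit(matrix.T, groups.reindex(matrix.columns))
    return est.results_, est.signature_, est.prior_
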