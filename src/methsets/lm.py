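"""Per-feature linear models with empirical-Bayes variance moderation.

This is the shared engine behind both the epigenome-wide association
analysis (response = methylation beta values) and differential gene
expression (response = log2 expression).  Each feature (CpG or gene) is
regressed on the same design matrix by ordinary least squares; the
per-feature residual variances are then shrunk toward a pooled prior
estimated by the method of moments on log s^2, giving moderated
t-statistics with ``d0 + d`` degrees of freedom.  Multiple-testing
helpers (Benjamini-Hochberg FDR, genomic inflation factor) and principal
component scores for design-matrix adjustment live here too.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, stats
from scipy.special import digamma, polygamma
from statsmodels.stats.multitest import multipletests

__all__ = [
    "DesignError",
    "FeatureFit",
    "ModeratedStats",
    "PCAResult",
    "build_design",
    "validate_design",
    "fit_feature_lm",
    "ebayes_moderate",
    "bh_fdr",
    "genomic_inflation",
    "pca_scores",
]

#: Median of the 1-df chi-square distribution, the null expectation used
#: by the genomic inflation factor.
CHI2_MEDIAN_1DF = float(stats.chi2.ppf(0.5, 1))  # 0.45493642...


class DesignError(ValueError):
    """Raised for rank-deficient or misaligned design matrices."""


# ---------------------------------------------------------------------------
# design matrices
# ---------------------------------------------------------------------------

def build_design(
    covariates: pd.DataFrame,
    terms: list[str],
    pcs: pd.DataFrame | None = None,
    intercept: bool = True,
) -> pd.DataFrame:
    """Assemble a design matrix from a covariate table.

    Object/categorical columns are dummy-encoded with the first level as
    reference.  ``pcs`` (sample x k principal-component scores) are
    appended as extra columns.  Rows keep the covariate table's sample
    order.
    """
    blocks: list[pd.DataFrame] = []
    if intercept:
        blocks.append(pd.DataFrame({"Intercept": 1.0}, index=covariates.index))
    for term in terms:
        if term not in covariates.columns:
            raise DesignError(f"covariate {term!r} not found")
        col = covariates[term]
        if col.dtype == object or isinstance(col.dtype, pd.CategoricalDtype):
            dummies = pd.get_dummies(col, prefix=term, drop_first=True, dtype=float)
            blocks.append(dummies)
        else:
            blocks.append(col.astype(float).to_frame(term))
    if pcs is not None:
        if not pcs.index.equals(covariates.index):
            pcs = pcs.reindex(covariates.index)
        blocks.append(pcs.astype(float))
    X = pd.concat(blocks, axis=1)
    if X.isna().any().any():
        raise DesignError("design matrix contains missing values")
    return X


def validate_design(X: pd.DataFrame, exposure: str | None = None) -> None:
    """Check full column rank (naming collinear columns) and, optionally,
    that the exposure column is a 0/1 indicator."""
    A = np.asarray(X, dtype=float)
    n, p = A.shape
    if n <= p:
        raise DesignError(f"need more samples ({n}) than design columns ({p})")
    rank = np.linalg.matrix_rank(A)
    if rank < p:
        # QR with pivoting: trailing pivots with negligible diagonal are the
        # columns expressible from the earlier ones.
        _, R, piv = linalg.qr(A, mode="economic", pivoting=True)
        diag = np.abs(np.diag(R))
        tol = diag.max() * max(A.shape) * np.finfo(float).eps
        bad = [X.columns[j] for j in piv[diag < tol]]
        raise DesignError(f"design matrix is rank deficient; collinear columns: {bad}")
    if exposure is not None:
        vals = set(np.unique(np.asarray(X[exposure], dtype=float)))
        if not vals <= {0.0, 1.0}:
            raise DesignError(f"exposure column {exposure!r} is not a 0/1 indicator")


# ---------------------------------------------------------------------------
# least squares stage
# ---------------------------------------------------------------------------

@dataclass
class FeatureFit:
    """Per-feature OLS output for one tested coefficient.

    ``se = sigma * stdev_unscaled`` and ``df_resid = n - rank(X)`` for
    every feature with complete data.
    """

    coef: pd.Series
    sigma: pd.Series
    df_resid: int
    stdev_unscaled: float
    tested: str
    n_samples: int
    rank: int
    dropped: list = field(default_factory=list)
    zero_variance: pd.Index = field(default_factory=lambda: pd.Index([]))

    @property
    def se(self) -> pd.Series:
        return self.sigma * self.stdev_unscaled


def fit_feature_lm(Y: pd.DataFrame, X: pd.DataFrame, test_column: str) -> FeatureFit:
    """Ordinary least squares of every row of ``Y`` (feature x sample) on
    the design ``X``; returns the tested coefficient, residual SD and df.

    Features containing missing values are dropped from the fit and
    listed in ``FeatureFit.dropped``.  Features with (numerically) zero
    residual variance are flagged in ``zero_variance``.
    """
    if list(Y.columns) != list(X.index):
        if set(Y.columns) == set(X.index):
            Y = Y.loc[:, X.index]
        else:
            raise DesignError("Y columns and design rows name different samples")
    validate_design(X)
    if test_column not in X.columns:
        raise DesignError(f"tested column {test_column!r} not in design")

    keep = ~Y.isna().any(axis=1)
    dropped = list(Y.index[~keep])
    Yc = Y.loc[keep]
    A = np.asarray(X, dtype=float)
    n, p = A.shape
    j = list(X.columns).index(test_column)

    xtx_inv = np.linalg.inv(A.T @ A)
    B = Yc.to_numpy(dtype=float) @ (xtx_inv @ A.T).T  # features x p
    resid = Yc.to_numpy(dtype=float) - B @ A.T
    df = n - p
    rss = np.einsum("ij,ij->i", resid, resid)
    sigma = np.sqrt(np.maximum(rss, 0.0) / df)
    scale = np.nanmean(Yc.to_numpy(dtype=float) ** 2) if len(Yc) else 1.0
    zero = Yc.index[sigma**2 <= 1e-14 * max(scale, 1e-300)]

    return FeatureFit(
        coef=pd.Series(B[:, j], index=Yc.index, name=test_column),
        sigma=pd.Series(sigma, index=Yc.index, name="sigma"),
        df_resid=df,
        stdev_unscaled=float(np.sqrt(xtx_inv[j, j])),
        tested=test_column,
        n_samples=n,
        rank=p,
        dropped=dropped,
        zero_variance=zero,
    )


# ---------------------------------------------------------------------------
# empirical-Bayes moderation
# ---------------------------------------------------------------------------

@dataclass
class ModeratedStats:
    """Moderated t-statistics after shrinking residual variances.

    Posterior variance ``s2_post = (d0*s0^2 + d*s^2) / (d0 + d)``;
    ``t = coef / (sqrt(s2_post) * stdev_unscaled)`` on ``d0 + d`` df.
    """

    prior_df: float
    prior_var: float
    s2_post: pd.Series
    t: pd.Series
    p: pd.Series
    fdr: pd.Series
    coef: pd.Series
    se: pd.Series
    df_total: float


def _trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x for y > 0 by Newton iteration."""
    if x <= 0:
        return np.inf
    if x > 1e7:
        return 1.0 / np.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(75):
        tri = polygamma(1, y)
        dif = tri * (1.0 - tri / x) / polygamma(2, y)
        y += dif
        if abs(dif) / y < 1e-8:
            break
    return float(y)


def estimate_prior(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Method-of-moments fit of the scaled inverse chi-square prior on
    residual variances: matches the mean and variance of log s^2 against
    digamma/trigamma expressions, returning (prior df d0, prior var s0^2).
    d0 = inf when the observed spread of log s^2 is no larger than the
    sampling spread expected from chi-square variation alone.
    """
    s2 = np.asarray(s2, dtype=float)
    ok = s2 > 0
    if ok.sum() < 2:
        raise ValueError("need at least 2 features with positive residual variance")
    z = np.log(s2[ok])
    e = z - digamma(df / 2.0) + np.log(df / 2.0)
    emean = e.mean()
    evar = e.var(ddof=1) - polygamma(1, df / 2.0)
    if evar > 0:
        d0 = 2.0 * _trigamma_inverse(float(evar))
        s0_2 = float(np.exp(emean + digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    else:
        d0 = np.inf
        s0_2 = float(np.exp(emean))
    return float(d0), s0_2


def moderated_t_from_arrays(
    coef: np.ndarray,
    s2: np.ndarray,
    df: float,
    stdev_unscaled: float,
    d0: float,
    s0_2: float,
) -> tuple[np.ndarray, np.ndarray, float, np.ndarray]:
    """Posterior variances, moderated t, total df and two-sided p for a
    given prior."""
    if np.isinf(d0):
        s2_post = np.full_like(np.asarray(s2, dtype=float), s0_2)
        df_total = np.inf
    elif d0 == 0:
        s2_post = np.asarray(s2, dtype=float)
        df_total = df
    else:
        s2_post = (d0 * s0_2 + df * np.asarray(s2, dtype=float)) / (d0 + df)
        df_total = d0 + df
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.asarray(coef, dtype=float) / (np.sqrt(s2_post) * stdev_unscaled)
    if np.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df_total)
    return s2_post, t, float(df_total), p  # type: ignore[return-value]


def ebayes_moderate(
    fit: FeatureFit,
    prior_df: float | None = None,
    prior_var: float | None = None,
) -> ModeratedStats:
    """Empirical-Bayes moderation of a :class:`FeatureFit`.

    ``prior_df``/``prior_var`` may be forced (0 reproduces the ordinary
    t-test exactly; inf replaces every variance by the prior); by default
    both are estimated from the fit by :func:`estimate_prior`.
    """
    s2 = fit.sigma.to_numpy() ** 2
    if prior_df is None or prior_var is None:
        est_d0, est_s0 = estimate_prior(s2, fit.df_resid)
        d0 = est_d0 if prior_df is None else prior_df
        s0_2 = est_s0 if prior_var is None else prior_var
    else:
        d0, s0_2 = prior_df, prior_var
    s2_post, t, df_total, p = moderated_t_from_arrays(
        fit.coef.to_numpy(), s2, fit.df_resid, fit.stdev_unscaled, d0, s0_2
    )
    idx = fit.coef.index
    return ModeratedStats(
        prior_df=d0,
        prior_var=s0_2,
        s2_post=pd.Series(s2_post, index=idx),
        t=pd.Series(t, index=idx),
        p=pd.Series(p, index=idx),
        fdr=pd.Series(bh_fdr(p), index=idx),
        coef=fit.coef,
        se=pd.Series(np.sqrt(s2_post) * fit.stdev_unscaled, index=idx),
        df_total=df_total,
    )


def results_table(
    mod: ModeratedStats, annotation: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Per-feature results (coefficient, SE, t, p, FDR), optionally joined
    with probe annotation columns (chromosome, position, genes)."""
    tab = pd.DataFrame(
        {
            "coef": mod.coef,
            "se": mod.se,
            "t": mod.t,
            "p": mod.p,
            "fdr": mod.fdr,
        }
    )
    if annotation is not None:
        tab = annotation.join(tab, how="right")
    return tab.sort_values("p")


# ---------------------------------------------------------------------------
# multiple testing & diagnostics
# ---------------------------------------------------------------------------

def bh_fdr(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, order-preserving."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def genomic_inflation(p) -> float:
    """Genomic inflation factor lambda.

    P-values are converted to 1-df chi-square quantiles; lambda is the
    ratio of their median to the null median (~0.4549).  Any p = 0 maps
    to an infinite statistic, so +inf is returned with a warning.
    """
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if np.any(p == 0):
        warnings.warn("p-value of 0 gives an infinite inflation factor")
        return float(np.inf)
    chi2 = stats.chi2.isf(p, 1)
    return float(np.median(chi2) / CHI2_MEDIAN_1DF)


# ---------------------------------------------------------------------------
# principal components
# ---------------------------------------------------------------------------

@dataclass
class PCAResult:
    scores: pd.DataFrame       # sample x k
    loadings: np.ndarray       # feature x k
    explained_ratio: np.ndarray


def pca_scores(M: pd.DataFrame, k: int) -> PCAResult:
    """Top-k principal component scores of the samples of a feature x
    sample matrix after feature (row) centering.

    Deterministic up to sign; the sign of each component is fixed so that
    its largest-magnitude feature loading is positive.
    """
    A = np.asarray(M, dtype=float)
    if np.isnan(A).any():
        raise ValueError("matrix contains missing values")
    n_feat, n_samp = A.shape
    if not (1 <= k <= min(n_feat, n_samp)):
        raise ValueError(f"k={k} out of range for a {n_feat}x{n_samp} matrix")
    Ac = A - A.mean(axis=1, keepdims=True)
    U, S, Vt = np.linalg.svd(Ac, full_matrices=False)
    signs = np.sign(U[np.argmax(np.abs(U), axis=0), np.arange(U.shape[1])])
    signs[signs == 0] = 1.0
    U *= signs
    Vt *= signs[:, None]
    total = (S**2).sum()
    scores = (Vt[:k].T * S[:k])
    cols = [f"PC{i+1}" for i in range(k)]
    index = M.columns if isinstance(M, pd.DataFrame) else pd.RangeIndex(n_samp)
    return PCAResult(
        scores=pd.DataFrame(scores, index=index, columns=cols),
        loadings=U[:, :k],
        explained_ratio=(S[:k] ** 2) / total if total > 0 else np.zeros(k),
    )
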