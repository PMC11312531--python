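"""Shared statistical primitives.

All model fits in the package go through this module so that one aliasing
policy, one p-value convention (two-sided), and one CI convention
(estimate ± t_crit(df)·SE) hold everywhere.

The ordinary-least-squares fit is rank-revealing with a *first-come-kept*
aliasing policy: columns are admitted left to right and a column that is
(numerically) in the span of the already-admitted columns is dropped.  Which
column survives an aliasing is therefore decided by term order, which in turn
fixes the degrees of freedom of every sequential ANOVA built on top of it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ModelFit",
    "ols",
    "sequential_anova",
    "one_sample_t",
    "paired_t",
    "binomial_logit",
    "fisher_z",
    "fisher_z_inverse",
    "bonferroni",
]


@dataclass
class ModelFit:
    """Result of a linear or generalized-linear model fit.

    ``params`` etc. are indexed by the *kept* column names; aliased (dropped)
    columns are listed in ``aliased``.
    """

    params: pd.Series
    bse: pd.Series
    tvalues: pd.Series
    pvalues: pd.Series
    df_resid: int
    rss: float
    r2: float
    r2_adj: float
    loglik: float
    conf_int: pd.DataFrame
    aliased: list[str] = field(default_factory=list)
    fitted: np.ndarray | None = None
    resid: np.ndarray | None = None
    nobs: int = 0

    def to_dict(self) -> dict:
        return {
            "params": self.params.to_dict(),
            "bse": self.bse.to_dict(),
            "tvalues": self.tvalues.to_dict(),
            "pvalues": self.pvalues.to_dict(),
            "df_resid": int(self.df_resid),
            "rss": float(self.rss),
            "r2": float(self.r2),
            "r2_adj": float(self.r2_adj),
            "loglik": float(self.loglik),
            "conf_int": {k: list(map(float, v)) for k, v in self.conf_int.iterrows()},
            "aliased": list(self.aliased),
            "nobs": int(self.nobs),
        }


def _independent_columns(X: np.ndarray, tol_scale: float = 1e-9) -> np.ndarray:
    """Indices of a maximal left-to-right independent column subset.

    Modified Gram–Schmidt with a relative tolerance; the first column of any
    aliased group is kept, later copies are dropped (deterministic policy).
    """
    n, p = X.shape
    basis: list[np.ndarray] = []
    kept: list[int] = []
    for j in range(p):
        v = X[:, j].astype(float).copy()
        norm0 = np.linalg.norm(v)
        if norm0 == 0.0:
            continue
        for q in basis:
            v -= (q @ v) * q
        # second pass for numerical robustness
        for q in basis:
            v -= (q @ v) * q
        if np.linalg.norm(v) > tol_scale * max(norm0, 1.0) * np.sqrt(max(n, p)):
            basis.append(v / np.linalg.norm(v))
            kept.append(j)
    return np.asarray(kept, dtype=int)


def ols(X, y, names: list[str] | None = None) -> ModelFit:
    """Ordinary least squares with rank-revealing column selection.

    Parameters
    ----------
    X : (n, p) design matrix (include the intercept column explicitly).
    y : (n,) response.
    names : column names; defaults to ``x0..x{p-1}``.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if names is None:
        names = [f"x{j}" for j in range(p)]
    if len(names) != p:
        raise ValueError("names length does not match column count")

    kept = _independent_columns(X)
    Xk = X[:, kept]
    rank = len(kept)
    beta, *_ = np.linalg.lstsq(Xk, y, rcond=None)
    # snap numerically-exact fits: round-off residuals must not manufacture
    # spurious t statistics for coefficients that are really zero
    if beta.size:
        scale = np.max(np.abs(beta))
        if scale > 0:
            beta[np.abs(beta) < 1e-12 * scale] = 0.0
    fitted = Xk @ beta
    resid = y - fitted
    rss = float(resid @ resid)
    if rss < 1e-20 * max(1.0, float(y @ y)):
        rss = 0.0
        resid = np.zeros_like(resid)
    df_resid = n - rank
    if df_resid > 0:
        sigma2 = rss / df_resid
        XtX_inv = np.linalg.pinv(Xk.T @ Xk)
        bse = np.sqrt(np.maximum(np.diag(XtX_inv) * sigma2, 0.0))
    else:
        bse = np.full(rank, np.nan)
    with np.errstate(divide="ignore", invalid="ignore"):
        tvals = np.where(bse > 0, beta / bse, np.where(beta == 0, 0.0, np.inf * np.sign(beta)))
    if df_resid > 0:
        pvals = 2.0 * stats.t.sf(np.abs(tvals), df_resid)
        tcrit = stats.t.ppf(0.975, df_resid)
    else:
        pvals = np.full(rank, np.nan)
        tcrit = np.nan
    lo = beta - tcrit * bse
    hi = beta + tcrit * bse

    tss = float(np.sum((y - y.mean()) ** 2))
    has_const = any(np.allclose(X[:, j], X[0, j]) and X[0, j] != 0 for j in kept)
    r2 = 1.0 - rss / tss if tss > 0 else np.nan
    if df_resid > 0 and tss > 0 and n - 1 > 0:
        r2_adj = 1.0 - (rss / df_resid) / (tss / (n - 1))
    else:
        r2_adj = np.nan
    # Gaussian log-likelihood at the MLE variance rss/n
    if rss > 0:
        loglik = -0.5 * n * (np.log(2 * np.pi * rss / n) + 1.0)
    else:
        loglik = np.inf

    kept_names = [names[j] for j in kept]
    aliased = [names[j] for j in range(p) if j not in set(kept.tolist())]
    idx = pd.Index(kept_names)
    return ModelFit(
        params=pd.Series(beta, index=idx),
        bse=pd.Series(bse, index=idx),
        tvalues=pd.Series(tvals, index=idx),
        pvalues=pd.Series(pvals, index=idx),
        df_resid=df_resid,
        rss=rss,
        r2=r2 if has_const or tss > 0 else np.nan,
        r2_adj=r2_adj,
        loglik=loglik,
        conf_int=pd.DataFrame({"lower": lo, "upper": hi}, index=idx),
        aliased=aliased,
        fitted=fitted,
        resid=resid,
        nobs=n,
    )


def sequential_anova(
    y,
    terms: list[tuple[str, np.ndarray]],
    include_intercept: bool = True,
) -> pd.DataFrame:
    """Sequential (type-I) ANOVA by incremental nested-model comparison.

    ``terms`` is an ordered list of ``(name, column_block)``; each block is
    added to the design in turn and contributes df equal to the *rank
    increase* it brings (aliased columns within or across blocks absorb no
    df).  F statistics use the residual mean square of the full model.

    Returns a table with one row per term plus a ``Residual`` row, and
    columns ``df, sum_sq, F, p, eta_sq``.
    """
    y = np.asarray(y, dtype=float).ravel()
    n = y.size
    blocks = []
    if include_intercept:
        blocks.append(np.ones((n, 1)))
    sizes = []
    for _, M in terms:
        M = np.asarray(M, dtype=float)
        if M.ndim == 1:
            M = M[:, None]
        blocks.append(M)
        sizes.append(M.shape[1])
    Xfull = np.hstack(blocks)
    kept = _independent_columns(Xfull)

    offset = 1 if include_intercept else 0
    # cumulative column counts marking block boundaries
    bounds = np.cumsum([offset] + sizes)

    rss_prev = None
    rows = []
    tss = float(np.sum((y - y.mean()) ** 2))
    # residuals of successively larger kept designs
    for b_idx, bound in enumerate(bounds):
        cols = kept[kept < bound]
        if cols.size:
            beta, *_ = np.linalg.lstsq(Xfull[:, cols], y, rcond=None)
            resid = y - Xfull[:, cols] @ beta
        else:
            resid = y.copy()
        rss = float(resid @ resid)
        rank = cols.size
        if b_idx == 0:
            rss_prev, rank_prev = rss, rank
            continue
        name = terms[b_idx - 1][0]
        rows.append((name, rank - rank_prev, rss_prev - rss))
        rss_prev, rank_prev = rss, rank

    rss_full = rss_prev
    rank_full = rank_prev
    df_resid = n - rank_full
    ms_resid = rss_full / df_resid if df_resid > 0 else np.nan

    out = []
    for name, df_t, ss in rows:
        if df_t > 0 and ms_resid > 0:
            F = (ss / df_t) / ms_resid
            pval = stats.f.sf(F, df_t, df_resid)
        else:
            F, pval = np.nan, np.nan
        eta = ss / tss if tss > 0 else np.nan
        out.append({"term": name, "df": df_t, "sum_sq": ss, "F": F, "p": pval, "eta_sq": eta})
    out.append(
        {"term": "Residual", "df": df_resid, "sum_sq": rss_full, "F": np.nan, "p": np.nan, "eta_sq": np.nan}
    )
    return pd.DataFrame(out).set_index("term")


@dataclass
class TTestResult:
    t: float
    df: int
    p: float
    cohens_d: float
    mean: float
    ci: tuple[float, float]


def _t_from_values(x: np.ndarray, popmean: float) -> TTestResult:
    x = np.asarray(x, dtype=float).ravel()
    n = x.size
    if n < 2:
        raise ValueError("need at least 2 observations")
    m = float(x.mean())
    sd = float(x.std(ddof=1))
    df = n - 1
    if sd == 0.0:
        if m == popmean:
            return TTestResult(0.0, df, 1.0, 0.0, m, (m, m))
        t = np.inf * np.sign(m - popmean)
        return TTestResult(float(t), df, 0.0, float(t), m, (m, m))
    se = sd / np.sqrt(n)
    t = (m - popmean) / se
    p = 2.0 * stats.t.sf(abs(t), df)
    d = (m - popmean) / sd
    tcrit = stats.t.ppf(0.975, df)
    return TTestResult(float(t), df, float(p), float(d), m, (m - tcrit * se, m + tcrit * se))


def one_sample_t(x, popmean: float = 0.0) -> TTestResult:
    """Two-sided one-sample t-test with Cohen's d = (mean − popmean)/SD."""
    return _t_from_values(np.asarray(x), popmean)


def paired_t(a, b) -> TTestResult:
    """Two-sided paired t-test on matched vectors (a − b)."""
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.shape != b.shape:
        raise ValueError("paired vectors must have equal length")
    return _t_from_values(a - b, 0.0)


@dataclass
class LogitFit:
    params: pd.Series
    bse: pd.Series
    odds_ratios: pd.Series
    or_conf_int: pd.DataFrame
    pvalues: pd.Series
    converged: bool


def binomial_logit(X, y, names: list[str] | None = None, add_const: bool = True) -> LogitFit:
    """Binomial logistic regression (statsmodels behind the surface).

    Returns Wald odds ratios ``exp(beta)`` with 95% CIs on the OR scale.
    """
    import statsmodels.api as sm

    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    y = np.asarray(y, dtype=float).ravel()
    if names is None:
        names = [f"x{j}" for j in range(X.shape[1])]
    cols = list(names)
    if add_const:
        X = np.column_stack([np.ones(len(y)), X])
        cols = ["const"] + cols
    Xdf = pd.DataFrame(X, columns=cols)
    import warnings as _warnings

    with _warnings.catch_warnings(), np.errstate(over="ignore"):
        # perfectly separated tasks (e.g. an error-free classifier) are a
        # legitimate input; the OR is then unbounded and reported as such
        _warnings.simplefilter("ignore")
        res = sm.GLM(y, Xdf, family=sm.families.Binomial()).fit()
        ci = res.conf_int()
    with np.errstate(over="ignore"):
        odds = np.exp(res.params)
        or_ci = np.exp(ci).rename(columns={0: "lower", 1: "upper"})
    return LogitFit(
        params=res.params,
        bse=res.bse,
        odds_ratios=odds,
        or_conf_int=or_ci,
        pvalues=res.pvalues,
        converged=bool(getattr(res, "converged", True)),
    )


def fisher_z(r, clip: float = 1.0 - 1e-12):
    """Fisher z transform atanh(r), clipping |r| at 1 − 1e-12 to stay finite."""
    r = np.clip(np.asarray(r, dtype=float), -clip, clip)
    return np.arctanh(r)


def fisher_z_inverse(z):
    return np.tanh(np.asarray(z, dtype=float))


def bonferroni(p, m: int | None = None):
    """Bonferroni adjustment: p·m capped at 1 (m defaults to len(p))."""
    p = np.asarray(p, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if m is None:
        m = p.size
    if m < 1:
        raise ValueError("m must be >= 1")
    return np.minimum(p * m, 1.0)
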