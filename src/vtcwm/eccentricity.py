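"""Connections to eccentricity bands in early visual cortex (EVC).

Each fROI's streamlines to EVC are counted per eccentricity band (0-5, 5-10,
10-20 degrees): a streamline contributes when one terminal lies within the
radial-search radius of the fROI and the other within the radius of any band
vertex; it is assigned to the band of that endpoint's nearest band vertex
(equidistant bands resolve to the lowest band).  Percentages are per-fROI
shares of the EVC-connected streamlines, so they sum to 100.

The factorial analysis models the central-5-degree percentage by
cytoarchitecture x category x age group with sequential (type-I) sums of
squares; rank-deficient interaction columns (the places<->FG3 confound) are
dropped first-come-kept, which fixes the degrees of freedom.  Longitudinal
post-hoc development is modelled with a subject random intercept fitted by
profiled REML.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.spatial import cKDTree

from . import statcore
from .synthetic import AGE_GROUP_ORDER, CATEGORY_ORDER, CYTO_ORDER
from .tractogeom import LabeledMesh, Tractogram, project_roi

__all__ = [
    "EccentricityProfile",
    "band_profile",
    "band_table",
    "factorial_model",
    "posthoc_paired_t",
    "lmm_random_intercept",
    "LmmFit",
    "reml_criterion",
    "DEFAULT_POSTHOC_PAIRS",
]

BAND_NAMES = ["band_0_5", "band_5_10", "band_10_20"]

DEFAULT_POSTHOC_PAIRS = [
    ("pFus-faces", "pOTS-words"),
    ("mFus-faces", "OTS-bodies"),
    ("mFus-faces", "mOTS-words"),
    ("OTS-bodies", "mOTS-words"),
]


@dataclass
class EccentricityProfile:
    """Streamline counts and percentages over the three EVC bands."""

    froi_id: str
    counts: np.ndarray
    percentages: np.ndarray  # NaN sentinel when no EVC-connected streamlines

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=int)
        self.percentages = np.asarray(self.percentages, dtype=float)
        if np.any(self.counts < 0):
            raise ValueError("band counts must be nonnegative")
        total = self.counts.sum()
        if total > 0 and not np.isclose(self.percentages.sum(), 100.0, atol=1e-9):
            raise ValueError("percentages must sum to 100 when connections exist")

    @property
    def total(self) -> int:
        return int(self.counts.sum())


def band_profile(
    tractogram: Tractogram,
    mesh: LabeledMesh,
    froi_id: str,
    radius_mm: float = 3.0,
    endpoints: np.ndarray | None = None,
) -> EccentricityProfile:
    """Count one fROI's streamline connections per eccentricity band."""
    hemi, name = froi_id.split("_", 1)
    froi_lab = np.asarray(mesh.labels["froi"]).astype(str)
    hemis = np.asarray(mesh.labels["hemisphere"]).astype(str)
    band_lab = np.asarray(mesh.labels["eccentricity_band"], dtype=int)

    roi_vertices = np.flatnonzero((froi_lab == name) & (hemis == hemi))
    if roi_vertices.size == 0:
        raise ValueError(f"fROI {froi_id!r} not present on the mesh")
    band_vertex_sets = [np.flatnonzero(band_lab == b) for b in (1, 2, 3)]
    for b, vs in enumerate(band_vertex_sets, start=1):
        if vs.size == 0:
            raise ValueError(f"eccentricity band {b} has no labeled vertices")
    for i in range(3):
        for j in range(i + 1, 3):
            if np.intersect1d(band_vertex_sets[i], band_vertex_sets[j]).size:
                raise ValueError("eccentricity bands overlap on the mesh")

    if endpoints is None:
        endpoints = tractogram.endpoints()
    ends = np.asarray(endpoints, dtype=float)
    if ends.shape[0] == 0:
        return EccentricityProfile(froi_id, np.zeros(3, int), np.full(3, np.nan))

    roi_points = project_roi(mesh, roi_vertices, 0.0)
    roi_tree = cKDTree(roi_points)
    d0, _ = roi_tree.query(ends[:, 0, :])
    d1, _ = roi_tree.query(ends[:, 1, :])
    selected = (d0 <= radius_mm) | (d1 <= radius_mm)
    # the fROI-side terminal is the nearer one; the other terminal is tested
    # against the bands
    other = np.where((d0 <= d1)[:, None], ends[:, 1, :], ends[:, 0, :])[selected]
    if other.shape[0] == 0:
        return EccentricityProfile(froi_id, np.zeros(3, int), np.full(3, np.nan))

    band_dist = np.column_stack(
        [cKDTree(mesh.vertices[vs]).query(other)[0] for vs in band_vertex_sets]
    )
    nearest_band = np.argmin(band_dist, axis=1)  # ties -> lowest band
    in_evc = band_dist[np.arange(len(other)), nearest_band] <= radius_mm
    counts = np.bincount(nearest_band[in_evc], minlength=3)
    total = counts.sum()
    if total == 0:
        return EccentricityProfile(froi_id, counts, np.full(3, np.nan))
    return EccentricityProfile(froi_id, counts, 100.0 * counts / total)


def band_table(
    sessions: pd.DataFrame,
    mesh: LabeledMesh,
    tractograms,
    radius_mm: float = 3.0,
) -> pd.DataFrame:
    """Per-(fROI, session) band percentages for the whole cohort."""
    from .synthetic import FROI_CATEGORY, FROI_CYTO, froi_ids

    rows = []
    for _, ses in sessions.iterrows():
        tr = tractograms(ses) if callable(tractograms) else tractograms[ses["session_id"]]
        ends = tr.endpoints()
        for froi_id in froi_ids():
            hemi, name = froi_id.split("_", 1)
            prof = band_profile(tr, mesh, froi_id, radius_mm=radius_mm, endpoints=ends)
            rows.append(
                {
                    "froi_id": froi_id,
                    "froi": name,
                    "hemisphere": hemi,
                    "category": FROI_CATEGORY[name],
                    "cytoarchitecture": FROI_CYTO[name],
                    "subject_id": ses["subject_id"],
                    "session_id": ses["session_id"],
                    "age_days": float(ses["age_days"]),
                    "age_group": ses["age_group"],
                    "n_evc_streamlines": prof.total,
                    **{BAND_NAMES[b]: prof.percentages[b] for b in range(3)},
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Factorial model

def _dummies(series: pd.Series, order: list[str]) -> np.ndarray:
    levels = [lv for lv in order if lv in set(series)]
    if len(levels) < 2:
        raise ValueError(f"factor needs >= 2 levels, got {levels}")
    return np.column_stack([(series == lv).to_numpy(float) for lv in levels[1:]])


def _interact(*blocks: np.ndarray) -> np.ndarray:
    out = blocks[0]
    for b in blocks[1:]:
        out = np.einsum("ni,nj->nij", out, b).reshape(len(out), -1)
    return out


def factorial_model(table: pd.DataFrame, response: str = "band_0_5") -> pd.DataFrame:
    """Three-way factorial ANOVA of the central-5-degree percentage.

    Treatment coding with sequential sums of squares in the order
    cytoarchitecture, category, age group, then the interactions; aliased
    columns (e.g. places within FG3) absorb no degrees of freedom.  Restrict
    the input to left-hemisphere fROIs to replicate the standard design
    (6 fROIs x sessions).
    """
    y = table[response].to_numpy(float)
    if np.any(~np.isfinite(y)):
        raise ValueError("response contains undefined percentages")
    cy = _dummies(table["cytoarchitecture"], CYTO_ORDER)
    ca = _dummies(table["category"], CATEGORY_ORDER)
    ag = _dummies(table["age_group"], AGE_GROUP_ORDER)
    terms = [
        ("cytoarchitecture", cy),
        ("category", ca),
        ("age_group", ag),
        ("cytoarchitecture:category", _interact(cy, ca)),
        ("cytoarchitecture:age_group", _interact(cy, ag)),
        ("category:age_group", _interact(ca, ag)),
        ("cytoarchitecture:category:age_group", _interact(cy, ca, ag)),
    ]
    table_out = statcore.sequential_anova(y, terms)
    if table_out.loc["Residual", "df"] <= 0:
        raise ValueError("model leaves no residual degrees of freedom")
    return table_out


def posthoc_paired_t(
    table: pd.DataFrame,
    pairs: list[tuple[str, str]] | None = None,
    response: str = "band_0_5",
    hemisphere: str = "L",
    m: int | None = None,
) -> pd.DataFrame:
    """Session-matched paired t-tests between fROIs of the same area.

    p-values are Bonferroni-multiplied by ``m`` (default: the number of
    pairs) and capped at 1.
    """
    pairs = pairs or DEFAULT_POSTHOC_PAIRS
    m = m if m is not None else len(pairs)
    sub = table[table["hemisphere"] == hemisphere]
    wide = sub.pivot_table(index="session_id", columns="froi", values=response)
    rows = []
    for f1, f2 in pairs:
        paired = wide[[f1, f2]].dropna()
        res = statcore.paired_t(paired[f1], paired[f2])
        rows.append(
            {
                "froi_a": f1,
                "froi_b": f2,
                "n": len(paired),
                "t": res.t,
                "df": res.df,
                "p_adj": float(statcore.bonferroni(np.array([res.p]), m)[0]),
                "cohens_d": res.cohens_d,
                "mean_diff": res.mean,
                "ci_lower": res.ci[0],
                "ci_upper": res.ci[1],
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Random-intercept mixed model (profiled REML)

def reml_criterion(lam: float, y: np.ndarray, X: np.ndarray, group_idx: list[np.ndarray]) -> float:
    """-2 x restricted log-likelihood (up to a constant) at variance ratio lam.

    The residual variance is profiled out; ``lam = sigma_u^2 / sigma_e^2``.
    V is block diagonal with blocks I + lam * J per subject, giving
    closed-form inverses and determinants.
    """
    n, p = X.shape
    A = np.zeros((p, p))
    b = np.zeros(p)
    yVy = 0.0
    logdet = 0.0
    for idx in group_idx:
        Xg, yg = X[idx], y[idx]
        ng = len(idx)
        c = lam / (1.0 + ng * lam)
        sX = Xg.sum(axis=0)
        sy = yg.sum()
        A += Xg.T @ Xg - c * np.outer(sX, sX)
        b += Xg.T @ yg - c * sX * sy
        yVy += yg @ yg - c * sy * sy
        logdet += np.log1p(ng * lam)
    beta = np.linalg.solve(A, b)
    rVr = yVy - b @ beta
    rVr = max(rVr, 1e-300)
    sign, logdetA = np.linalg.slogdet(A)
    return (n - p) * np.log(rVr) + logdet + logdetA


@dataclass
class LmmFit:
    """Fixed-effect summary of y ~ x + (1 | subject), fitted by REML."""

    beta: float          # fixed slope of x
    intercept: float
    se: float
    df: float            # Satterthwaite-style approximate df
    t: float
    p: float
    ci: tuple[float, float]
    sigma_u: float
    sigma_e: float
    lam: float
    boundary: bool       # True when the variance ratio collapsed to 0 (OLS)


def _solve_beta(lam, y, X, group_idx):
    n, p = X.shape
    A = np.zeros((p, p))
    b = np.zeros(p)
    yVy = 0.0
    for idx in group_idx:
        Xg, yg = X[idx], y[idx]
        ng = len(idx)
        c = lam / (1.0 + ng * lam)
        sX = Xg.sum(axis=0)
        sy = yg.sum()
        A += Xg.T @ Xg - c * np.outer(sX, sX)
        b += Xg.T @ yg - c * sX * sy
        yVy += yg @ yg - c * sy * sy
    beta = np.linalg.solve(A, b)
    rVr = yVy - b @ beta
    sigma_e2 = rVr / (n - p)
    return beta, sigma_e2, np.linalg.inv(A)


def _reml_loglik_theta(theta, y, X, group_idx):
    """Restricted log-likelihood as a function of (sigma_e^2, sigma_u^2)."""
    se2, su2 = theta
    if se2 <= 0 or su2 < 0:
        return -np.inf
    lam = su2 / se2
    n, p = X.shape
    A = np.zeros((p, p))
    b = np.zeros(p)
    yVy = 0.0
    logdetV = n * np.log(se2)
    for idx in group_idx:
        Xg, yg = X[idx], y[idx]
        ng = len(idx)
        c = lam / (1.0 + ng * lam)
        sX = Xg.sum(axis=0)
        sy = yg.sum()
        A += Xg.T @ Xg - c * np.outer(sX, sX)
        b += Xg.T @ yg - c * sX * sy
        yVy += yg @ yg - c * sy * sy
        logdetV += np.log1p(ng * lam)
    A /= se2
    b /= se2
    yVy /= se2
    beta = np.linalg.solve(A, b)
    rVr = yVy - b @ beta
    _, logdetA = np.linalg.slogdet(A)
    return -0.5 * (logdetV + logdetA + rVr)


def lmm_random_intercept(values, age_days, subjects) -> LmmFit:
    """Fit value ~ log10(age_days) + (1 | subject) by profiled REML.

    The variance ratio ``lam = sigma_u^2 / sigma_e^2`` is profiled on a 1-D
    criterion; a boundary optimum (lam -> 0) collapses to OLS with a flag.
    The fixed-slope df is a Satterthwaite-style approximation from the
    curvature of the restricted likelihood in the two variance components.
    """
    y = np.asarray(values, dtype=float).ravel()
    age_days = np.asarray(age_days, dtype=float).ravel()
    subjects = np.asarray(subjects)
    if np.any(age_days <= 0):
        raise ValueError("age_days must be positive")
    x = np.log10(age_days)
    X = np.column_stack([np.ones_like(x), x])
    uniq = pd.unique(pd.Series(subjects))
    if len(uniq) < 2:
        raise ValueError("need at least 2 subjects")
    group_idx = [np.flatnonzero(subjects == g) for g in uniq]
    if not any(len(idx) >= 2 for idx in group_idx):
        raise ValueError("need at least one subject with >= 2 sessions")
    n, p = X.shape

    res = optimize.minimize_scalar(
        lambda u: reml_criterion(np.exp(u), y, X, group_idx),
        bounds=(-12.0, 8.0),
        method="bounded",
        options={"xatol": 1e-8},
    )
    lam = float(np.exp(res.x))
    boundary = reml_criterion(0.0, y, X, group_idx) <= res.fun + 1e-10 or lam < 1e-6
    if boundary:
        lam = 0.0
    beta, sigma_e2, Ainv = _solve_beta(lam, y, X, group_idx)
    cov_beta = sigma_e2 * Ainv
    se = float(np.sqrt(cov_beta[1, 1]))
    sigma_u2 = lam * sigma_e2

    if boundary:
        df = float(n - p)
    else:
        theta = np.array([sigma_e2, sigma_u2])

        def var_slope(th):
            lam_t = th[1] / th[0]
            _, _, Ainv_t = _solve_beta(lam_t, y, X, group_idx)
            return th[0] * Ainv_t[1, 1]

        h = 1e-5 * np.maximum(np.abs(theta), 1e-12)
        grad = np.zeros(2)
        for k in range(2):
            tp, tm = theta.copy(), theta.copy()
            tp[k] += h[k]
            tm[k] -= h[k]
            grad[k] = (var_slope(tp) - var_slope(tm)) / (2 * h[k])
        # numeric Hessian of the restricted log-likelihood
        H = np.zeros((2, 2))
        f0 = _reml_loglik_theta(theta, y, X, group_idx)
        for a in range(2):
            for b2 in range(2):
                ta = theta.copy()
                ta[a] += h[a]
                ta[b2] += h[b2]
                tb = theta.copy()
                tb[a] += h[a]
                tb[b2] -= h[b2]
                tc = theta.copy()
                tc[a] -= h[a]
                tc[b2] += h[b2]
                td = theta.copy()
                td[a] -= h[a]
                td[b2] -= h[b2]
                H[a, b2] = (
                    _reml_loglik_theta(ta, y, X, group_idx)
                    - _reml_loglik_theta(tb, y, X, group_idx)
                    - _reml_loglik_theta(tc, y, X, group_idx)
                    + _reml_loglik_theta(td, y, X, group_idx)
                ) / (4 * h[a] * h[b2])
        try:
            cov_theta = np.linalg.inv(-H)
            denom = float(grad @ cov_theta @ grad)
            df = 2.0 * (cov_beta[1, 1] ** 2) / denom if denom > 0 else float(n - p)
        except np.linalg.LinAlgError:
            df = float(n - p)
        df = float(np.clip(df, 1.0, n - p))
        _ = f0

    t = beta[1] / se if se > 0 else np.nan
    pval = 2.0 * stats.t.sf(abs(t), df) if np.isfinite(t) else np.nan
    tcrit = stats.t.ppf(0.975, df)
    return LmmFit(
        beta=float(beta[1]),
        intercept=float(beta[0]),
        se=se,
        df=df,
        t=float(t),
        p=float(pval),
        ci=(float(beta[1] - tcrit * se), float(beta[1] + tcrit * se)),
        sigma_u=float(np.sqrt(sigma_u2)),
        sigma_e=float(np.sqrt(sigma_e2)),
        lam=lam,
        boundary=bool(boundary),
    )
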