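"""Developmental slopes of endpoint density and their similarity structure.

For one fROI, the per-parcel developmental slope is the coefficient of
log10(age in days) in a simple regression of that parcel's endpoint density;
positive slopes mean increasing connectivity with age.  A global age x parcel
interaction test asks whether development differs across the brain.  Slope
similarity between fROI pairs is estimated by refitting all slopes on
bootstrap subsamples (75% of profiles, without replacement) and correlating
the slope vectors per iteration; Fisher-z correlations are modelled on
same-category / same-cytoarchitecture indicators.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from . import statcore
from .profiles import ProfileMatrix
from .synthetic import FROI_CATEGORY, FROI_CYTO

__all__ = [
    "SlopeMap",
    "age_by_parcel_model",
    "slope_map",
    "bootstrap_indices",
    "bootstrap_slopes",
    "slope_similarity",
]


@dataclass
class SlopeMap:
    """Per-parcel developmental regression for one fROI."""

    froi_id: str
    table: pd.DataFrame  # parcel, slope, intercept, se, p

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def _froi_block(matrix: ProfileMatrix, froi_id: str) -> tuple[np.ndarray, np.ndarray]:
    sub = matrix.for_froi(froi_id)
    if sub.n_rows == 0:
        raise ValueError(f"no profiles for fROI {froi_id!r}")
    x = np.log10(sub.meta["age_days"].to_numpy(float))
    return x, sub.values


def _parcel_slopes(x: np.ndarray, Y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Closed-form per-parcel simple-regression slopes and intercepts."""
    xc = x - x.mean()
    sxx = float(xc @ xc)
    if sxx <= 0:
        raise ValueError("need at least two distinct ages")
    slopes = (xc @ Y) / sxx
    intercepts = Y.mean(axis=0) - slopes * x.mean()
    return slopes, intercepts


def age_by_parcel_model(matrix: ProfileMatrix, froi_id: str) -> pd.DataFrame:
    """Global development test: density ~ log10(age) x parcel, long form.

    One row per profile x parcel; sequential ANOVA reports F tests for the
    parcel main effect, the age main effect, and the age x parcel
    interaction.  Densities are normalized fractions, so no subject random
    intercept is included.  All-zero parcels are retained (zeros are data).
    """
    x, Y = _froi_block(matrix, froi_id)
    n, P = Y.shape
    y_long = Y.ravel(order="C")
    parcel_idx = np.tile(np.arange(P), n)
    x_long = np.repeat(x, P)
    parcel_dum = np.zeros((n * P, P - 1))
    rows = np.flatnonzero(parcel_idx > 0)
    parcel_dum[rows, parcel_idx[rows] - 1] = 1.0
    xc = x_long - x_long.mean()
    terms = [
        ("parcel", parcel_dum),
        ("log10_age", xc[:, None]),
        ("log10_age:parcel", parcel_dum * xc[:, None]),
    ]
    return statcore.sequential_anova(y_long, terms)


def slope_map(matrix: ProfileMatrix, froi_id: str) -> SlopeMap:
    """Independent per-parcel regressions of density on log10(age)."""
    x, Y = _froi_block(matrix, froi_id)
    n = len(x)
    slopes, intercepts = _parcel_slopes(x, Y)
    fitted = intercepts[None, :] + np.outer(x, slopes)
    rss = ((Y - fitted) ** 2).sum(axis=0)
    df = n - 2
    xc = x - x.mean()
    sxx = float(xc @ xc)
    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.sqrt(rss / df / sxx)
        t = np.where(se > 0, slopes / se, 0.0)
    p = 2.0 * stats.t.sf(np.abs(t), df)
    table = pd.DataFrame(
        {
            "parcel": matrix.parcel_names,
            "slope": slopes,
            "intercept": intercepts,
            "se": se,
            "p": p,
        }
    )
    return SlopeMap(froi_id=froi_id, table=table)


def bootstrap_indices(
    n: int, n_iter: int = 1000, fraction: float = 0.75, seed: int = 0
) -> np.ndarray:
    """(n_iter, floor(fraction*n)) subsample index matrix, without replacement.

    Generated once and shared across fROIs so that iteration k uses the same
    session subsample for every fROI (paired bootstrap).
    """
    m = int(np.floor(fraction * n))
    if m < 3:
        raise ValueError("subsample size must be >= 3")
    rng = np.random.default_rng(seed)
    return np.stack([rng.choice(n, size=m, replace=False) for _ in range(n_iter)])


def bootstrap_slopes(
    matrix: ProfileMatrix,
    froi_id: str,
    n_iter: int = 1000,
    fraction: float = 0.75,
    seed: int = 0,
    indices: np.ndarray | None = None,
    max_resample: int = 100,
) -> np.ndarray:
    """(n_iter x parcels) per-parcel slopes refit on 75% subsamples.

    Pass a shared ``indices`` matrix (from :func:`bootstrap_indices`) to pair
    iterations across fROIs.  A subsample with a single unique age is
    resampled (counted, capped at ``max_resample``).
    """
    x, Y = _froi_block(matrix, froi_id)
    n = len(x)
    if indices is None:
        indices = bootstrap_indices(n, n_iter=n_iter, fraction=fraction, seed=seed)
    rng = np.random.default_rng(seed + 1)
    out = np.empty((indices.shape[0], Y.shape[1]))
    n_resampled = 0
    for k in range(indices.shape[0]):
        idx = indices[k]
        while np.unique(x[idx]).size < 2:
            n_resampled += 1
            if n_resampled > max_resample:
                raise RuntimeError("too many degenerate bootstrap subsamples")
            idx = rng.choice(n, size=indices.shape[1], replace=False)
        out[k], _ = _parcel_slopes(x[idx], Y[idx])
    return out


def slope_similarity(
    boot_slopes: dict[str, np.ndarray],
    method: str = "pearson",
) -> tuple[pd.DataFrame, statcore.ModelFit]:
    """Pairwise slope-vector correlations and the similarity model.

    For every unordered fROI pair and bootstrap iteration, the correlation
    between the two slope vectors across parcels; Fisher z = atanh(r) (|r|
    clipped below 1).  The similarity model regresses z on same_category and
    same_cytoarchitecture indicators (1 = same, 0 = different).
    Zero-variance slope vectors drop the pair-iteration row (count reported
    in the table attribute ``n_dropped``).
    """
    froi_list = list(boot_slopes)
    n_iter = {f: a.shape[0] for f, a in boot_slopes.items()}
    if len(set(n_iter.values())) != 1:
        raise ValueError("all fROIs must share the iteration count")
    shapes = {a.shape[1] for a in boot_slopes.values()}
    if len(shapes) != 1:
        raise ValueError("all fROIs must share the parcel dimension")

    # standardize rows once per fROI; zero-variance rows flagged as NaN
    zs = {}
    for f, A in boot_slopes.items():
        Ac = A - A.mean(axis=1, keepdims=True)
        sd = np.linalg.norm(Ac, axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            zs[f] = np.where(sd[:, None] > 0, Ac / sd[:, None], np.nan)

    rows = []
    n_dropped = 0
    for i, f1 in enumerate(froi_list):
        for f2 in froi_list[i + 1:]:
            r = np.einsum("ij,ij->i", zs[f1], zs[f2])
            valid = np.isfinite(r)
            n_dropped += int((~valid).sum())
            name1 = f1.split("_", 1)[1] if "_" in f1 else f1
            name2 = f2.split("_", 1)[1] if "_" in f2 else f2
            same_cat = int(FROI_CATEGORY[name1] == FROI_CATEGORY[name2])
            same_cyto = int(FROI_CYTO[name1] == FROI_CYTO[name2])
            for k in np.flatnonzero(valid):
                rows.append((f"{f1}|{f2}", k, r[k], same_cat, same_cyto))
    table = pd.DataFrame(
        rows, columns=["froi_pair", "iteration", "r", "same_category", "same_cytoarchitecture"]
    )
    table["r"] = np.clip(table["r"], -1.0, 1.0)
    table["fisher_z"] = statcore.fisher_z(table["r"].to_numpy())
    table.attrs["n_dropped"] = n_dropped

    X = np.column_stack(
        [
            np.ones(len(table)),
            table["same_category"].to_numpy(float),
            table["same_cytoarchitecture"].to_numpy(float),
        ]
    )
    fit = statcore.ols(
        X, table["fisher_z"].to_numpy(), names=["const", "same_category", "same_cytoarchitecture"]
    )
    return table, fit
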