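"""Parcel-level connectivity profiles and the cohort profile matrix.

A connectivity profile is the parcel-aggregated endpoint-density vector of
one fROI in one session: per retained parcel of the fROI's hemisphere, the
summed per-vertex endpoint density.  Densities are normalized on the whole
surface *before* the seed-region parcels are dropped, so with the default
``renormalize=False`` a profile may sum to less than 1 (the excluded mass is
the looping-fiber share near the seed fROI).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import statcore
from .synthetic import FROI_CATEGORY, FROI_CYTO, FROI_HEMIS, FROIS, froi_ids
from .tractogeom import (
    EndpointDensityMap,
    LabeledMesh,
    Tractogram,
    density_from_points,
    fsub_mask,
    project_roi,
)

__all__ = [
    "ProfileMatrix",
    "retained_parcels",
    "aggregate_to_parcels",
    "session_profiles",
    "build_profile_matrix",
    "relative_area_model",
    "froi_surface_areas",
]

META_COLUMNS = [
    "froi_id",
    "froi",
    "hemisphere",
    "category",
    "cytoarchitecture",
    "subject_id",
    "session_id",
    "age_days",
    "age_group",
]


def retained_parcels(mesh: LabeledMesh) -> np.ndarray:
    """Sorted retained (non-excluded) parcel ordinals; shared across hemispheres."""
    parcels = np.asarray(mesh.labels["parcel"])
    excluded = np.asarray(mesh.labels["excluded"], dtype=bool)
    return np.unique(parcels[~excluded])


def aggregate_to_parcels(
    dmap: EndpointDensityMap,
    mesh: LabeledMesh,
    hemisphere: str,
    renormalize: bool = False,
) -> np.ndarray:
    """Sum vertex densities into retained same-hemisphere parcels.

    Excluded parcels are dropped *after* whole-surface normalization; with
    ``renormalize=False`` (default) the retained vector may sum to < 1.
    """
    if dmap.density.shape[0] != mesh.n_vertices:
        raise ValueError("density map and mesh vertex counts do not match")
    parcels = np.asarray(mesh.labels["parcel"])
    hemis = np.asarray(mesh.labels["hemisphere"]).astype(str)
    excluded = np.asarray(mesh.labels["excluded"], dtype=bool)
    ret = retained_parcels(mesh)
    pos = {p: i for i, p in enumerate(ret)}
    values = np.zeros(len(ret))
    sel = (hemis == hemisphere) & ~excluded
    idx = np.fromiter((pos[p] for p in parcels[sel]), dtype=int, count=int(sel.sum()))
    np.add.at(values, idx, dmap.density[sel])
    if renormalize:
        total = values.sum()
        if total > 0:
            values = values / total
    return values


@dataclass
class ProfileMatrix:
    """Cohort profile matrix: one row per (fROI, session).

    ``meta`` carries the metadata columns, ``values`` the (rows x parcels)
    density fractions; rows are in canonical order (session order of the
    cohort table, then canonical fROI order).
    """

    meta: pd.DataFrame
    values: np.ndarray
    parcel_names: list[str]

    def __post_init__(self):
        if len(self.meta) != self.values.shape[0]:
            raise ValueError("metadata rows and value rows do not match")
        if self.values.shape[1] != len(self.parcel_names):
            raise ValueError("parcel name count does not match value columns")

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    def to_frame(self) -> pd.DataFrame:
        vals = pd.DataFrame(self.values, columns=self.parcel_names, index=self.meta.index)
        return pd.concat([self.meta, vals], axis=1)

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "ProfileMatrix":
        df = pd.read_csv(path, sep="\t")
        parcel_names = [c for c in df.columns if c.startswith("parcel_")]
        meta = df[[c for c in META_COLUMNS if c in df.columns]].copy()
        return cls(meta=meta, values=df[parcel_names].to_numpy(float), parcel_names=parcel_names)

    def subset(self, mask) -> "ProfileMatrix":
        mask = np.asarray(mask)
        return ProfileMatrix(
            meta=self.meta[mask].reset_index(drop=True),
            values=self.values[mask],
            parcel_names=self.parcel_names,
        )

    def for_froi(self, froi_id: str) -> "ProfileMatrix":
        return self.subset((self.meta["froi_id"] == froi_id).to_numpy())


def session_profiles(
    mesh: LabeledMesh,
    tractogram: Tractogram,
    radius_mm: float = 3.0,
    renormalize: bool = False,
) -> dict[str, np.ndarray]:
    """Per-fROI profile vectors for one session's tractogram.

    Runs the radial-search extraction and the endpoint-density map once per
    fROI, reusing the tractogram's terminal points.
    """
    froi_lab = np.asarray(mesh.labels["froi"]).astype(str)
    hemis = np.asarray(mesh.labels["hemisphere"]).astype(str)
    missing = [
        f"{h}_{name}"
        for h in ("L", "R")
        for name, _, _ in FROIS
        if h in FROI_HEMIS[name] and not np.any((froi_lab == name) & (hemis == h))
    ]
    if missing:
        raise ValueError(f"mesh is missing fROI labels: {missing}")
    ends = tractogram.endpoints()
    out: dict[str, np.ndarray] = {}
    for froi_id in froi_ids():
        hemi, name = froi_id.split("_", 1)
        roi_vertices = np.flatnonzero((froi_lab == name) & (hemis == hemi))
        roi_points = project_roi(mesh, roi_vertices, 0.0)
        mask = fsub_mask(ends, roi_points, radius_mm)
        dmap = density_from_points(ends[mask], mesh, radius_mm)
        out[froi_id] = aggregate_to_parcels(dmap, mesh, hemi, renormalize=renormalize)
    return out


def build_profile_matrix(
    sessions: pd.DataFrame,
    mesh: LabeledMesh,
    tractograms,
    radius_mm: float = 3.0,
    renormalize: bool = False,
) -> ProfileMatrix:
    """Assemble the cohort profile matrix.

    ``tractograms`` is either a mapping ``session_id -> Tractogram`` or a
    callable ``session_row -> Tractogram`` (the streaming path used by the
    pipeline, which never holds more than one session's tractogram).
    Row order is deterministic: cohort session order, then canonical fROI
    order within each session.
    """
    ret = retained_parcels(mesh)
    parcel_names = [f"parcel_{p:03d}" for p in ret]
    meta_rows, value_rows = [], []
    for _, ses in sessions.iterrows():
        if callable(tractograms):
            tr = tractograms(ses)
        else:
            tr = tractograms[ses["session_id"]]
        per_froi = session_profiles(mesh, tr, radius_mm=radius_mm, renormalize=renormalize)
        for froi_id, values in per_froi.items():
            hemi, name = froi_id.split("_", 1)
            meta_rows.append(
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
                }
            )
            value_rows.append(values)
    return ProfileMatrix(
        meta=pd.DataFrame(meta_rows, columns=META_COLUMNS),
        values=np.asarray(value_rows),
        parcel_names=parcel_names,
    )


def froi_surface_areas(mesh: LabeledMesh) -> tuple[pd.Series, pd.Series]:
    """(fROI areas by froi_id, hemisphere areas) in mm^2, barycentric vertex areas."""
    areas = mesh.vertex_areas()
    froi_lab = np.asarray(mesh.labels["froi"]).astype(str)
    hemis = np.asarray(mesh.labels["hemisphere"]).astype(str)
    froi_areas = {}
    for froi_id in froi_ids():
        hemi, name = froi_id.split("_", 1)
        froi_areas[froi_id] = float(areas[(froi_lab == name) & (hemis == hemi)].sum())
    hemi_areas = {h: float(areas[hemis == h].sum()) for h in np.unique(hemis)}
    return pd.Series(froi_areas), pd.Series(hemi_areas)


def relative_area_model(froi_area, hemi_area, age_days) -> statcore.ModelFit:
    """OLS of fROI-to-hemisphere surface-area ratio on log10(age in days).

    Observations are pooled over fROIs and sessions; the slope t-statistic
    has residual df = n - 2.
    """
    froi_area = np.asarray(froi_area, dtype=float)
    hemi_area = np.asarray(hemi_area, dtype=float)
    age_days = np.asarray(age_days, dtype=float)
    if froi_area.shape != hemi_area.shape or froi_area.shape != age_days.shape:
        raise ValueError("froi_area, hemi_area and age_days must be aligned")
    if froi_area.size < 3:
        raise ValueError("need at least 3 observations")
    if np.any(hemi_area <= 0):
        raise ValueError("zero or negative hemisphere area")
    ratio = froi_area / hemi_area
    X = np.column_stack([np.ones_like(ratio), np.log10(age_days)])
    return statcore.ols(X, ratio, names=["const", "log10_age"])
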