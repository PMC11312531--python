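"""Synthetic cohort generator: sessions, labeled meshes, and tractograms.

The generator emulates the study conditions every downstream stage expects:
a cohort of 88 sessions (23 newborn, 23 three-month, 21 six-month, 21 adult;
21 longitudinal infant subjects), a two-hemisphere parcellated surface with
180 parcels per hemisphere of which 11 are flagged as seed-region exclusions
(169 usable), ten functional regions (fROIs) with the standard
category/cytoarchitecture assignment, and tractograms whose endpoint
distributions are planted to cluster strongly by cytoarchitectonic area,
weakly by category, and to drift linearly with log10(age in days).

Planted structure is exact by construction: one terminal of every streamline
sits in the (excluded) seed parcel of its fROI and the other is drawn from a
multinomial over the retained parcels, so the retained endpoint-density
profile equals exactly one half of the planted target distribution.
Age slopes are built to keep every adjusted probability vector on the simplex
over the whole cohort age range without clipping, so per-parcel densities are
exactly linear in log10(age).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .tractogeom import LabeledMesh, Tractogram

__all__ = [
    "FROIS",
    "FROI_HEMIS",
    "CATEGORY_ORDER",
    "CYTO_ORDER",
    "AGE_GROUP_ORDER",
    "CohortConfig",
    "MeshConfig",
    "GroundTruth",
    "make_cohort",
    "filter_sessions",
    "make_labeled_mesh",
    "sample_tractogram",
    "adjusted_profile",
    "sample_parcel_counts",
    "planted_separation",
    "froi_ids",
]

# fROI name -> (category, cytoarchitectonic area); word-selective regions are
# left-hemisphere only.
FROIS: list[tuple[str, str, str]] = [
    ("pFus-faces", "faces", "FG2"),
    ("pOTS-words", "words", "FG2"),
    ("CoS-places", "places", "FG3"),
    ("mFus-faces", "faces", "FG4"),
    ("OTS-bodies", "bodies", "FG4"),
    ("mOTS-words", "words", "FG4"),
]
FROI_HEMIS: dict[str, tuple[str, ...]] = {
    name: (("L",) if cat == "words" else ("L", "R")) for name, cat, _ in FROIS
}
FROI_CATEGORY = {name: cat for name, cat, _ in FROIS}
FROI_CYTO = {name: cyto for name, _, cyto in FROIS}

CATEGORY_ORDER = ["faces", "words", "bodies", "places"]
CYTO_ORDER = ["FG2", "FG3", "FG4"]
AGE_GROUP_ORDER = ["newborn", "3mo", "6mo", "adult"]

DAYS_PER_YEAR = 365.25


def froi_ids(hemispheres: tuple[str, ...] = ("L", "R")) -> list[str]:
    """Canonical '<hemi>_<froi>' identifiers (6 left + 4 right by default)."""
    out = []
    for hemi in hemispheres:
        for name, _, _ in FROIS:
            if hemi in FROI_HEMIS[name]:
                out.append(f"{hemi}_{name}")
    return out


# ---------------------------------------------------------------------------
# Session table

@dataclass
class CohortConfig:
    """Cohort layout and age/QC sampling settings.

    Age means/SDs are in days for infant groups and years for adults (adult
    ages are drawn in years and converted to days, years x 365.25).  Group
    bins in days: newborn < 60, 3mo 60-150, 6mo 150-250, adult > 6000.
    """

    n_newborn: int = 23
    n_3mo: int = 23
    n_6mo: int = 21
    n_adult: int = 21
    longitudinal_triples: int = 4   # infants with newborn+3mo+6mo sessions
    longitudinal_doubles: int = 17  # infants with sessions in two groups
    age_mean_sd: dict = field(
        default_factory=lambda: {
            "newborn": [28.6, 10.2],
            "3mo": [106.9, 19.3],
            "6mo": [189.0, 15.8],
            "adult": [28.21, 5.51],  # years
        }
    )
    age_bins: dict = field(
        default_factory=lambda: {
            "newborn": [7.0, 59.0],
            "3mo": [61.0, 149.0],
            "6mo": [151.0, 249.0],
            "adult": [18.0 * DAYS_PER_YEAR, 45.0 * DAYS_PER_YEAR],
        }
    )
    outlier_mean_sd: dict = field(
        default_factory=lambda: {"infant": [0.0045, 0.0043], "adult": [0.0029, 0.0010]}
    )

    def group_counts(self) -> dict[str, int]:
        return {
            "newborn": self.n_newborn,
            "3mo": self.n_3mo,
            "6mo": self.n_6mo,
            "adult": self.n_adult,
        }


def _longitudinal_layout(config: CohortConfig) -> list[tuple[str, ...]]:
    """Deterministic subject layout: list of per-subject age-group tuples.

    Longitudinal subjects (3-session, then 2-session) are placed greedily
    under the constraint that every infant group retains at least one
    cross-sectional subject; remaining slots become single-session subjects.
    """
    infant_groups = ["newborn", "3mo", "6mo"]
    slots = {g: config.group_counts()[g] for g in infant_groups}
    layout: list[tuple[str, ...]] = []
    for _ in range(config.longitudinal_triples):
        if all(slots[g] > 1 for g in infant_groups):
            for g in infant_groups:
                slots[g] -= 1
            layout.append(tuple(infant_groups))
    for _ in range(config.longitudinal_doubles):
        # two groups with most remaining slots (ties -> group order)
        ranked = sorted(infant_groups, key=lambda g: (-slots[g], infant_groups.index(g)))
        g1, g2 = ranked[0], ranked[1]
        if slots[g1] > 1 and slots[g2] > 1:
            slots[g1] -= 1
            slots[g2] -= 1
            pair = tuple(sorted((g1, g2), key=infant_groups.index))
            layout.append(pair)
    for g in infant_groups:
        layout.extend([(g,)] * slots[g])
    layout.extend([("adult",)] * config.group_counts()["adult"])
    return layout


def make_cohort(config: CohortConfig | None = None, seed: int = 0) -> pd.DataFrame:
    """Generate the session table.

    Returns a DataFrame with columns ``subject_id, session_id, age_days,
    age_group, outlier_fraction``; deterministic given (config, seed).
    """
    config = config or CohortConfig()
    for g, n in config.group_counts().items():
        if n <= 0:
            raise ValueError(f"non-positive session count for group {g!r}")
    rng = np.random.default_rng(seed)
    layout = _longitudinal_layout(config)

    rows = []
    for si, groups in enumerate(layout):
        subject = f"sub-{si + 1:03d}"
        for ti, group in enumerate(groups):
            mean, sd = config.age_mean_sd[group]
            lo, hi = config.age_bins[group]
            if group == "adult":
                age = float(np.clip(rng.normal(mean, sd) * DAYS_PER_YEAR, lo, hi))
            else:
                age = float(np.clip(rng.normal(mean, sd), lo, hi))
            kind = "adult" if group == "adult" else "infant"
            om, osd = config.outlier_mean_sd[kind]
            outlier = float(np.clip(abs(rng.normal(om, osd)), 0.0, 0.05))
            rows.append(
                {
                    "subject_id": subject,
                    "session_id": f"{subject}_ses-{ti + 1}",
                    "age_days": age,
                    "age_group": group,
                    "outlier_fraction": outlier,
                }
            )
    df = pd.DataFrame(rows)
    order = {g: i for i, g in enumerate(AGE_GROUP_ORDER)}
    df = df.sort_values(
        by=["age_group", "subject_id", "age_days"],
        key=lambda c: c.map(order) if c.name == "age_group" else c,
        kind="stable",
    ).reset_index(drop=True)
    return df


def filter_sessions(records: pd.DataFrame, threshold: float = 0.05) -> pd.DataFrame:
    """Session QC filter: retain sessions with outlier_fraction <= threshold.

    Strictly-greater fractions are excluded (>5% excluded, =5% retained at
    the default threshold).
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must lie in [0, 1]")
    if "outlier_fraction" not in records.columns:
        raise ValueError("records lack an outlier_fraction column")
    return records[records["outlier_fraction"] <= threshold].reset_index(drop=True)


# ---------------------------------------------------------------------------
# Mesh + ground truth

@dataclass
class MeshConfig:
    """Parcellated-surface layout.

    Each parcel is a small square grid of vertices; parcels are tiled with a
    pitch that keeps neighbouring parcels farther apart than the radial
    search radius plus the endpoint jitter, so parcel assignment of sampled
    endpoints is exact.
    """

    n_parcels: int = 180
    n_excluded: int = 11
    hemispheres: tuple[str, ...] = ("L", "R")
    parcel_side: int = 3      # vertices per parcel edge
    spacing_mm: float = 2.0   # vertex spacing inside a parcel
    pitch_mm: float = 10.0    # parcel-to-parcel pitch
    n_bands: int = 3          # eccentricity bands, on the first retained parcels
    evc_mass: float = 0.2     # planted endpoint mass on the band parcels
    category_scale: float = 0.10
    age_scale: float = 0.06
    cyto_base_weight: float = 0.75
    dev_shared_weight: float = 0.85  # within-cytoarchitecture shared slope share
    log_age_center: float = 2.8
    log_age_halfrange: float = 1.45


@dataclass
class GroundTruth:
    """Planted statistical structure behind the sampled tractograms.

    ``mean_profile[(cyto, category)]`` is a probability vector over the
    retained parcels (sums to 1); ``age_slope[froi]`` is a signed density
    change per log10(day) per retained parcel (sums to 0);
    ``band_props[cyto]`` is a probability triple over eccentricity bands.
    """

    mean_profile: dict[tuple[str, str], np.ndarray]
    age_slope: dict[str, np.ndarray]
    band_props: dict[str, np.ndarray]
    effect_scales: dict[str, float]
    log_age_center: float
    log_age_halfrange: float
    n_retained: int

    def __post_init__(self):
        for key, p in self.mean_profile.items():
            s = float(np.sum(p))
            if abs(s - 1.0) > 1e-12:
                raise ValueError(f"mean_profile[{key}] sums to {s}, not 1")
            if np.any(p < 0):
                raise ValueError(f"mean_profile[{key}] has negative mass")
        for cyto, b in self.band_props.items():
            if abs(float(np.sum(b)) - 1.0) > 1e-12:
                raise ValueError(f"band_props[{cyto}] does not sum to 1")

    def to_json(self, path) -> None:
        obj = {
            "mean_profile": {f"{c}|{k}": v.tolist() for (c, k), v in self.mean_profile.items()},
            "age_slope": {f: v.tolist() for f, v in self.age_slope.items()},
            "band_props": {c: v.tolist() for c, v in self.band_props.items()},
            "effect_scales": self.effect_scales,
            "log_age_center": self.log_age_center,
            "log_age_halfrange": self.log_age_halfrange,
            "n_retained": self.n_retained,
        }
        with open(path, "w") as fh:
            json.dump(obj, fh)

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        with open(path) as fh:
            obj = json.load(fh)
        return cls(
            mean_profile={
                tuple(k.split("|")): np.asarray(v) for k, v in obj["mean_profile"].items()
            },
            age_slope={f: np.asarray(v) for f, v in obj["age_slope"].items()},
            band_props={c: np.asarray(v) for c, v in obj["band_props"].items()},
            effect_scales=obj["effect_scales"],
            log_age_center=obj["log_age_center"],
            log_age_halfrange=obj["log_age_halfrange"],
            n_retained=obj["n_retained"],
        )


# Eccentricity-band proportions (central 0-5, mid 5-10, peripheral 10-20 deg)
# per cytoarchitectonic area.  FG2 is strongly central-biased, FG3 (places)
# peripherally biased, FG4 intermediate.
DEFAULT_BAND_PROPS = {
    "FG2": np.array([0.6357, 0.0985, 0.2658]),
    "FG3": np.array([0.2658, 0.2942, 0.4400]),
    "FG4": np.array([0.4397, 0.2803, 0.2800]),
}


def _build_ground_truth(config: MeshConfig, rng: np.random.Generator) -> GroundTruth:
    n_ret = config.n_parcels - config.n_excluded
    n_bands = min(config.n_bands, n_ret)
    n_rest = n_ret - n_bands
    evc_mass = config.evc_mass if n_bands == 3 else 0.0

    base = {c: rng.dirichlet(np.full(n_rest, 0.5)) for c in CYTO_ORDER}
    cat_vec = {k: rng.dirichlet(np.full(n_rest, 0.5)) for k in CATEGORY_ORDER}

    mean_profile: dict[tuple[str, str], np.ndarray] = {}
    for name, cat, cyto in FROIS:
        rest = config.cyto_base_weight * base[cyto] + config.category_scale * cat_vec[cat]
        rest = rest / rest.sum()
        if n_bands == 3:
            head = evc_mass * DEFAULT_BAND_PROPS[cyto]
        else:
            head = np.zeros(n_bands)
        p = np.concatenate([head, (1.0 - evc_mass) * rest])
        p = p / p.sum()
        mean_profile[(cyto, cat)] = p

    # Developmental slopes: shared within-cytoarchitecture direction plus a
    # small fROI-specific component, scaled per parcel by the parcel's own
    # mass so the adjusted vector stays positive across the age range.
    w = config.dev_shared_weight
    u = {c: rng.standard_normal(n_ret) for c in CYTO_ORDER}
    h = config.log_age_halfrange
    age_slope: dict[str, np.ndarray] = {}
    for name, cat, cyto in FROIS:
        v = rng.standard_normal(n_ret)
        d = w * u[cyto] + (1.0 - w) * v
        d = d / np.max(np.abs(d))
        p = mean_profile[(cyto, cat)]
        slope = config.age_scale * d * p
        bound = 0.9 * p / h
        for _ in range(200):
            slope = slope - p * slope.sum()  # conserve total mass
            slope = np.clip(slope, -bound, bound)
            if abs(slope.sum()) < 1e-15:
                break
        slope = slope - p * slope.sum()
        age_slope[name] = slope

    return GroundTruth(
        mean_profile=mean_profile,
        age_slope=age_slope,
        band_props={c: b.copy() for c, b in DEFAULT_BAND_PROPS.items()},
        effect_scales={
            "cytoarchitecture": 1.0 - config.category_scale,
            "category": config.category_scale,
            "age": config.age_scale,
        },
        log_age_center=config.log_age_center,
        log_age_halfrange=config.log_age_halfrange,
        n_retained=n_ret,
    )


def make_labeled_mesh(
    config: MeshConfig | None = None, seed: int = 0
) -> tuple[LabeledMesh, GroundTruth]:
    """Build the two-hemisphere parcellated surface and its planted truth.

    Default layout: 180 parcels per hemisphere, ordinals 0..10 flagged as
    seed-region exclusions (169 usable), eccentricity bands 1..3 on retained
    ordinals 11..13, and the ten fROIs placed on distinct excluded parcels
    (word fROIs left hemisphere only).  fROI vertex sets are pairwise
    disjoint by construction.
    """
    config = config or MeshConfig()
    if config.n_excluded < 0 or config.n_excluded >= config.n_parcels:
        raise ValueError("n_excluded must lie in [0, n_parcels)")
    rng = np.random.default_rng(seed)

    side = config.parcel_side
    n_cols = int(np.ceil(np.sqrt(config.n_parcels)))
    verts, faces = [], []
    labels: dict[str, list] = {
        "parcel": [],
        "hemisphere": [],
        "excluded": [],
        "froi": [],
        "cytoarchitecture": [],
        "eccentricity_band": [],
    }

    hemi_offset = {"L": -300.0, "R": 300.0}
    for hemi in config.hemispheres:
        froi_names = [n for n, _, _ in FROIS if hemi in FROI_HEMIS[n]]
        for parcel in range(config.n_parcels):
            gi, gj = divmod(parcel, n_cols)
            ox = hemi_offset[hemi] + gj * config.pitch_mm
            oy = gi * config.pitch_mm
            v0 = len(verts)
            for i in range(side):
                for j in range(side):
                    verts.append((ox + j * config.spacing_mm, oy + i * config.spacing_mm, 0.0))
            for i in range(side - 1):
                for j in range(side - 1):
                    a = v0 + i * side + j
                    b, c, d = a + 1, a + side, a + side + 1
                    faces.append((a, b, d))
                    faces.append((a, d, c))
            excluded = parcel < config.n_excluded
            band = 0
            retained_ordinal = parcel - config.n_excluded
            if not excluded and 0 <= retained_ordinal < config.n_bands:
                band = retained_ordinal + 1
            froi = ""
            cyto = ""
            if excluded and parcel < len(froi_names):
                froi = froi_names[parcel]
                cyto = FROI_CYTO[froi]
            npatch = side * side
            labels["parcel"].extend([parcel] * npatch)
            labels["hemisphere"].extend([hemi] * npatch)
            labels["excluded"].extend([excluded] * npatch)
            labels["froi"].extend([froi] * npatch)
            labels["cytoarchitecture"].extend([cyto] * npatch)
            labels["eccentricity_band"].extend([band] * npatch)

    vertices = np.asarray(verts, dtype=float)
    normals = np.zeros_like(vertices)
    normals[:, 2] = 1.0
    label_arrays = {
        "parcel": np.asarray(labels["parcel"], dtype=int),
        "hemisphere": np.asarray(labels["hemisphere"], dtype=object),
        "excluded": np.asarray(labels["excluded"], dtype=bool),
        "froi": np.asarray(labels["froi"], dtype=object),
        "cytoarchitecture": np.asarray(labels["cytoarchitecture"], dtype=object),
        "eccentricity_band": np.asarray(labels["eccentricity_band"], dtype=int),
    }
    mesh = LabeledMesh(
        vertices=vertices, faces=np.asarray(faces, dtype=int), normals=normals, labels=label_arrays
    )

    # fROI vertex sets must be pairwise disjoint (each owns one parcel patch)
    froi_key = np.char.add(
        np.char.add(label_arrays["hemisphere"].astype(str), "_"),
        label_arrays["froi"].astype(str),
    )
    seen: set[str] = set()
    for key in froi_key[label_arrays["froi"] != ""]:
        seen.add(key)
    counts = pd.Series(froi_key[label_arrays["froi"] != ""]).value_counts()
    if (counts != side * side).any():
        raise ValueError("overlapping or malformed fROI vertex sets")

    truth = _build_ground_truth(config, rng)
    return mesh, truth


# ---------------------------------------------------------------------------
# Sampling

def adjusted_profile(truth: GroundTruth, froi: str, age_days: float) -> np.ndarray:
    """Session-adjusted target-parcel distribution for one fROI.

    mean_profile + age_slope x (log10(age) - center), clipped to the simplex
    and renormalized.  By construction of the default truth no clipping is
    active inside the cohort age range, so densities are exactly linear in
    log10(age).
    """
    if age_days <= 0:
        raise ValueError("age_days must be positive")
    cyto, cat = FROI_CYTO[froi], FROI_CATEGORY[froi]
    x = np.log10(age_days) - truth.log_age_center
    p = truth.mean_profile[(cyto, cat)] + truth.age_slope[froi] * x
    p = np.clip(p, 0.0, None)
    total = p.sum()
    if total <= 0:
        raise ValueError("adjusted probability vector has no mass")
    return p / total


def sample_parcel_counts(
    truth: GroundTruth, froi: str, age_days: float, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Multinomial target-parcel endpoint counts for one (fROI, session)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    return rng.multinomial(n, adjusted_profile(truth, froi, age_days))


def sample_tractogram(
    mesh: LabeledMesh,
    truth: GroundTruth,
    session: pd.Series | dict,
    n_streamlines_per_froi: int = 2000,
    seed: int = 0,
    jitter_mm: float = 0.9,
    midpoint_sd_mm: float = 5.0,
) -> Tractogram:
    """Sample one session's tractogram (all fROIs, both hemispheres).

    Each streamline is a jittered 3-point polyline from a uniformly chosen
    vertex of the seed fROI patch to a vertex of a retained parcel drawn from
    the session-adjusted multinomial.  Streamlines are concatenated in
    canonical fROI order.
    """
    if n_streamlines_per_froi < 1:
        raise ValueError("n_streamlines_per_froi must be >= 1")
    age_days = float(session["age_days"])
    rng = np.random.default_rng(seed)

    parcels = np.asarray(mesh.labels["parcel"])
    hemis = np.asarray(mesh.labels["hemisphere"]).astype(str)
    excluded = np.asarray(mesh.labels["excluded"], dtype=bool)
    froi_lab = np.asarray(mesh.labels["froi"]).astype(str)
    n_excluded = int(parcels[excluded].max()) + 1 if excluded.any() else 0

    streamlines: list[np.ndarray] = []
    hemi_list = sorted(set(hemis), key=lambda h: ("L", "R").index(h) if h in ("L", "R") else 2)
    for hemi in hemi_list:
        # retained-parcel vertex lookup for this hemisphere
        vertex_by_parcel: dict[int, np.ndarray] = {}
        in_hemi = hemis == hemi
        for parcel in np.unique(parcels[in_hemi & ~excluded]):
            vertex_by_parcel[int(parcel)] = np.flatnonzero(in_hemi & (parcels == parcel))
        for name, _, _ in FROIS:
            if hemi not in FROI_HEMIS[name]:
                continue
            seed_vertices = np.flatnonzero(in_hemi & (froi_lab == name))
            if seed_vertices.size == 0:
                continue
            n = n_streamlines_per_froi
            probs = adjusted_profile(truth, name, age_days)
            target_parcels = rng.choice(truth.n_retained, size=n, p=probs) + n_excluded
            sv = rng.choice(seed_vertices, size=n)
            a = mesh.vertices[sv].copy()
            a[:, :2] += rng.uniform(-jitter_mm, jitter_mm, size=(n, 2))
            tv = np.array(
                [rng.choice(vertex_by_parcel[int(tp)]) for tp in target_parcels], dtype=int
            )
            b = mesh.vertices[tv].copy()
            b[:, :2] += rng.uniform(-jitter_mm, jitter_mm, size=(n, 2))
            mid = 0.5 * (a + b)
            mid[:, 2] += np.abs(rng.normal(20.0, midpoint_sd_mm, size=n))  # dive into white matter
            for i in range(n):
                streamlines.append(np.vstack([a[i], mid[i], b[i]]).astype(np.float32))
    return Tractogram(streamlines)


# ---------------------------------------------------------------------------
# Planted-structure diagnostics

def planted_separation(truth: GroundTruth, log_age_span: float = 2.6) -> dict[str, float]:
    """Mean between-group L2 distances of the *generated* mean profiles.

    cytoarchitecture: same category, different area; category: same area,
    different category; age: mean profile displacement over the cohort
    log10-age span.  Defaults are chosen so cytoarchitecture > category > age.
    """
    cyto_pairs, cat_pairs = [], []
    keys = list(truth.mean_profile)
    for i, (c1, k1) in enumerate(keys):
        for c2, k2 in keys[i + 1:]:
            d = float(np.linalg.norm(truth.mean_profile[(c1, k1)] - truth.mean_profile[(c2, k2)]))
            if c1 != c2 and k1 == k2:
                cyto_pairs.append(d)
            elif c1 == c2 and k1 != k2:
                cat_pairs.append(d)
    age = [float(np.linalg.norm(s)) * log_age_span for s in truth.age_slope.values()]
    return {
        "cytoarchitecture": float(np.mean(cyto_pairs)),
        "category": float(np.mean(cat_pairs)),
        "age": float(np.mean(age)),
    }
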