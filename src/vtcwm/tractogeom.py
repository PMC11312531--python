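"""Tractogram I/O, labeled surface meshes, and sub-bundle geometry.

Streamlines are ordered polylines in real-world millimetres.  Track files
follow the MRtrix layout: a text header (``mrtrix tracks`` magic, ``key:
value`` lines, terminated by ``END``) followed by little/big-endian float32
triplets, with a NaN triplet separating streamlines and an Inf triplet
terminating the stream.

Sub-bundle ("fsub") extraction selects streamlines whose *terminal* points
fall within a radius of a set of ROI points (radial search); interior points
never count.  Endpoint-density maps assign each terminal point to its nearest
mesh vertex (ties broken toward the lowest vertex index) and normalize by the
number of retained endpoints, so a non-empty map sums to one.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.spatial import cKDTree

__all__ = [
    "Tractogram",
    "LabeledMesh",
    "EndpointDensityMap",
    "TrackFormatError",
    "read_track_file",
    "write_track_file",
    "project_roi",
    "extract_fsub",
    "endpoint_density",
]


class TrackFormatError(ValueError):
    """Raised for malformed track files; the message names the offending field."""


@dataclass
class Tractogram:
    """A sequence of streamlines; each an (k>=2, 3) float array in mm."""

    streamlines: list[np.ndarray] = field(default_factory=list)

    def __post_init__(self):
        cleaned = []
        for i, s in enumerate(self.streamlines):
            s = np.asarray(s, dtype=np.float32)
            if s.ndim != 2 or s.shape[1] != 3:
                raise ValueError(f"streamline {i} is not an (k, 3) array")
            if s.shape[0] < 2:
                raise ValueError(f"streamline {i} has fewer than 2 points")
            if not np.all(np.isfinite(s)):
                raise ValueError(f"streamline {i} contains non-finite coordinates")
            cleaned.append(s)
        self.streamlines = cleaned

    @property
    def count(self) -> int:
        return len(self.streamlines)

    def endpoints(self) -> np.ndarray:
        """(count, 2, 3) array of the two terminal points per streamline."""
        if not self.streamlines:
            return np.empty((0, 2, 3), dtype=np.float32)
        return np.stack([[s[0], s[-1]] for s in self.streamlines]).astype(np.float32)

    def subset(self, mask) -> "Tractogram":
        mask = np.asarray(mask, dtype=bool)
        if mask.size != self.count:
            raise ValueError("mask length does not match streamline count")
        return Tractogram([self.streamlines[i] for i in np.flatnonzero(mask)])


@dataclass
class LabeledMesh:
    """Triangle mesh with named per-vertex categorical label maps.

    Required labels for the pipeline: ``parcel`` (int parcel ordinal),
    ``hemisphere`` ('L'/'R'), ``excluded`` (bool seed-region flag), ``froi``
    ('' where absent), ``cytoarchitecture`` ('' where absent),
    ``eccentricity_band`` (0 = none, 1..3 = band).
    """

    vertices: np.ndarray
    faces: np.ndarray
    normals: np.ndarray
    labels: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self):
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.faces = np.asarray(self.faces, dtype=int)
        self.normals = np.asarray(self.normals, dtype=float)
        V = self.vertices.shape[0]
        if self.faces.size and (self.faces.min() < 0 or self.faces.max() >= V):
            raise ValueError("face indices out of range")
        if self.normals.shape != self.vertices.shape:
            raise ValueError("normals shape must match vertices")
        nrm = np.linalg.norm(self.normals, axis=1)
        if self.normals.size and not np.allclose(nrm, 1.0, atol=1e-6):
            raise ValueError("normals must be unit length")
        for name, lab in self.labels.items():
            lab = np.asarray(lab)
            if lab.shape[0] != V:
                raise ValueError(f"label map '{name}' length does not match vertex count")
            self.labels[name] = lab

    @property
    def n_vertices(self) -> int:
        return self.vertices.shape[0]

    def vertex_areas(self) -> np.ndarray:
        """Barycentric vertex areas: one third of each adjacent triangle area."""
        v = self.vertices
        f = self.faces
        tri_area = 0.5 * np.linalg.norm(
            np.cross(v[f[:, 1]] - v[f[:, 0]], v[f[:, 2]] - v[f[:, 0]]), axis=1
        )
        areas = np.zeros(self.n_vertices)
        for c in range(3):
            np.add.at(areas, f[:, c], tri_area / 3.0)
        return areas

    def roi_vertices(self, label_name: str, value) -> np.ndarray:
        return np.flatnonzero(np.asarray(self.labels[label_name]) == value)


@dataclass
class EndpointDensityMap:
    """Per-vertex endpoint-density fractions; sums to 1 when non-empty."""

    density: np.ndarray
    total_endpoints: int

    def __post_init__(self):
        self.density = np.asarray(self.density, dtype=float)
        if self.total_endpoints > 0:
            s = self.density.sum()
            if not np.isclose(s, 1.0, atol=1e-9):
                raise ValueError(f"density must sum to 1, got {s!r}")


# ---------------------------------------------------------------------------
# Track-file I/O (MRtrix layout)

_MAGIC = "mrtrix tracks"
_DTYPES = {"Float32LE": "<f4", "Float32BE": ">f4"}


def write_track_file(tractogram: Tractogram, path) -> None:
    """Write a tractogram in the MRtrix track-file layout (Float32LE)."""
    path = Path(path)
    count = tractogram.count
    # assemble the triplet stream: points, NaN separator after each
    # streamline, Inf terminator
    chunks = []
    for s in tractogram.streamlines:
        chunks.append(np.asarray(s, dtype="<f4"))
        chunks.append(np.full((1, 3), np.nan, dtype="<f4"))
    chunks.append(np.full((1, 3), np.inf, dtype="<f4"))
    blob = np.vstack(chunks).tobytes()

    header_lines = [
        _MAGIC,
        "datatype: Float32LE",
        f"count: {count}",
    ]
    # the offset depends on its own textual length; iterate to a fixed point
    offset = 0
    for _ in range(5):
        header = "\n".join(header_lines + [f"file: . {offset}", "END"]) + "\n"
        if len(header.encode()) == offset:
            break
        offset = len(header.encode())
    with open(path, "wb") as fh:
        fh.write(header.encode())
        fh.write(blob)


def read_track_file(path) -> Tractogram:
    """Read an MRtrix-layout track file; raises TrackFormatError on damage."""
    path = Path(path)
    raw = path.read_bytes()
    # header is text up to and including the END line
    end_marker = b"\nEND\n"
    pos = raw.find(end_marker)
    if not raw.startswith(_MAGIC.encode()) or pos < 0:
        raise TrackFormatError("missing 'mrtrix tracks' magic or END terminator in header")
    header_text = raw[: pos + len(end_marker)].decode("utf-8", errors="replace")
    fields: dict[str, str] = {}
    for line in io.StringIO(header_text):
        line = line.strip()
        if not line or line == _MAGIC or line == "END":
            continue
        if ":" not in line:
            raise TrackFormatError(f"malformed header line (no key-value separator): {line!r}")
        key, val = line.split(":", 1)
        fields[key.strip()] = val.strip()

    datatype = fields.get("datatype")
    if datatype not in _DTYPES:
        raise TrackFormatError(f"unsupported or missing datatype field: {datatype!r}")
    if "file" not in fields:
        raise TrackFormatError("missing file field (data offset)")
    try:
        offset = int(fields["file"].split()[-1])
    except (ValueError, IndexError) as exc:
        raise TrackFormatError(f"malformed file field: {fields['file']!r}") from exc
    if "count" in fields:
        try:
            declared = int(fields["count"])
        except ValueError as exc:
            raise TrackFormatError(f"malformed count field: {fields['count']!r}") from exc
    else:
        declared = None

    blob = raw[offset:]
    if len(blob) % 12 != 0:
        raise TrackFormatError("truncated triplet stream: byte count not a multiple of 12")
    pts = np.frombuffer(blob, dtype=_DTYPES[datatype]).reshape(-1, 3)
    if pts.shape[0] == 0 or not np.all(np.isinf(pts[-1])):
        raise TrackFormatError("triplet stream missing Inf terminator")
    pts = pts[:-1]

    streamlines: list[np.ndarray] = []
    cur: list[np.ndarray] = []
    for row in pts:
        if np.all(np.isnan(row)):
            if cur:
                streamlines.append(np.vstack(cur))
                cur = []
        elif np.any(np.isnan(row)) or np.any(np.isinf(row)):
            raise TrackFormatError("triplet stream contains a partial NaN/Inf triplet")
        else:
            cur.append(row.astype(np.float32))
    if cur:
        # data ended inside a streamline without a NaN separator
        raise TrackFormatError("truncated triplet stream: streamline missing NaN separator")
    if declared is not None and declared != len(streamlines):
        raise TrackFormatError(
            f"count field ({declared}) disagrees with parsed streamlines ({len(streamlines)})"
        )
    return Tractogram(streamlines)


# ---------------------------------------------------------------------------
# Geometry

def project_roi(mesh: LabeledMesh, roi_vertices, offset_mm: float = 0.0) -> np.ndarray:
    """Displace ROI vertex positions by ``offset_mm`` along per-vertex normals.

    With offset 0 this is the identity — on the synthetic meshes the vertices
    already sit on the gray/white interface.
    """
    roi_vertices = np.asarray(roi_vertices, dtype=int)
    if roi_vertices.size and (roi_vertices.min() < 0 or roi_vertices.max() >= mesh.n_vertices):
        raise IndexError("roi vertex index out of range")
    return mesh.vertices[roi_vertices] + offset_mm * mesh.normals[roi_vertices]


def fsub_mask(
    endpoints: np.ndarray, roi_points: np.ndarray, radius_mm: float = 3.0
) -> np.ndarray:
    """Radial-search selection mask from precomputed (n, 2, 3) endpoints."""
    roi_points = np.asarray(roi_points, dtype=float)
    if roi_points.size == 0:
        raise ValueError("empty ROI point set (distinguishable from no hits)")
    if radius_mm <= 0:
        raise ValueError("radius must be positive")
    endpoints = np.asarray(endpoints, dtype=float)
    if endpoints.size == 0:
        return np.zeros(0, dtype=bool)
    tree = cKDTree(roi_points)
    dist, _ = tree.query(endpoints.reshape(-1, 3))
    return (dist.reshape(-1, 2) <= radius_mm).any(axis=1)


def extract_fsub(
    tractogram: Tractogram, roi_points: np.ndarray, radius_mm: float = 3.0
) -> tuple[Tractogram, np.ndarray]:
    """Radial-search sub-bundle extraction.

    A streamline is selected iff either of its two terminal points lies within
    Euclidean distance <= radius of any ROI point.  Returns the order-
    preserving subset and the boolean selection mask.
    """
    if tractogram.count == 0:
        # still validate the ROI argument
        fsub_mask(np.empty((0, 2, 3)), roi_points, radius_mm)
        return Tractogram([]), np.zeros(0, dtype=bool)
    mask = fsub_mask(tractogram.endpoints(), roi_points, radius_mm)
    return tractogram.subset(mask), mask


def nearest_vertex(points: np.ndarray, vertices: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Nearest mesh vertex per point; exact distance ties go to the lower index."""
    tree = cKDTree(vertices)
    dist, idx = tree.query(points, k=2)
    dist = np.atleast_2d(dist)
    idx = np.atleast_2d(idx)
    tie = dist[:, 0] == dist[:, 1]
    best = idx[:, 0].copy()
    best[tie] = np.minimum(idx[tie, 0], idx[tie, 1])
    return dist[:, 0], best


def density_from_points(
    points: np.ndarray, mesh: LabeledMesh, radius_mm: float = 3.0
) -> EndpointDensityMap:
    """Bin terminal points to nearest mesh vertices and normalize to sum 1."""
    V = mesh.n_vertices
    points = np.asarray(points, dtype=float).reshape(-1, 3)
    if points.shape[0] == 0:
        return EndpointDensityMap(np.zeros(V), 0)
    dist, idx = nearest_vertex(points, mesh.vertices)
    keep = dist <= radius_mm
    n_kept = int(keep.sum())
    if n_kept == 0:
        return EndpointDensityMap(np.zeros(V), 0)
    counts = np.bincount(idx[keep], minlength=V).astype(float)
    return EndpointDensityMap(counts / n_kept, n_kept)


def endpoint_density(
    subbundle: Tractogram, mesh: LabeledMesh, radius_mm: float = 3.0
) -> EndpointDensityMap:
    """Endpoint-density map: terminal points binned to nearest vertices.

    Endpoints farther than ``radius_mm`` from every vertex are dropped from
    both numerator and denominator.  Zero retained endpoints yields the empty
    sentinel (all-zero density, total 0), never NaNs.
    """
    if subbundle.count == 0:
        return EndpointDensityMap(np.zeros(mesh.n_vertices), 0)
    return density_from_points(subbundle.endpoints(), mesh, radius_mm)


# ---------------------------------------------------------------------------
# Mesh serialization (PLY geometry + TSV labels)

def save_mesh(mesh: LabeledMesh, ply_path, labels_path) -> None:
    """Write geometry as PLY (via trimesh) and label maps as TSV."""
    import pandas as pd
    import trimesh

    tm = trimesh.Trimesh(vertices=mesh.vertices, faces=mesh.faces, process=False)
    tm.export(str(ply_path))
    df = pd.DataFrame({"vertex_index": np.arange(mesh.n_vertices)})
    for name, lab in mesh.labels.items():
        df[name] = lab
    for c, axis in enumerate("xyz"):
        df[f"normal_{axis}"] = mesh.normals[:, c]
    df.to_csv(labels_path, sep="\t", index=False)


def load_mesh(ply_path, labels_path) -> LabeledMesh:
    import pandas as pd
    import trimesh

    tm = trimesh.load(str(ply_path), process=False)
    df = pd.read_csv(labels_path, sep="\t")
    normals = df[["normal_x", "normal_y", "normal_z"]].to_numpy()
    labels = {}
    for name in df.columns:
        if name in ("vertex_index", "normal_x", "normal_y", "normal_z"):
            continue
        col = df[name]
        if col.dtype == object:
            labels[name] = col.fillna("").to_numpy(dtype=object)
        else:
            labels[name] = col.to_numpy()
    return LabeledMesh(
        vertices=np.asarray(tm.vertices), faces=np.asarray(tm.faces), normals=normals, labels=labels
    )
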