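"""Anatomical axes from labeled biventricular surface meshes.

Five long-axis definitions are supported, all in the patient DICOM LPS frame:

``PC1LV``
    First principal component of the LV endocardial point cloud.
``PC1LRV``
    First principal component of the biventricular epicardial point cloud.
``MVA`` / ``MAVA`` / ``VPA``
    Vector from the LV apex to a basal landmark: the mitral-valve centre,
    the mitral+aortic centre, or the centre of all four valve rings.
    The apex is the LV endocardial vertex furthest from the basal landmark
    and is recomputed independently for each basal definition.

Apex-to-base orientation is enforced for every method so directions from
different definitions are mutually comparable. Mesh quality control uses the
sphericity index (short-axis / long-axis extent of the epicardial cloud);
exclusion is a population-level +/-3 SD rule applied elsewhere.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import trimesh

from cardaxes.errors import (
    DegenerateGeometryError,
    FormatError,
    IncompleteMeshError,
    UsageError,
)

#: Region codes of a complete labeled biventricular surface.
REGIONS = ("LV_ENDO", "BIV_EPI", "MV_RING", "AV_RING", "TV_RING", "PV_RING")

#: Default integer encoding used in mesh files (PLY integer property).
DEFAULT_LABEL_MAP: dict[int, str] = {
    1: "LV_ENDO",
    2: "BIV_EPI",
    3: "MV_RING",
    4: "AV_RING",
    5: "TV_RING",
    6: "PV_RING",
}

ANATOMICAL_METHODS = ("PC1LV", "PC1LRV", "MVA", "MAVA", "VPA")

#: Valve-ring sets defining the basal landmark of each landmark-based method.
_METHOD_VALVES = {
    "MVA": ("MV_RING",),
    "MAVA": ("MV_RING", "AV_RING"),
    "VPA": ("MV_RING", "AV_RING", "TV_RING", "PV_RING"),
}

_LABEL_ARRAY_NAME = "region_label"


def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    if n < 1e-12:
        raise DegenerateGeometryError("cannot normalise a near-zero vector")
    return v / n


@dataclass
class LabeledSurfaceMesh:
    """Triangulated biventricular surface with per-vertex region labels.

    Vertices are in mm, patient LPS frame. ``labels`` holds one region code
    string per vertex, drawn from :data:`REGIONS`.
    """

    vertices: np.ndarray
    faces: np.ndarray
    labels: np.ndarray
    subject_id: str = "unknown"

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.faces = np.asarray(self.faces, dtype=np.int64)
        self.labels = np.asarray(self.labels)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise FormatError("vertices must be an (n, 3) array")
        if not np.all(np.isfinite(self.vertices)):
            raise FormatError("vertices contain non-finite coordinates")
        if self.faces.size and (
            self.faces.min() < 0 or self.faces.max() >= len(self.vertices)
        ):
            raise FormatError("face indices out of range")
        if len(self.labels) != len(self.vertices):
            raise FormatError("labels must align with vertices")

    def region_points(self, region: str) -> np.ndarray:
        """Vertices belonging to one labeled region, (k, 3)."""
        if region not in REGIONS:
            raise UsageError(f"unknown region code {region!r}")
        pts = self.vertices[self.labels == region]
        if len(pts) == 0:
            raise IncompleteMeshError(region)
        return pts

    def region_indices(self, region: str) -> np.ndarray:
        if region not in REGIONS:
            raise UsageError(f"unknown region code {region!r}")
        return np.flatnonzero(self.labels == region)

    def is_complete(self) -> bool:
        present = set(np.unique(self.labels))
        return all(r in present for r in REGIONS)

    def validate_complete(self) -> None:
        present = set(np.unique(self.labels))
        for r in REGIONS:
            if r not in present:
                raise IncompleteMeshError(r)


@dataclass
class CardiacAxis:
    """A unit axis direction with its origin point and provenance tags.

    The same container serves anatomical (mesh-derived) and electrical
    (QRS-loop-derived) axes; ``method`` records the definition and ``frame``
    the coordinate system (always "LPS" for comparable axes).
    """

    direction: np.ndarray
    origin: np.ndarray | None
    method: str
    subject_id: str = "unknown"
    frame: str = "LPS"

    def __post_init__(self) -> None:
        self.direction = np.asarray(self.direction, dtype=float)
        if self.direction.shape != (3,):
            raise UsageError("direction must be a 3-vector")
        n = np.linalg.norm(self.direction)
        if abs(n - 1.0) > 1e-9:
            raise UsageError(f"direction must be unit length, got norm {n}")
        if self.origin is not None:
            self.origin = np.asarray(self.origin, dtype=float)


@dataclass
class MeshQCRecord:
    """Sphericity index for one mesh; exclusion decided at population level."""

    subject_id: str
    sphericity_index: float
    excluded: bool = False


def _promote_face_labels(
    n_vertices: int, faces: np.ndarray, face_labels: np.ndarray
) -> np.ndarray:
    """Per-face integer labels -> per-vertex by majority vote over incident
    faces; ties broken by the lowest label value."""
    votes: list[dict[int, int]] = [dict() for _ in range(n_vertices)]
    for tri, lab in zip(faces, face_labels):
        for v in tri:
            votes[v][int(lab)] = votes[v].get(int(lab), 0) + 1
    out = np.zeros(n_vertices, dtype=np.int64)
    for i, counter in enumerate(votes):
        if not counter:
            raise FormatError(f"vertex {i} belongs to no labeled face")
        best = max(counter.items(), key=lambda kv: (kv[1], -kv[0]))
        out[i] = best[0]
    return out


def load_labeled_mesh(
    path: str | Path,
    label_map: Mapping[int, str] | None = None,
    subject_id: str | None = None,
    label_array: str = _LABEL_ARRAY_NAME,
    require_complete: bool = True,
) -> LabeledSurfaceMesh:
    """Load a PLY/VTK-readable triangulated surface with an integer label array.

    The label array may be per-vertex or per-face (promoted to per-vertex by
    majority vote, lowest-value tie-break). ``label_map`` translates file
    integers to region codes; unknown values raise :class:`FormatError`
    listing them. A missing label array or any empty required region is an
    error.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"mesh file not found: {path}")
    label_map = dict(label_map) if label_map is not None else dict(DEFAULT_LABEL_MAP)
    loaded = trimesh.load(path, process=False)
    if not isinstance(loaded, trimesh.Trimesh):
        raise FormatError(f"{path} did not parse as a single triangulated surface")
    raw = loaded.metadata.get("_ply_raw", {})

    def _raw_array(element: str) -> np.ndarray | None:
        data = raw.get(element, {}).get("data")
        if isinstance(data, dict) and label_array in data:
            return np.asarray(data[label_array]).reshape(-1).astype(np.int64)
        return None

    int_labels = _raw_array("vertex")
    if int_labels is None:
        face_labels = _raw_array("face")
        if face_labels is None:
            raise FormatError(
                f"{path} has no integer array {label_array!r} on vertices or faces"
            )
        int_labels = _promote_face_labels(
            len(loaded.vertices), np.asarray(loaded.faces), face_labels
        )

    unknown = sorted(set(int_labels.tolist()) - set(label_map))
    if unknown:
        raise FormatError(f"unknown label values in {path}: {unknown}")
    codes = np.array([label_map[int(v)] for v in int_labels])
    mesh = LabeledSurfaceMesh(
        vertices=np.asarray(loaded.vertices, dtype=float),
        faces=np.asarray(loaded.faces, dtype=np.int64),
        labels=codes,
        subject_id=subject_id or path.stem,
    )
    if require_complete:
        mesh.validate_complete()
    return mesh


def save_labeled_mesh(
    mesh: LabeledSurfaceMesh,
    path: str | Path,
    label_map: Mapping[int, str] | None = None,
    label_array: str = _LABEL_ARRAY_NAME,
) -> Path:
    """Write a mesh as ASCII PLY with a per-vertex integer label property."""
    path = Path(path)
    label_map = dict(label_map) if label_map is not None else dict(DEFAULT_LABEL_MAP)
    inverse = {code: value for value, code in label_map.items()}
    missing = sorted(set(np.unique(mesh.labels)) - set(inverse))
    if missing:
        raise UsageError(f"label_map lacks integer codes for regions {missing}")
    tm = trimesh.Trimesh(vertices=mesh.vertices, faces=mesh.faces, process=False)
    tm.vertex_attributes[label_array] = np.array(
        [inverse[c] for c in mesh.labels], dtype=np.int32
    )
    tm.export(path, encoding="ascii")
    return path


def _principal_axes(points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Principal directions (rows, descending variance) and centroid."""
    pts = np.asarray(points, dtype=float)
    if len(pts) < 4:
        raise DegenerateGeometryError("need at least 4 points for PCA")
    centroid = pts.mean(axis=0)
    _, s, vt = np.linalg.svd(pts - centroid, full_matrices=False)
    if s[1] < 1e-9 * max(s[0], 1.0):
        raise DegenerateGeometryError("point cloud is rank-deficient (collinear)")
    return vt, centroid


def sphericity_index(mesh: LabeledSurfaceMesh) -> float:
    """Short-to-long axis extent ratio of the biventricular epicardial cloud.

    Extents are max-min of projections onto the first two principal
    components; the ratio lies in (0, 1] and is invariant to rigid motion
    and uniform scaling. Abnormally flat meshes score low.
    """
    pts = mesh.region_points("BIV_EPI")
    vt, centroid = _principal_axes(pts)
    centered = pts - centroid
    extents = [np.ptp(centered @ vt[i]) for i in (0, 1)]
    if extents[0] <= 0:
        raise DegenerateGeometryError("degenerate epicardial point cloud")
    return float(min(extents[1] / extents[0], 1.0))


def valve_centroid(mesh: LabeledSurfaceMesh, regions: Iterable[str]) -> np.ndarray:
    """Basal landmark: mean of per-valve ring centroids.

    Each ring contributes its own centroid with equal weight, so a densely
    sampled ring does not pull the landmark toward itself.
    """
    regions = tuple(regions)
    if not regions:
        raise UsageError("at least one valve region required")
    centroids = [mesh.region_points(r).mean(axis=0) for r in regions]
    return np.mean(centroids, axis=0)


def find_apex(mesh: LabeledSurfaceMesh, basal_point: np.ndarray) -> np.ndarray:
    """LV endocardial vertex furthest from the basal landmark.

    Ties are broken by the lowest vertex index, making the result
    deterministic on symmetric meshes.
    """
    basal_point = np.asarray(basal_point, dtype=float)
    if basal_point.shape != (3,) or not np.all(np.isfinite(basal_point)):
        raise UsageError("basal_point must be a finite 3-vector")
    pts = mesh.region_points("LV_ENDO")
    d2 = np.einsum("ij,ij->i", pts - basal_point, pts - basal_point)
    return pts[int(np.argmax(d2))].copy()


def anatomical_axis(mesh: LabeledSurfaceMesh, method: str) -> CardiacAxis:
    """Compute one anatomical long-axis definition, oriented apex -> base."""
    if method in _METHOD_VALVES:
        basal = valve_centroid(mesh, _METHOD_VALVES[method])
        apex = find_apex(mesh, basal)
        direction = _unit(basal - apex)
        origin = apex
    elif method in ("PC1LV", "PC1LRV"):
        region = "LV_ENDO" if method == "PC1LV" else "BIV_EPI"
        vt, centroid = _principal_axes(mesh.region_points(region))
        direction = vt[0].copy()
        # PC1 sign is arbitrary: orient along the mesh's own MVA (apex->base)
        # direction, falling back to +z (superior) when the mitral ring is
        # absent.
        try:
            reference = anatomical_axis(mesh, "MVA").direction
        except IncompleteMeshError:
            reference = np.array([0.0, 0.0, 1.0])
        if float(direction @ reference) < 0:
            direction = -direction
        origin = centroid
    else:
        raise UsageError(
            f"unknown anatomical method {method!r}; expected one of {ANATOMICAL_METHODS}"
        )
    return CardiacAxis(
        direction=direction, origin=origin, method=method, subject_id=mesh.subject_id
    )


def axes_table_rows(axes: Sequence[CardiacAxis]) -> list[dict]:
    """Flatten axes into rows for a delimited-text table."""
    rows = []
    for ax in axes:
        origin = ax.origin if ax.origin is not None else np.full(3, np.nan)
        rows.append(
            {
                "subject_id": ax.subject_id,
                "method": ax.method,
                "origin_x_mm": origin[0],
                "origin_y_mm": origin[1],
                "origin_z_mm": origin[2],
                "dir_x": ax.direction[0],
                "dir_y": ax.direction[1],
                "dir_z": ax.direction[2],
                "frame": ax.frame,
            }
        )
    return rows
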