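"""Mesh data model and geometry primitives for 4D endocardial surfaces.

The central container is :class:`MeshFrameSequence`: one closed triangulated
endocardial surface per cardiac frame, with vertex correspondence across
frames (same vertex tracked through the cycle) and a per-face wall-region
labelling.  All coordinates are world millimetres.

Strain is elemental (per triangle), so region labels live on faces, not
vertices.  Faces whose reference area falls below ``DEGENERATE_AREA_MM2``
are excluded from strain averaging and logged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import trimesh

__all__ = [
    "REGIONS",
    "EXCLUDED",
    "MeshFrameSequence",
    "VolumeCurve",
    "element_areas",
    "enclosed_volume",
    "assign_regions",
    "spherical_region_chart",
]

logger = logging.getLogger(__name__)

#: The five left-atrial body wall regions, in canonical order.
REGIONS = ("septum", "lateral", "posterior", "anterior", "inferior")

#: Label for faces excluded from the body (pulmonary-vein / appendage analogues).
EXCLUDED = "excluded"

#: Faces with reference area below this (mm^2) are treated as degenerate.
DEGENERATE_AREA_MM2 = 1e-12

MM3_PER_ML = 1000.0


def element_areas(vertices: np.ndarray, faces: np.ndarray) -> np.ndarray:
    """Per-triangle areas (mm^2) of a single mesh frame.

    Each area is half the magnitude of the cross product of two edge
    vectors.  Degenerate (near-zero-area) faces are reported in the log
    with their indices but still returned, so callers decide the policy.
    """
    v = np.asarray(vertices, dtype=float)
    f = np.asarray(faces, dtype=int)
    if f.ndim != 2 or f.shape[1] != 3:
        raise ValueError("faces must be an (n, 3) integer array")
    if f.size and (f.min() < 0 or f.max() >= len(v)):
        raise ValueError("faces reference vertices outside the vertex array")
    e1 = v[f[:, 1]] - v[f[:, 0]]
    e2 = v[f[:, 2]] - v[f[:, 0]]
    areas = 0.5 * np.linalg.norm(np.cross(e1, e2), axis=1)
    bad = np.flatnonzero(areas < DEGENERATE_AREA_MM2)
    if bad.size:
        logger.warning("degenerate faces (area < %g mm^2): %s",
                       DEGENERATE_AREA_MM2, bad.tolist())
    return areas


def enclosed_volume(vertices: np.ndarray, faces: np.ndarray) -> float:
    """Volume (mL) enclosed by a closed triangulated surface.

    Uses the divergence theorem (sum of signed tetrahedron volumes against
    the origin); the result is returned positive regardless of the surface
    orientation.  Raises ``ValueError`` for open (non-watertight) surfaces.
    """
    v = np.asarray(vertices, dtype=float)
    f = np.asarray(faces, dtype=int)
    tm = trimesh.Trimesh(vertices=v, faces=f, process=False)
    if not tm.is_watertight:
        raise ValueError("surface is not closed (open edges present)")
    a, b, c = v[f[:, 0]], v[f[:, 1]], v[f[:, 2]]
    signed = np.einsum("ij,ij->i", a, np.cross(b, c)).sum() / 6.0
    return abs(signed) / MM3_PER_ML


def spherical_region_chart(directions: np.ndarray) -> np.ndarray:
    """Map unit-sphere directions to the five-wall labelling.

    The chart stands in for a universal-atrial-coordinate style division:
    a small superior cap (``z > 0.85``) is excluded as the pulmonary-vein /
    appendage analogue, an inferior cap (``z < -0.55``) is the inferior
    wall, and the remaining band is split into azimuthal quadrants for the
    anterior, lateral, posterior and septal walls.

    Parameters
    ----------
    directions : (n, 3) array of unit vectors (points on the parametric sphere).

    Returns
    -------
    (n,) array of label strings.
    """
    d = np.asarray(directions, dtype=float)
    d = d / np.linalg.norm(d, axis=1, keepdims=True)
    z = d[:, 2]
    phi = np.degrees(np.arctan2(d[:, 1], d[:, 0]))  # (-180, 180]
    labels = np.empty(len(d), dtype=object)
    labels[:] = EXCLUDED
    body = z <= 0.85
    inferior = body & (z < -0.55)
    band = body & ~inferior
    labels[inferior] = "inferior"
    labels[band & (phi >= -45) & (phi < 45)] = "anterior"
    labels[band & (phi >= 45) & (phi < 135)] = "lateral"
    labels[band & ((phi >= 135) | (phi < -135))] = "posterior"
    labels[band & (phi >= -135) & (phi < -45)] = "septum"
    return labels.astype(str)


def assign_regions(
    vertices: np.ndarray,
    faces: np.ndarray,
    chart_directions: np.ndarray | None = None,
    explicit_labels: np.ndarray | None = None,
) -> np.ndarray:
    """Per-face region labels by parametric chart or explicit pass-through.

    With ``explicit_labels`` the labels are validated and returned
    unchanged.  Otherwise every face is labelled by the chart position of
    its centroid in the parametric coordinates (``chart_directions`` gives
    each vertex's position on the parametric sphere; a face straddling a
    patch boundary is assigned by its centroid).
    """
    f = np.asarray(faces, dtype=int)
    if explicit_labels is not None:
        lab = np.asarray(explicit_labels, dtype=str)
        if len(lab) != len(f):
            raise ValueError(
                f"label length {len(lab)} does not match face count {len(f)}")
        bad = set(np.unique(lab)) - set(REGIONS) - {EXCLUDED}
        if bad:
            raise ValueError(f"unknown region labels: {sorted(bad)}")
        return lab
    if chart_directions is None:
        raise ValueError("either chart_directions or explicit_labels required")
    cd = np.asarray(chart_directions, dtype=float)
    if len(cd) != len(np.asarray(vertices)):
        raise ValueError("chart_directions must be per-vertex")
    centroids = cd[f].mean(axis=1)
    return spherical_region_chart(centroids)


@dataclass
class MeshFrameSequence:
    """One closed endocardial surface per cardiac frame, vertex-corresponded.

    Parameters
    ----------
    vertices_per_frame : list of (n_vertices, 3) float arrays, mm.
    faces : (n_faces, 3) int array shared by all frames.
    frame_times : normalized R-R times in [0, 1), strictly increasing,
        first entry 0 (the end-diastolic reference frame).
    region_labels : (n_faces,) array of strings in ``REGIONS`` or
        ``EXCLUDED``.
    """

    vertices_per_frame: list[np.ndarray]
    faces: np.ndarray
    frame_times: np.ndarray
    region_labels: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.faces = np.asarray(self.faces, dtype=int)
        self.frame_times = np.asarray(self.frame_times, dtype=float)
        self.vertices_per_frame = [np.asarray(v, dtype=float)
                                   for v in self.vertices_per_frame]
        n_v = {v.shape for v in self.vertices_per_frame}
        if len(n_v) != 1:
            raise ValueError("vertex count differs across frames")
        if len(self.vertices_per_frame) != len(self.frame_times):
            raise ValueError("frame_times length must match frame count")
        if self.frame_times[0] != 0.0:
            raise ValueError("first frame time must be 0 (end-diastole)")
        if np.any(np.diff(self.frame_times) <= 0):
            raise ValueError("frame_times must be strictly increasing")
        if np.any(self.frame_times >= 1.0) or np.any(self.frame_times < 0.0):
            raise ValueError("frame_times must lie in [0, 1)")
        if self.region_labels is None:
            self.region_labels = np.full(len(self.faces), REGIONS[0], dtype=object).astype(str)
        else:
            self.region_labels = np.asarray(self.region_labels, dtype=str)
            if len(self.region_labels) != len(self.faces):
                raise ValueError("region_labels must be per-face")

    # -- basic introspection -------------------------------------------------

    @property
    def n_frames(self) -> int:
        return len(self.vertices_per_frame)

    @property
    def n_vertices(self) -> int:
        return self.vertices_per_frame[0].shape[0]

    @property
    def n_faces(self) -> int:
        return self.faces.shape[0]

    @property
    def body_mask(self) -> np.ndarray:
        """Boolean mask over faces belonging to the LA body (non-excluded)."""
        return self.region_labels != EXCLUDED

    def frame(self, k: int) -> trimesh.Trimesh:
        """Frame ``k`` as a :class:`trimesh.Trimesh` (no reprocessing)."""
        return trimesh.Trimesh(vertices=self.vertices_per_frame[k],
                               faces=self.faces, process=False)

    # -- derived quantities ---------------------------------------------------

    def element_areas(self, k: int) -> np.ndarray:
        return element_areas(self.vertices_per_frame[k], self.faces)

    def volume_curve(self, chamber: str = "LA") -> "VolumeCurve":
        """Enclosed volume (mL) at every frame."""
        vols = np.array([enclosed_volume(v, self.faces)
                         for v in self.vertices_per_frame])
        return VolumeCurve(chamber=chamber, volumes=vols,
                           frame_times=self.frame_times.copy())

    def decimate_frames(self, step: int = 2) -> "MeshFrameSequence":
        """Keep every ``step``-th frame starting at the reference frame."""
        idx = np.arange(0, self.n_frames, step)
        return MeshFrameSequence(
            vertices_per_frame=[self.vertices_per_frame[i].copy() for i in idx],
            faces=self.faces.copy(),
            frame_times=self.frame_times[idx].copy(),
            region_labels=self.region_labels.copy(),
        )

    def validate_closed(self) -> None:
        """Raise if the reference surface is open or inconsistently wound."""
        tm = self.frame(0)
        if not tm.is_watertight:
            raise ValueError("reference surface is not closed")
        if not tm.is_winding_consistent:
            raise ValueError("reference surface winding is inconsistent")


@dataclass
class VolumeCurve:
    """Chamber volume (mL) at each frame over normalized R-R time."""

    chamber: str  # "LA" or "LV"
    volumes: np.ndarray
    frame_times: np.ndarray

    def __post_init__(self) -> None:
        self.volumes = np.asarray(self.volumes, dtype=float)
        self.frame_times = np.asarray(self.frame_times, dtype=float)
        if self.chamber not in ("LA", "LV"):
            raise ValueError("chamber must be 'LA' or 'LV'")
        if len(self.volumes) != len(self.frame_times):
            raise ValueError("volumes and frame_times length mismatch")
        if np.any(self.volumes <= 0):
            raise ValueError("volumes must be positive")
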