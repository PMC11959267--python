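"""File formats for mesh sequences and volume frame stacks.

A mesh sequence on disk is one surface file per frame (PLY, OFF, or
legacy ASCII VTK polydata) plus a ``sequence.json`` sidecar holding the
frame order, normalized R-R frame times, and the per-face region labels
(for VTK the labels are additionally embedded as a CELL_DATA attribute).
Round trips are lossless to the declared float precision (ASCII doubles
for VTK and OFF; PLY stores float32 coordinates); frames are ordered by
the sidecar's index, not by filename.

Volume frames are NIfTI files with consistent axis-aligned spacing.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import trimesh

from .image import Image3D
from .mesh import REGIONS, EXCLUDED, MeshFrameSequence

__all__ = [
    "write_mesh_sequence",
    "read_mesh_sequence",
    "write_volume_frames",
    "read_volume_frames",
]

_FORMATS = ("ply", "off", "vtk")
_LABEL_CODES = {name: i for i, name in enumerate((*REGIONS, EXCLUDED))}
_CODE_LABELS = {i: name for name, i in _LABEL_CODES.items()}


# ---------------------------------------------------------------------------
# legacy ASCII VTK polydata (hand-rolled: supports embedded cell labels)
# ---------------------------------------------------------------------------

def _write_vtk(path: Path, vertices: np.ndarray, faces: np.ndarray,
               labels: np.ndarray) -> None:
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\n")
        fh.write("lastrain surface frame\nASCII\nDATASET POLYDATA\n")
        fh.write(f"POINTS {len(vertices)} double\n")
        for p in vertices:
            fh.write(f"{p[0]:.9g} {p[1]:.9g} {p[2]:.9g}\n")
        fh.write(f"POLYGONS {len(faces)} {4 * len(faces)}\n")
        for f in faces:
            fh.write(f"3 {f[0]} {f[1]} {f[2]}\n")
        fh.write(f"CELL_DATA {len(faces)}\n")
        fh.write("SCALARS region_label int 1\nLOOKUP_TABLE default\n")
        for lab in labels:
            fh.write(f"{_LABEL_CODES[lab]}\n")


def _read_vtk(path: Path):
    tokens: list[str] = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                continue
            tokens.extend(line.split())
    def expect(word, at):
        if tokens[at].upper() != word:
            raise ValueError(f"{path}: expected {word}, got {tokens[at]!r}")
    i = tokens.index("POINTS")
    n_pts = int(tokens[i + 1])
    coords = np.array(tokens[i + 3: i + 3 + 3 * n_pts], float).reshape(n_pts, 3)
    i = tokens.index("POLYGONS")
    n_poly = int(tokens[i + 1])
    body = tokens[i + 3: i + 3 + 4 * n_poly]
    faces = np.empty((n_poly, 3), int)
    for k in range(n_poly):
        if body[4 * k] != "3":
            raise ValueError(f"{path}: only triangle faces supported")
        faces[k] = [int(body[4 * k + 1]), int(body[4 * k + 2]),
                    int(body[4 * k + 3])]
    labels = None
    if "CELL_DATA" in tokens:
        i = tokens.index("LOOKUP_TABLE")
        codes = np.array(tokens[i + 2: i + 2 + n_poly], int)
        labels = np.array([_CODE_LABELS[c] for c in codes], dtype=str)
    return coords, faces, labels


# ---------------------------------------------------------------------------
# mesh sequences
# ---------------------------------------------------------------------------

def write_mesh_sequence(seq: MeshFrameSequence, out_dir,
                        fmt: str = "vtk") -> Path:
    """Write one file per frame plus the ``sequence.json`` sidecar."""
    if fmt not in _FORMATS:
        raise ValueError(f"format must be one of {_FORMATS}")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    files = []
    for k, verts in enumerate(seq.vertices_per_frame):
        name = f"frame_{k:03d}.{fmt}"
        path = out / name
        if fmt == "vtk":
            _write_vtk(path, verts, seq.faces, seq.region_labels)
        else:
            tm = trimesh.Trimesh(vertices=verts, faces=seq.faces, process=False)
            tm.export(path)
        files.append(name)
    sidecar = {
        "frames": [{"index": k, "file": f, "time_rr_fraction": float(t)}
                   for k, (f, t) in enumerate(zip(files, seq.frame_times))],
        "region_labels": seq.region_labels.tolist(),
        "format": fmt,
        "units": "mm",
    }
    with open(out / "sequence.json", "w") as fh:
        json.dump(sidecar, fh, indent=1)
    return out


def read_mesh_sequence(in_dir) -> MeshFrameSequence:
    """Read a mesh sequence directory written by :func:`write_mesh_sequence`.

    Frames are ordered by the sidecar index regardless of filename
    order; connectivity must be identical across frames and the label
    sidecar must match the face count, otherwise a specific error names
    the offending frame.
    """
    in_dir = Path(in_dir)
    sidecar_path = in_dir / "sequence.json"
    if not sidecar_path.exists():
        raise FileNotFoundError(f"missing sidecar {sidecar_path}")
    with open(sidecar_path) as fh:
        sidecar = json.load(fh)
    frames = sorted(sidecar["frames"], key=lambda f: f["index"])
    fmt = sidecar.get("format", "vtk")
    verts_list, faces_ref, labels_embedded = [], None, None
    times = []
    for entry in frames:
        path = in_dir / entry["file"]
        if fmt == "vtk":
            verts, faces, labels_embedded = _read_vtk(path)
        else:
            tm = trimesh.load(path, process=False)
            verts, faces = np.asarray(tm.vertices, float), np.asarray(tm.faces, int)
        if faces_ref is None:
            faces_ref = faces
        elif faces.shape != faces_ref.shape or not np.array_equal(faces, faces_ref):
            raise ValueError(
                f"frame {entry['index']} ({entry['file']}): connectivity "
                "differs from frame 0")
        verts_list.append(verts)
        times.append(entry["time_rr_fraction"])
    labels = sidecar.get("region_labels")
    if labels is not None:
        labels = np.asarray(labels, dtype=str)
    elif labels_embedded is not None:
        labels = labels_embedded
    if labels is not None and len(labels) != len(faces_ref):
        raise ValueError(
            f"region label count {len(labels)} does not match face count "
            f"{len(faces_ref)}")
    return MeshFrameSequence(vertices_per_frame=verts_list, faces=faces_ref,
                             frame_times=np.asarray(times, float),
                             region_labels=labels)


# ---------------------------------------------------------------------------
# volume frame stacks (NIfTI)
# ---------------------------------------------------------------------------

def write_volume_frames(frames: list[Image3D], out_dir,
                        frame_times: np.ndarray | None = None) -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if frame_times is None:
        frame_times = np.arange(len(frames)) / len(frames)
    meta = {"frames": []}
    for k, img in enumerate(frames):
        name = f"frame_{k:03d}.nii"
        img.to_nifti(out / name)
        meta["frames"].append({"index": k, "file": name,
                               "time_rr_fraction": float(frame_times[k])})
    with open(out / "frames.json", "w") as fh:
        json.dump(meta, fh, indent=1)
    return out


def read_volume_frames(in_dir) -> tuple[list[Image3D], np.ndarray]:
    """Read a NIfTI frame stack, ordered by declared R-R fraction.

    All frames must share spacing and origin; a mixed-geometry stack is
    rejected with the offending frame named.
    """
    in_dir = Path(in_dir)
    meta_path = in_dir / "frames.json"
    if meta_path.exists():
        with open(meta_path) as fh:
            meta = json.load(fh)
        entries = sorted(meta["frames"], key=lambda f: f["time_rr_fraction"])
        paths = [in_dir / e["file"] for e in entries]
        times = np.array([e["time_rr_fraction"] for e in entries])
    else:
        paths = sorted(in_dir.glob("*.nii*"))
        times = np.arange(len(paths)) / max(len(paths), 1)
    if not paths:
        raise FileNotFoundError(f"no volume frames under {in_dir}")
    frames = [Image3D.from_nifti(p) for p in paths]
    ref = frames[0]
    for p, img in zip(paths[1:], frames[1:]):
        if not img.same_grid(ref):
            raise ValueError(f"{p}: spacing/origin differs from first frame")
    return frames, times
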