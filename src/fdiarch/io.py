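"""Readers/writers: PLY meshes, Teeth3DS-style JSON annotations,
prediction JSON.

On-disk dialect (Teeth3DS convention): the annotation sidecar holds
parallel per-vertex ``labels`` (FDI code, 0 = background) and
``instances`` arrays (positive ids, 0 = background).  Internally the
background instance is -1, so instance ids shift by one on read/write.
Coordinates are millimetres throughout; PLY colour properties are
ignored on read.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional, Tuple, Union

import numpy as np
import trimesh

from .errors import PlyParseError, ValidationError
from .scan import AnnotatedScan, PredictedInstances, PredictedTooth

PathLike = Union[str, Path]


def write_ply(path: PathLike, points: np.ndarray,
              faces: Optional[np.ndarray] = None,
              binary: bool = True) -> None:
    """Write a mesh or point cloud as PLY (binary little-endian or ascii)."""
    path = Path(path)
    encoding = "binary" if binary else "ascii"
    if faces is not None and len(faces):
        mesh = trimesh.Trimesh(vertices=points, faces=faces, process=False)
        data = trimesh.exchange.ply.export_ply(mesh, encoding=encoding)
    else:
        cloud = trimesh.PointCloud(points)
        data = trimesh.exchange.ply.export_ply(cloud, encoding=encoding)
    path.write_bytes(data)


def read_ply(path: PathLike) -> Tuple[np.ndarray, Optional[np.ndarray]]:
    """Read vertices (float64 mm) and faces (or None) from a PLY file."""
    path = Path(path)
    if not path.exists():
        raise PlyParseError(f"no such file: {path}")
    try:
        with open(path, "rb") as handle:
            loaded = trimesh.exchange.ply.load_ply(handle)
    except Exception as exc:   # malformed header or truncated payload
        raise PlyParseError(f"failed to parse {path}: {exc}") from exc
    points = np.asarray(loaded["vertices"], dtype=np.float64)
    faces = loaded.get("faces")
    if faces is not None and len(faces):
        faces = np.asarray(faces, dtype=np.int64)
    else:
        faces = None
    return points, faces


def write_annotation(path: PathLike, scan: AnnotatedScan) -> None:
    """Write the JSON annotation sidecar for a scan."""
    payload = {
        "labels": scan.vertex_fdi.tolist(),
        "instances": (scan.vertex_instance + 1).tolist(),
        "arch": scan.arch,
    }
    Path(path).write_text(json.dumps(payload))


def read_annotation(path: PathLike, vertex_count: int) -> dict:
    """Read and validate an annotation sidecar.

    Checks array lengths against the mesh and the one-label-per-instance
    invariant; returns internal-convention arrays (background instance
    -1) plus the arch tag.
    """
    data = json.loads(Path(path).read_text())
    for key in ("labels", "instances"):
        if key not in data:
            raise ValidationError(f"annotation file missing {key!r} array")
        if len(data[key]) != vertex_count:
            raise ValidationError(
                f"annotation {key!r} has {len(data[key])} entries for "
                f"{vertex_count} vertices")
    labels = np.asarray(data["labels"], dtype=np.int64)
    instances = np.asarray(data["instances"], dtype=np.int64) - 1
    for inst in np.unique(instances):
        if inst == -1:
            continue
        inst_labels = np.unique(labels[instances == inst])
        if len(inst_labels) != 1 or inst_labels[0] == 0:
            raise ValidationError(
                f"instance {int(inst) + 1} carries labels "
                f"{sorted(int(l) for l in inst_labels)}; each instance must "
                "map to exactly one nonzero label")
    return {"labels": labels, "instances": instances,
            "arch": data.get("arch")}


def read_scan(mesh_path: PathLike, annotation_path: PathLike,
              arch: Optional[str] = None) -> AnnotatedScan:
    points, faces = read_ply(mesh_path)
    ann = read_annotation(annotation_path, len(points))
    arch = arch or ann["arch"]
    if arch is None:
        raise ValidationError(
            "annotation file has no arch tag; pass the arch explicitly")
    return AnnotatedScan(points, faces, ann["instances"], ann["labels"], arch)


def write_scan(mesh_path: PathLike, annotation_path: PathLike,
               scan: AnnotatedScan, binary: bool = True) -> None:
    write_ply(mesh_path, scan.points, scan.faces, binary=binary)
    write_annotation(annotation_path, scan)


def write_predictions(path: PathLike,
                      predictions: PredictedInstances) -> None:
    payload = {
        "instances": [
            {
                "centroid": tooth.centroid.tolist(),
                "logits": tooth.logits.tolist(),
                "vertices": tooth.vertices.tolist(),
            }
            for tooth in predictions.instances
        ],
        "n_vertices": int(predictions.n_vertices),
    }
    Path(path).write_text(json.dumps(payload))


def read_predictions(path: PathLike,
                     vertex_count: Optional[int] = None,
                     ) -> PredictedInstances:
    data = json.loads(Path(path).read_text())
    teeth = [
        PredictedTooth(
            np.asarray(entry.get("vertices", []), dtype=np.int64),
            np.asarray(entry["centroid"], dtype=np.float64),
            np.asarray(entry["logits"], dtype=np.float64),
        )
        for entry in data["instances"]
    ]
    n = vertex_count or int(data.get("n_vertices", 0))
    vertex_instance = np.full(n, -1, dtype=np.int64)
    for idx, tooth in enumerate(teeth):
        vertex_instance[tooth.vertices] = idx
    return PredictedInstances(teeth, vertex_instance, n_vertices=n)
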