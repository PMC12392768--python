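"""In-memory containers for annotated scans and mock network predictions.

An :class:`AnnotatedScan` is a triangle mesh (or bare point cloud) of one
dental arch with per-vertex instance ids and FDI labels, mirroring the
Teeth3DS annotation convention (parallel ``labels`` / ``instances``
arrays).  Internally the background/gingiva instance is ``-1`` and the
background label is ``0``; the io module maps these to the on-disk
dialect.

A :class:`PredictedInstances` bundle is what an upstream instance
segmenter would hand the postprocessor: per-instance vertex memberships,
centroids (mm) and 32-class logit vectors in the fixed
:data:`fdiarch.fdi.ALL_LABELS` order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components as _sparse_cc
from scipy.spatial import cKDTree

from . import fdi
from .errors import ValidationError

BACKGROUND_INSTANCE = -1
BACKGROUND_LABEL = 0


@dataclass
class AnnotatedScan:
    """Mesh/point cloud of one arch with ground-truth annotations.

    points : (N, 3) float64, mm
    faces : (M, 3) int triangle indices, or None for a bare point cloud
    vertex_instance : (N,) int, -1 = gingiva/background
    vertex_fdi : (N,) int FDI code, 0 = background
    arch : "upper" | "lower"
    """

    points: np.ndarray
    faces: Optional[np.ndarray]
    vertex_instance: np.ndarray
    vertex_fdi: np.ndarray
    arch: str

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=np.float64)
        self.vertex_instance = np.asarray(self.vertex_instance, dtype=np.int64)
        self.vertex_fdi = np.asarray(self.vertex_fdi, dtype=np.int64)
        if self.faces is not None:
            self.faces = np.asarray(self.faces, dtype=np.int64)
        n = len(self.points)
        if len(self.vertex_instance) != n or len(self.vertex_fdi) != n:
            raise ValidationError("annotation arrays must match vertex count")
        self._check_one_label_per_instance()

    def _check_one_label_per_instance(self) -> None:
        for inst in self.instance_ids():
            labels = np.unique(self.vertex_fdi[self.vertex_instance == inst])
            if len(labels) != 1:
                raise ValidationError(
                    f"instance {inst} carries labels {sorted(labels.tolist())};"
                    " every instance must have exactly one FDI label"
                )
            fdi.validate_fdi(int(labels[0]))
            if fdi.arch_of(int(labels[0])) != self.arch:
                raise ValidationError(
                    f"label {int(labels[0])} does not belong to the "
                    f"{self.arch} arch"
                )

    # -- queries ---------------------------------------------------------

    def instance_ids(self) -> List[int]:
        ids = np.unique(self.vertex_instance)
        return [int(i) for i in ids if i != BACKGROUND_INSTANCE]

    @property
    def n_teeth(self) -> int:
        return len(self.instance_ids())

    def label_of_instance(self, inst: int) -> int:
        mask = self.vertex_instance == inst
        if not mask.any():
            raise ValidationError(f"no vertices with instance id {inst}")
        return int(self.vertex_fdi[mask][0])

    def present_labels(self) -> List[int]:
        """FDI labels present, ordered along the canonical arch sequence."""
        present = {self.label_of_instance(i) for i in self.instance_ids()}
        return [l for l in fdi.arch_sequence(self.arch).labels if l in present]

    def instance_of_label(self, label: int) -> int:
        for inst in self.instance_ids():
            if self.label_of_instance(inst) == label:
                return inst
        raise ValidationError(f"label {label} not present in scan")

    def centroid_of_instance(self, inst: int) -> np.ndarray:
        return self.points[self.vertex_instance == inst].mean(axis=0)

    def centroid_of_label(self, label: int) -> np.ndarray:
        mask = self.vertex_fdi == label
        if not mask.any():
            raise ValidationError(f"label {label} not present in scan")
        return self.points[mask].mean(axis=0)

    def tooth_centroids(self) -> Dict[int, np.ndarray]:
        """Instance id -> centroid (mm)."""
        return {i: self.centroid_of_instance(i) for i in self.instance_ids()}

    # -- edits -----------------------------------------------------------

    def copy(self) -> "AnnotatedScan":
        return AnnotatedScan(
            self.points.copy(),
            None if self.faces is None else self.faces.copy(),
            self.vertex_instance.copy(),
            self.vertex_fdi.copy(),
            self.arch,
        )

    def translated(self, offset: np.ndarray) -> "AnnotatedScan":
        out = self.copy()
        out.points = out.points + np.asarray(offset, dtype=np.float64)
        return out

    def subset(self, keep: np.ndarray) -> "AnnotatedScan":
        """Restrict to a boolean vertex mask, dropping cut faces."""
        keep = np.asarray(keep, dtype=bool)
        index_map = -np.ones(len(self.points), dtype=np.int64)
        index_map[keep] = np.arange(int(keep.sum()))
        faces = None
        if self.faces is not None:
            face_ok = keep[self.faces].all(axis=1)
            faces = index_map[self.faces[face_ok]]
        return AnnotatedScan(
            self.points[keep],
            faces,
            self.vertex_instance[keep],
            self.vertex_fdi[keep],
            self.arch,
        )


def vertex_adjacency(points: np.ndarray,
                     faces: Optional[np.ndarray]) -> coo_matrix:
    """Symmetric vertex adjacency: mesh edges, or an epsilon-radius graph
    (epsilon = 2x median nearest-neighbour distance) for bare point clouds."""
    n = len(points)
    if faces is not None and len(faces):
        i = np.concatenate([faces[:, 0], faces[:, 1], faces[:, 2]])
        j = np.concatenate([faces[:, 1], faces[:, 2], faces[:, 0]])
    else:
        tree = cKDTree(points)
        nn_dist, _ = tree.query(points, k=2)
        eps = 2.0 * float(np.median(nn_dist[:, 1]))
        pairs = tree.query_pairs(eps, output_type="ndarray")
        i, j = pairs[:, 0], pairs[:, 1]
    data = np.ones(len(i), dtype=np.int8)
    adj = coo_matrix((data, (i, j)), shape=(n, n))
    return adj + adj.T


def connected_components(points: np.ndarray,
                         faces: Optional[np.ndarray]) -> np.ndarray:
    """Per-vertex component id for the surface connectivity graph."""
    if len(points) == 0:
        return np.zeros(0, dtype=np.int64)
    _, labels = _sparse_cc(vertex_adjacency(points, faces), directed=False)
    return labels.astype(np.int64)


@dataclass
class PredictedTooth:
    """One predicted tooth instance as emitted by an instance segmenter."""

    vertices: np.ndarray          # vertex indices into the scan
    centroid: np.ndarray          # (3,) mm
    logits: np.ndarray            # (32,) in fdi.ALL_LABELS order
    source_instance: Optional[int] = None   # ground-truth id for mocks

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=np.int64)
        self.centroid = np.asarray(self.centroid, dtype=np.float64)
        self.logits = np.asarray(self.logits, dtype=np.float64)
        if self.logits.shape != (32,):
            raise ValidationError("logit vectors carry 32 classes")

    def argmax_label(self) -> int:
        return fdi.ALL_LABELS[int(np.argmax(self.logits))]


@dataclass
class PredictedInstances:
    """Instance-segmentation output for one scan."""

    instances: List[PredictedTooth]
    vertex_instance: np.ndarray   # (N,) predicted instance id per vertex
    n_vertices: int = field(default=0)

    def __post_init__(self) -> None:
        self.vertex_instance = np.asarray(self.vertex_instance, dtype=np.int64)
        if self.n_vertices == 0:
            self.n_vertices = len(self.vertex_instance)
        seen: set = set()
        for tooth in self.instances:
            overlap = seen.intersection(tooth.vertices.tolist())
            if overlap:
                raise ValidationError("instance vertex sets must be disjoint")
            seen.update(tooth.vertices.tolist())

    def centroids(self) -> np.ndarray:
        return np.array([t.centroid for t in self.instances], dtype=np.float64)

    def logit_matrix(self) -> np.ndarray:
        return np.array([t.logits for t in self.instances], dtype=np.float64)
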