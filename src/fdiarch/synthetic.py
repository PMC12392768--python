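"""Seeded generator of annotated synthetic dental arches and of noisy
mock network predictions.

The generator emulates the geometry the downstream stages care about —
teeth placed along a parabolic arch curve, class-dependent tooth sizes,
a connected gingiva band, per-vertex instance/FDI annotations, scans
already in the standard pose — without attempting photorealistic
anatomy.  Teeth are anisotropically scaled icospheres; the gingiva is a
triangulated ribbon bridged to every tooth base so the mesh forms a
single connected surface (the property the partial-arch crop step
relies on).

`perturb_predictions` converts ground truth into network-like output:
per-instance centroids (optionally jittered), 32-class logit vectors
peaked at the (possibly confused) label, boundary flips, dropped and
spurious instances.  All randomness flows from the single seed in the
config, so fixtures are reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
import trimesh

from . import fdi
from .align import standard_pose_from_landmarks
from .errors import LandmarkError, ValidationError
from .scan import (AnnotatedScan, PredictedInstances, PredictedTooth,
                   vertex_adjacency)

# mesiodistal / buccolingual widths (mm) by position digit, anatomically
# plausible proportions (molars > premolars > canines/incisors); scaled
# to the arch so teeth fill ~65% of their slot, leaving small gaps
_TOOTH_WIDTH_MM = {
    1: (8.5, 7.0), 2: (6.5, 6.5), 3: (7.5, 8.0), 4: (7.0, 9.0),
    5: (7.0, 9.0), 6: (10.0, 11.0), 7: (10.0, 10.5), 8: (9.0, 10.0),
}
_CROWN_HEIGHT_MM = 8.0
_FILL_FACTOR = 0.65        # mesiodistal only: creates inter-tooth gaps
_RIBBON_HALF_WIDTH_MM = 3.0

#: 14 teeth (third molars absent) — the most common full-arch pattern
DEFAULT_UPPER_LABELS: Tuple[int, ...] = tuple(
    l for l in fdi.UPPER_SEQUENCE if l % 10 != 8)
DEFAULT_LOWER_LABELS: Tuple[int, ...] = tuple(
    l for l in fdi.LOWER_SEQUENCE if l % 10 != 8)


@dataclass
class GeneratorConfig:
    arch: str = fdi.UPPER
    present_labels: Optional[Sequence[int]] = None   # default: 14 teeth
    points_per_tooth: int = 42
    gingiva_points: int = 240
    arch_width_mm: float = 55.0
    arch_depth_mm: float = 45.0
    centroid_jitter_mm: float = 0.3
    with_faces: bool = True
    seed: int = 0

    def resolved_labels(self) -> List[int]:
        if self.present_labels is None:
            labels = (DEFAULT_UPPER_LABELS if self.arch == fdi.UPPER
                      else DEFAULT_LOWER_LABELS)
            return list(labels)
        labels = [fdi.validate_fdi(int(l)) for l in self.present_labels]
        if not labels:
            raise ValidationError("present_labels must be nonempty")
        for label in labels:
            if fdi.arch_of(label) != self.arch:
                raise ValidationError(
                    f"label {label} does not belong to the {self.arch} arch")
        if len(set(labels)) != len(labels):
            raise ValidationError("present_labels must be distinct")
        return labels

    def validate(self) -> None:
        if self.arch not in (fdi.UPPER, fdi.LOWER):
            raise ValidationError(f"unknown arch {self.arch!r}")
        if self.arch_width_mm <= 0 or self.arch_depth_mm <= 0:
            raise ValidationError("arch dimensions must be positive")
        if self.points_per_tooth < 12:
            raise ValidationError("points_per_tooth must be at least 12")
        if self.gingiva_points < 0 or self.centroid_jitter_mm < 0:
            raise ValidationError("counts and jitter must be nonnegative")
        self.resolved_labels()


@dataclass
class NoiseConfig:
    """Noise model for the mock predictor (all rates in [0, 1])."""

    centroid_sigma_mm: float = 0.0
    logit_temperature: float = 1.0
    label_confusion_rate: float = 0.0
    boundary_flip_rate: float = 0.0
    drop_rate: float = 0.0
    spurious_rate: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        for name in ("label_confusion_rate", "boundary_flip_rate",
                     "drop_rate"):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ValidationError(f"{name} must lie in [0, 1]")
        if self.logit_temperature <= 0:
            raise ValidationError("logit_temperature must be positive")
        if self.centroid_sigma_mm < 0 or self.spurious_rate < 0:
            raise ValidationError("noise scales must be nonnegative")


# -- arch curve geometry -------------------------------------------------


def _arch_curve(width: float, depth: float):
    """Parabola y = depth*(x/w)^2 - depth with w = width/2, densely
    sampled; returns (x, y, cumulative arc length)."""
    w = width / 2.0
    x = np.linspace(-w, w, 2001)
    y = depth * (x / w) ** 2 - depth
    seg = np.hypot(np.diff(x), np.diff(y))
    s = np.concatenate([[0.0], np.cumsum(seg)])
    return x, y, s


def _point_at_arc(x, y, s, target):
    """Position and unit tangent of the curve at arc length ``target``."""
    px = float(np.interp(target, s, x))
    py = float(np.interp(target, s, y))
    ds = 1e-3 * s[-1]
    ta = np.array([np.interp(min(target + ds, s[-1]), s, x)
                   - np.interp(max(target - ds, 0.0), s, x),
                   np.interp(min(target + ds, s[-1]), s, y)
                   - np.interp(max(target - ds, 0.0), s, y)])
    ta /= np.linalg.norm(ta)
    return np.array([px, py]), ta


def _icosphere_subdivisions(points_per_tooth: int) -> int:
    for sub, count in ((3, 642), (2, 162), (1, 42), (0, 12)):
        if count <= points_per_tooth:
            return sub
    return 0


def generate_arch(config: GeneratorConfig) -> AnnotatedScan:
    """Generate one annotated synthetic arch in the standard pose.

    Teeth are ellipsoid point clusters (triangulated when faces are
    requested) laid out along the arch curve with anterior teeth toward
    -y and occlusal surfaces toward +z; each of the 16 FDI positions
    owns a fixed arc-length slot, so missing teeth leave anatomical
    gaps.  Deterministic for a fixed config and seed.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    labels = config.resolved_labels()
    sequence = fdi.arch_sequence(config.arch).labels

    cx, cy, cs = _arch_curve(config.arch_width_mm, config.arch_depth_mm)
    total = cs[-1]
    widths = np.array([_TOOTH_WIDTH_MM[l % 10][0] for l in sequence])
    slots = widths / widths.sum() * total
    slot_end = np.cumsum(slots)
    slot_centre = slot_end - slots / 2.0

    sphere = trimesh.creation.icosphere(
        subdivisions=_icosphere_subdivisions(config.points_per_tooth),
        radius=1.0)
    unit_vertices = np.asarray(sphere.vertices)
    unit_faces = np.asarray(sphere.faces)

    all_points: List[np.ndarray] = []
    all_faces: List[np.ndarray] = []
    all_instance: List[np.ndarray] = []
    all_fdi: List[np.ndarray] = []
    tooth_base_vertex: List[int] = []   # global index of each tooth's base
    tooth_station: List[float] = []     # arc position of each tooth centre
    offset = 0

    for instance_id, label in enumerate(labels):
        slot_index = sequence.index(label)
        centre2d, tangent = _point_at_arc(cx, cy, cs, slot_centre[slot_index])
        md, bl = _TOOTH_WIDTH_MM[label % 10]
        arch_scale = slots[slot_index] / md
        radii = np.array([_FILL_FACTOR * arch_scale * md / 2.0,
                          arch_scale * bl / 2.0,
                          _CROWN_HEIGHT_MM / 2.0])
        normal2d = np.array([-tangent[1], tangent[0]])
        frame = np.array([
            [tangent[0], normal2d[0], 0.0],
            [tangent[1], normal2d[1], 0.0],
            [0.0, 0.0, 1.0],
        ])
        centre = np.array([centre2d[0], centre2d[1], _CROWN_HEIGHT_MM / 2.0])
        centre = centre + rng.normal(scale=config.centroid_jitter_mm, size=3)
        verts = (unit_vertices * radii) @ frame.T + centre
        all_points.append(verts)
        all_faces.append(unit_faces + offset)
        all_instance.append(np.full(len(verts), instance_id, dtype=np.int64))
        all_fdi.append(np.full(len(verts), label, dtype=np.int64))
        tooth_base_vertex.append(offset + int(np.argmin(verts[:, 2])))
        tooth_station.append(float(slot_centre[slot_index]))
        offset += len(verts)

    # gingiva ribbon: two vertex rows along the whole curve at z = 0
    n_station = max(config.gingiva_points // 2, 2)
    ribbon_start = offset
    stations = np.linspace(0.0, total, n_station)
    rows = []
    for s_val in stations:
        pos, tangent = _point_at_arc(cx, cy, cs, s_val)
        normal2d = np.array([-tangent[1], tangent[0]])
        inner = pos - _RIBBON_HALF_WIDTH_MM * normal2d
        outer = pos + _RIBBON_HALF_WIDTH_MM * normal2d
        rows.append([inner[0], inner[1], 0.0])
        rows.append([outer[0], outer[1], 0.0])
    ribbon = np.array(rows)
    ribbon_faces = []
    for k in range(n_station - 1):
        a, b = ribbon_start + 2 * k, ribbon_start + 2 * k + 1
        c, d = ribbon_start + 2 * (k + 1), ribbon_start + 2 * (k + 1) + 1
        ribbon_faces.extend([[a, b, c], [b, d, c]])
    all_points.append(ribbon)
    all_faces.append(np.array(ribbon_faces, dtype=np.int64))
    all_instance.append(np.full(len(ribbon), -1, dtype=np.int64))
    all_fdi.append(np.zeros(len(ribbon), dtype=np.int64))

    points = np.vstack(all_points)
    faces = np.vstack(all_faces)

    # bridge each tooth base to the concave-side ribbon vertices of the
    # stations directly beneath it, so the face graph has one connected
    # component and a crop that keeps a tooth always keeps its bridge
    # (a clipped neighbour fragment, in contrast, always loses its
    # bridge and is removed by the largest-component rule)
    concave = 0 if np.linalg.norm(ribbon[0][:2]) <= \
        np.linalg.norm(ribbon[1][:2]) else 1
    bridges = []
    for base, station in zip(tooth_base_vertex, tooth_station):
        k = int(np.clip(np.searchsorted(stations, station) - 1,
                        0, n_station - 2))
        v1 = ribbon_start + 2 * k + concave
        v2 = ribbon_start + 2 * (k + 1) + concave
        bridges.append([base, v1, v2])
    faces = np.vstack([faces, np.array(bridges, dtype=np.int64)])

    scan = AnnotatedScan(
        points=points,
        faces=faces if config.with_faces else None,
        vertex_instance=np.concatenate(all_instance),
        vertex_fdi=np.concatenate(all_fdi),
        arch=config.arch,
    )
    return _snap_to_standard(scan)


def _snap_to_standard(scan: AnnotatedScan) -> AnnotatedScan:
    """Put a freshly generated scan exactly into the standard frame.

    Uses the landmark construction when all four landmark teeth are
    present (making the generator/alignment round trip the identity);
    otherwise only recenters on the vertex mean.
    """
    try:
        transform = standard_pose_from_landmarks(scan)
    except LandmarkError:
        out = scan.copy()
        out.points = out.points - out.points.mean(axis=0)
        return out
    out = scan.copy()
    out.points = transform.apply(out.points)
    return out


# -- mock predictor ------------------------------------------------------

_PEAK_LOGIT = 5.0


def _confused_label(label: int, rng: np.random.Generator) -> int:
    """A neighbouring label along the arch sequence (uniform over the
    1 or 2 neighbours)."""
    seq = fdi.arch_sequence(fdi.arch_of(label)).labels
    idx = seq.index(label)
    options = [seq[i] for i in (idx - 1, idx + 1) if 0 <= i < 16]
    return int(options[rng.integers(len(options))])


def perturb_predictions(scan: AnnotatedScan,
                        noise: NoiseConfig) -> PredictedInstances:
    """Turn ground-truth annotations into noisy network-style output.

    One predicted instance per surviving ground-truth tooth (plus
    spurious small instances); logits form a softmax-ready vector with
    peak ``5 / temperature`` at the (possibly confused) label; centroids
    are the member-vertex means perturbed by an isotropic Gaussian.
    Deterministic for a fixed seed.
    """
    noise.validate()
    rng = np.random.default_rng(noise.seed)
    pred_instance = scan.vertex_instance.copy()
    gt_ids = scan.instance_ids()

    dropped = {i for i in gt_ids if rng.random() < noise.drop_rate}
    for inst in dropped:
        pred_instance[scan.vertex_instance == inst] = -1

    if noise.boundary_flip_rate > 0:
        adjacency = vertex_adjacency(scan.points, scan.faces).tocsr()
        flips = []
        for v in range(len(scan.points)):
            mine = pred_instance[v]
            if mine == -1:
                continue
            neighbours = adjacency.indices[
                adjacency.indptr[v]:adjacency.indptr[v + 1]]
            foreign = pred_instance[neighbours]
            foreign = foreign[foreign != mine]
            if len(foreign) and rng.random() < noise.boundary_flip_rate:
                values, counts = np.unique(foreign, return_counts=True)
                flips.append((v, int(values[np.argmax(counts)])))
        for v, target in flips:
            pred_instance[v] = target

    instances: List[PredictedTooth] = []
    next_id = 0
    remap = np.full(max(gt_ids, default=-1) + 2, -1, dtype=np.int64)
    for inst in gt_ids:
        if inst in dropped:
            continue
        members = np.flatnonzero(pred_instance == inst)
        if len(members) == 0:
            continue
        true_label = scan.label_of_instance(inst)
        peak = true_label
        if rng.random() < noise.label_confusion_rate:
            peak = _confused_label(true_label, rng)
        logits = np.zeros(32)
        logits[fdi.ALL_LABELS.index(peak)] = _PEAK_LOGIT
        logits /= noise.logit_temperature
        centroid = scan.points[members].mean(axis=0)
        if noise.centroid_sigma_mm > 0:
            centroid = centroid + rng.normal(scale=noise.centroid_sigma_mm,
                                             size=3)
        instances.append(PredictedTooth(members, centroid, logits,
                                        source_instance=inst))
        remap[inst] = next_id
        next_id += 1

    out_vertex = np.where(pred_instance >= 0, remap[pred_instance], -1)

    n_spurious = int(rng.poisson(noise.spurious_rate))
    arch_labels = fdi.arch_sequence(scan.arch).labels
    for _ in range(n_spurious):
        background = np.flatnonzero(out_vertex == -1)
        if len(background) < 6:
            break
        anchor = scan.points[background[rng.integers(len(background))]]
        dist = np.linalg.norm(scan.points[background] - anchor, axis=1)
        members = background[np.argsort(dist)[:6]]
        out_vertex[members] = next_id
        logits = np.zeros(32)
        peak = arch_labels[rng.integers(16)]
        logits[fdi.ALL_LABELS.index(peak)] = _PEAK_LOGIT
        logits /= noise.logit_temperature
        centroid = scan.points[members].mean(axis=0)
        if noise.centroid_sigma_mm > 0:
            centroid = centroid + rng.normal(scale=noise.centroid_sigma_mm,
                                             size=3)
        instances.append(PredictedTooth(members, centroid, logits,
                                        source_instance=None))
        next_id += 1

    return PredictedInstances(instances, out_vertex)
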