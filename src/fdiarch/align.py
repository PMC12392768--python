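"""Pose standardization for intraoral scans and the alignment losses.

The standard pose is built from dental landmarks: the occlusal plane is
the plane through the two first-molar centroids and the mean centroid of
the central incisors.  A scan in standard pose is centred on the origin
(mean of all vertices), the first-molar centroids differ only in x, the
occlusal-plane normal on the coronal (crown) side points along +z, and
the anterior-posterior axis follows y with the forward direction
``(0, -1, 0)``.  Upper and lower arches end up oriented the same way.

The loss functions (`orient_loss`, `align_loss`) supervise a pose
regressor that predicts forward/up directions, a recentering translation
and an auxiliary binary tooth segmentation; they are pure functions here,
usable by any trainer.  `apply_standardization` is the inference-side
counterpart: it re-applies a predicted pose to bring a scan into the
standard frame, orthonormalizing the predicted directions first.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional, Tuple

import numpy as np

from .errors import LandmarkError, ValidationError
from .scan import AnnotatedScan

_EPS = 1e-7


@dataclass
class PoseParams:
    """Forward/up directions plus translation (all in the scan's frame)."""

    forward: np.ndarray
    up: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        self.forward = np.asarray(self.forward, dtype=np.float64)
        self.up = np.asarray(self.up, dtype=np.float64)
        self.translation = np.asarray(self.translation, dtype=np.float64)


#: the pose of a scan that is already in the standard frame
STANDARD_POSE = PoseParams(
    forward=np.array([0.0, -1.0, 0.0]),
    up=np.array([0.0, 0.0, 1.0]),
    translation=np.zeros(3),
)


@dataclass
class RigidTransform:
    """Proper rigid motion ``p -> R @ p + t``."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        self.rotation = np.asarray(self.rotation, dtype=np.float64)
        self.translation = np.asarray(self.translation, dtype=np.float64)
        if not np.allclose(self.rotation @ self.rotation.T, np.eye(3),
                           atol=1e-9):
            raise ValidationError("rotation must be orthonormal")
        if not np.isclose(np.linalg.det(self.rotation), 1.0, atol=1e-9):
            raise ValidationError("rotation must be proper (det = +1)")

    def apply(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points) @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """self after other: (self o other)(p) = self(other(p))."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    @staticmethod
    def identity() -> "RigidTransform":
        return RigidTransform(np.eye(3), np.zeros(3))


def _unit(v: np.ndarray) -> np.ndarray:
    norm = np.linalg.norm(v)
    if norm < _EPS:
        raise ValidationError("zero-length direction vector")
    return v / norm


_LANDMARKS = {
    "upper": {"molars": (16, 26), "incisors": (11, 21)},
    "lower": {"molars": (46, 36), "incisors": (41, 31)},
}


def standard_pose_from_landmarks(scan: AnnotatedScan) -> RigidTransform:
    """Transform taking ``scan`` into the standard frame.

    Requires both first molars and both central incisors.  The molar on
    the patient-right side (quadrant 1 or 4) maps to negative x, the
    occlusal-plane normal on the coronal side to +z, and the scan is
    centred on the mean of all its vertices.
    """
    marks = _LANDMARKS[scan.arch]
    present = set(scan.present_labels())
    missing = [l for l in marks["molars"] + marks["incisors"]
               if l not in present]
    if missing:
        raise LandmarkError(
            f"landmark teeth {missing} missing; both first molars and both "
            "central incisors are required for the standard pose"
        )
    right_molar = scan.centroid_of_label(marks["molars"][0])
    left_molar = scan.centroid_of_label(marks["molars"][1])
    incisor_mean = 0.5 * (scan.centroid_of_label(marks["incisors"][0])
                          + scan.centroid_of_label(marks["incisors"][1]))

    x_axis = _unit(left_molar - right_molar)
    normal = np.cross(left_molar - right_molar, incisor_mean - right_molar)
    if np.linalg.norm(normal) < _EPS:
        raise LandmarkError("landmark centroids are collinear")
    z_axis = _unit(normal)
    z_axis = _coronal_side(scan, z_axis)
    # molars and incisors all lie in the occlusal plane, so z is exactly
    # orthogonal to x; y completes the right-handed frame
    y_axis = np.cross(z_axis, x_axis)
    rotation = np.vstack([x_axis, y_axis, z_axis])
    centre = scan.points.mean(axis=0)
    return RigidTransform(rotation, -rotation @ centre)


def _coronal_side(scan: AnnotatedScan, normal: np.ndarray) -> np.ndarray:
    """Orient the occlusal normal toward the crowns.

    The crowns lie on the opposite side of the occlusal plane from the
    gingiva, so the normal is flipped to point from the gingiva centroid
    toward the tooth centroid.  Without gingiva vertices the overall
    vertex mean is the reference (tooth crowns protrude past it).
    """
    tooth_mask = scan.vertex_instance != -1
    tooth_centre = scan.points[tooth_mask].mean(axis=0)
    if (~tooth_mask).any():
        reference = scan.points[~tooth_mask].mean(axis=0)
    else:
        reference = scan.points.mean(axis=0)
    direction = tooth_centre - reference
    if abs(float(direction @ normal)) < _EPS:
        return normal
    return normal if float(direction @ normal) > 0 else -normal


def pca_rough_align(points: np.ndarray) -> RigidTransform:
    """PCA pose normalization: principal axes -> x, y, z by variance.

    Sign convention: each axis is flipped so the coordinate skewness
    along it is nonnegative (near-zero skewness: largest-magnitude
    loading made positive); the determinant is then corrected to +1 by
    flipping the last axis.  Deterministic for any non-degenerate input.
    """
    points = np.asarray(points, dtype=np.float64)
    if len(points) < 3:
        raise ValidationError("need at least 3 points for PCA alignment")
    centre = points.mean(axis=0)
    centred = points - centre
    cov = centred.T @ centred / len(points)
    eigval, eigvec = np.linalg.eigh(cov)
    if eigval[0] < 0 or eigval[-1] < _EPS or np.linalg.matrix_rank(cov) < 2:
        raise ValidationError("degenerate covariance: points are collinear")
    order = np.argsort(eigval)[::-1]
    axes = eigvec[:, order].T           # rows: descending variance
    for k in range(3):
        coords = centred @ axes[k]
        skew = float(np.mean(coords ** 3))
        if abs(skew) > 1e-12:
            if skew < 0:
                axes[k] = -axes[k]
        elif axes[k][int(np.argmax(np.abs(axes[k])))] < 0:
            axes[k] = -axes[k]
    if np.linalg.det(axes) < 0:
        axes[2] = -axes[2]
    return RigidTransform(axes, -axes @ centre)


def _cos(a: np.ndarray, b: np.ndarray) -> float:
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na < _EPS or nb < _EPS:
        raise ValidationError("zero-length direction vector")
    return float(a @ b / (na * nb))


def orient_loss(truth: PoseParams, pred: PoseParams) -> float:
    """Direction loss: 2 - cos(f', f^) - cos(u', u^) + |cos(f^, u^)|.

    Rewards predicted forward/up directions parallel to the ground truth
    and penalizes non-orthogonal predictions; invariant to positive
    rescaling of the predictions.  Zero iff the predictions are parallel
    to the (orthonormal) truth and mutually orthogonal.
    """
    return (2.0
            - _cos(truth.forward, pred.forward)
            - _cos(truth.up, pred.up)
            + abs(_cos(pred.forward, pred.up)))


def smooth_l1(truth: np.ndarray, pred: np.ndarray, beta: float = 1.0) -> float:
    """Elementwise smooth-L1 (Huber) with mean reduction."""
    diff = np.abs(np.asarray(truth, dtype=np.float64)
                  - np.asarray(pred, dtype=np.float64))
    per = np.where(diff < beta, 0.5 * diff ** 2 / beta, diff - 0.5 * beta)
    return float(per.mean())


def bce_loss(truth: np.ndarray, pred: np.ndarray) -> float:
    """Binary cross-entropy, mean over vertices, scores clamped at 1e-7."""
    t = np.asarray(truth, dtype=np.float64)
    p = np.clip(np.asarray(pred, dtype=np.float64), _EPS, 1.0 - _EPS)
    return float(-(t * np.log(p) + (1 - t) * np.log(1 - p)).mean())


def dice_loss(truth: np.ndarray, pred: np.ndarray,
              smooth: float = 1e-6) -> float:
    """1 - soft Dice with additive smoothing."""
    t = np.asarray(truth, dtype=np.float64)
    p = np.asarray(pred, dtype=np.float64)
    inter = float((t * p).sum())
    return 1.0 - (2.0 * inter + smooth) / (float(t.sum() + p.sum()) + smooth)


def align_loss(truth: PoseParams, pred: PoseParams,
               seg_truth: np.ndarray, seg_pred: np.ndarray,
               ) -> Tuple[float, Dict[str, float]]:
    """Total alignment loss and its per-term breakdown.

    total = orient + smooth-L1(c', c^) + BCE(s', s^) + Dice(s', s^).
    """
    seg_truth = np.asarray(seg_truth, dtype=np.float64)
    seg_pred = np.asarray(seg_pred, dtype=np.float64)
    if seg_truth.shape != seg_pred.shape:
        raise ValidationError("segmentation arrays must have equal length")
    terms = {
        "orient": orient_loss(truth, pred),
        "smooth_l1": smooth_l1(truth.translation, pred.translation),
        "bce": bce_loss(seg_truth, seg_pred),
        "dice": dice_loss(seg_truth, seg_pred),
    }
    return float(sum(terms.values())), terms


def standardization_basis(pred: PoseParams) -> np.ndarray:
    """Orthonormal right-handed basis (rows) from predicted directions.

    The up direction is kept, the forward direction is Gram-Schmidt
    orthogonalized against it, and the left-right axis is their cross
    product, oriented so the basis is right-handed with forward -> -y
    and up -> +z.
    """
    up = _unit(pred.up)
    forward = np.asarray(pred.forward, dtype=np.float64)
    forward = forward - (forward @ up) * up
    if np.linalg.norm(forward) < _EPS:
        raise ValidationError("forward and up directions are parallel")
    forward = _unit(forward)
    x_axis = np.cross(up, forward)
    return np.vstack([x_axis, -forward, up])


def apply_standardization(points: np.ndarray, pred: PoseParams) -> np.ndarray:
    """Bring points into the standard frame using a predicted pose.

    The predicted translation is applied in reverse, then the
    orthonormalized (left-right, forward, up) basis rotates the point
    set so forward maps to (0, -1, 0) and up to (0, 0, 1).
    """
    basis = standardization_basis(pred)
    return (np.asarray(points, dtype=np.float64) - pred.translation) @ basis.T


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Rotation matrix uniform over SO(3) via quaternion sampling."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])
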