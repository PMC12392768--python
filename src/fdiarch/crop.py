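"""Artificial partial-arch augmentation.

A full-arch scan is turned into a convincing partial-arch scan in four
steps: pick 2-12 consecutive teeth along the arch sequence, crop the
surface with an oriented bounding box around the selected teeth, keep
only the largest connected surface inside the box, and recenter the
result at the origin.  The augmentation is applied with probability 0.9
and the tooth count is drawn from a distribution skewed toward fewer
teeth (truncated geometric by default).  The translation that recenters
the crop is recorded — it is the ground-truth target c' the alignment
stage regresses.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional

import numpy as np

from . import fdi
from .errors import ValidationError
from .scan import AnnotatedScan, connected_components


def truncated_geometric(min_teeth: int = 2, max_teeth: int = 12,
                        ratio: float = 0.75) -> Dict[int, float]:
    """P(n) proportional to ratio**(n - min) on {min..max}: monotonically
    decreasing mass, i.e. fewer teeth are more likely."""
    support = np.arange(min_teeth, max_teeth + 1)
    weights = ratio ** (support - min_teeth)
    weights = weights / weights.sum()
    return {int(n): float(w) for n, w in zip(support, weights)}


@dataclass
class CropConfig:
    apply_probability: float = 0.9
    min_teeth: int = 2
    max_teeth: int = 12
    count_distribution: Optional[Dict[int, float]] = None
    box_margin_mm: float = 2.0
    seed: int = 0

    def resolved_distribution(self) -> Dict[int, float]:
        dist = self.count_distribution
        if dist is None:
            dist = truncated_geometric(self.min_teeth, self.max_teeth)
        total = sum(dist.values())
        if not np.isclose(total, 1.0):
            raise ValidationError("count_distribution must sum to 1")
        for n in dist:
            if not self.min_teeth <= n <= self.max_teeth:
                raise ValidationError(
                    f"count {n} outside [{self.min_teeth}, {self.max_teeth}]")
        return dist

    def validate(self) -> None:
        if not 0.0 <= self.apply_probability <= 1.0:
            raise ValidationError("apply_probability must lie in [0, 1]")
        if self.min_teeth < 1 or self.max_teeth < self.min_teeth:
            raise ValidationError("need 1 <= min_teeth <= max_teeth")
        if self.box_margin_mm < 0:
            raise ValidationError("box_margin_mm must be nonnegative")
        self.resolved_distribution()


@dataclass
class CropResult:
    scan: AnnotatedScan
    selected_labels: List[int]
    applied: bool
    translation_target: np.ndarray   # c', the recentering translation


def select_segment(scan: AnnotatedScan, config: CropConfig,
                   rng: np.random.Generator) -> List[int]:
    """Labels of a contiguous run of the scan's present-tooth sequence.

    The run length is drawn from the configured count distribution and
    clipped to the number of available teeth; the start position is
    uniform over feasible offsets.
    """
    config.validate()
    present = scan.present_labels()
    if len(present) < config.min_teeth:
        raise ValidationError(
            f"scan has {len(present)} teeth; at least {config.min_teeth} "
            "are needed for a crop")
    dist = config.resolved_distribution()
    counts = np.array(sorted(dist))
    probs = np.array([dist[int(n)] for n in counts])
    count = int(rng.choice(counts, p=probs))
    count = min(count, len(present))
    start = int(rng.integers(len(present) - count + 1))
    return present[start:start + count]


def _oriented_box_mask(points: np.ndarray, selected_points: np.ndarray,
                       margin: float) -> np.ndarray:
    """Vertices inside the oriented bounding box of the selected teeth's
    vertices, padded by ``margin`` on every side.

    The box is upright: its horizontal axes are the principal axes of
    the selected vertices' xy coordinates and its third axis is z.
    Scans are standardized (occlusal toward +z), so an upright box
    follows the arch segment without tilting into the gingiva."""
    centre = selected_points.mean(axis=0)
    centred = selected_points - centre
    xy = centred[:, :2]
    cov = xy.T @ xy / len(xy)
    _, eigvec = np.linalg.eigh(cov)
    axes = np.eye(3)
    axes[0, :2] = eigvec[:, 1]     # along-arch (largest xy variance)
    axes[1, :2] = eigvec[:, 0]
    local = centred @ axes.T
    lo = local.min(axis=0) - margin
    hi = local.max(axis=0) + margin
    all_local = (points - centre) @ axes.T
    return np.all((all_local >= lo) & (all_local <= hi), axis=1)


def crop_to_segment(scan: AnnotatedScan, selected: List[int],
                    config: CropConfig) -> CropResult:
    """Crop to the oriented bounding box of the selected teeth, keep the
    largest connected surface, recenter at the origin."""
    if not selected:
        raise ValidationError("empty tooth selection")
    present = set(scan.present_labels())
    missing = [l for l in selected if l not in present]
    if missing:
        raise ValidationError(f"selected teeth {missing} not present in scan")

    tooth_mask = np.isin(scan.vertex_fdi, selected)
    inside = _oriented_box_mask(scan.points, scan.points[tooth_mask],
                                config.box_margin_mm)
    if not inside.any():
        raise ValidationError("crop produced an empty surface")
    cropped = scan.subset(inside)

    components = connected_components(cropped.points, cropped.faces)
    sizes = np.bincount(components)
    largest = np.flatnonzero(sizes == sizes.max())
    if len(largest) > 1:
        # tie: keep the component whose centroid is nearest the teeth
        target = scan.points[tooth_mask].mean(axis=0)
        dists = [np.linalg.norm(cropped.points[components == c].mean(axis=0)
                                - target) for c in largest]
        keep_component = int(largest[int(np.argmin(dists))])
    else:
        keep_component = int(largest[0])
    cropped = cropped.subset(components == keep_component)

    translation = -cropped.points.mean(axis=0)
    cropped.points = cropped.points + translation
    return CropResult(cropped, list(selected), True, translation)


def maybe_crop(scan: AnnotatedScan, config: CropConfig,
               rng: np.random.Generator) -> CropResult:
    """Apply the crop augmentation with the configured probability."""
    config.validate()
    if rng.random() < config.apply_probability:
        selected = select_segment(scan, config, rng)
        return crop_to_segment(scan, selected, config)
    return CropResult(scan, scan.present_labels(), False, np.zeros(3))
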