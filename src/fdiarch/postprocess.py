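"""FDI relabeling by minimum-cost sequence dynamic programming.

Given predicted tooth instances (centroids + 32-class logits) in the
standard frame, the postprocessor

1. orders the teeth along the dental arch (start at the most posterior
   centroid, then repeatedly append the unvisited centroid whose
   direction from the origin makes the smallest angle with the last
   appended one),
2. turns per-tooth class logits into unary costs (-log softmax over the
   selected arch's 16 labels),
3. turns centroid offsets between consecutive teeth into pairwise costs
   (-log density under a per-label-pair multivariate Gaussian prior
   learned from annotated scans), and
4. solves for the minimum-cost FDI label sequence with a forward
   dynamic program over the 16 arch labels, recording predecessors for
   backtracking.

The Gaussian prior is anatomical: the offset between, say, 11 and 21 is
a tight distribution in the standard frame.  Offsets are mirrored
across the midline (x negated, labels reflected) to double the sample
count, and same-FDI offsets — centroid offsets between disconnected
components of a single annotated tooth — are pooled per arch and shared
by every (i, i) pair, so the dynamic program can keep two fragments of
one tooth on the same label.  Repeated labels are therefore allowed in
the optimal sequence.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from . import fdi
from .errors import ValidationError
from .scan import AnnotatedScan, PredictedInstances, connected_components

_LOG_2PI = float(np.log(2.0 * np.pi))


@dataclass
class ToothOrdering:
    order: List[int]                 # permutation of instance indices
    direction: str = "unknown"       # left-to-right | right-to-left | unknown


@dataclass
class CostTables:
    """Unary (T x 16) and pairwise ((T-1) x 16 x 16) label costs.

    Column order is the canonical arch sequence of ``arch``; all
    entries are finite (a fallback replaces unobserved pairs).
    """

    arch: str
    unary: np.ndarray
    pairwise: np.ndarray

    def __post_init__(self) -> None:
        self.unary = np.asarray(self.unary, dtype=np.float64)
        self.pairwise = np.asarray(self.pairwise, dtype=np.float64)
        t = len(self.unary)
        if self.unary.shape != (t, 16):
            raise ValidationError("unary table must be T x 16")
        if self.pairwise.shape != (max(t - 1, 0), 16, 16):
            raise ValidationError("pairwise table must be (T-1) x 16 x 16")
        if not (np.isfinite(self.unary).all()
                and np.isfinite(self.pairwise).all()):
            raise ValidationError("cost tables must be finite")


@dataclass
class LabelAssignment:
    labels: List[int]                # one FDI label per instance
    total_cost: float
    predecessors: Optional[np.ndarray] = None   # (T-1, 16) DP argmins
    ordering: Optional[ToothOrdering] = None
    arch: Optional[str] = None


# -- step 1: tooth ordering ---------------------------------------------


def order_teeth(centroids: np.ndarray) -> ToothOrdering:
    """Sequence teeth along the arch from the most posterior one.

    The first tooth is the centroid with maximum y (ties: maximum x);
    each subsequent tooth is the unvisited centroid whose xy-direction
    from the origin has maximum cosine similarity to that of the last
    appended one.  Works for full and partial arches in the standard
    frame (posterior toward +y, arch centred on the origin).
    """
    centroids = np.asarray(centroids, dtype=np.float64)
    if centroids.ndim != 2 or centroids.shape[1] != 3 or len(centroids) == 0:
        raise ValidationError("need a nonempty (T, 3) centroid array")
    xy = centroids[:, :2]
    norms = np.linalg.norm(xy, axis=1)
    directions = np.divide(xy, norms[:, None],
                           out=np.zeros_like(xy),
                           where=norms[:, None] > 1e-12)

    start = int(np.lexsort((centroids[:, 0], centroids[:, 1]))[-1])
    order = [start]
    remaining = set(range(len(centroids))) - {start}
    while remaining:
        last = directions[order[-1]]
        candidates = sorted(remaining)
        cosines = [float(directions[c] @ last) for c in candidates]
        best = candidates[int(np.argmax(cosines))]
        order.append(best)
        remaining.discard(best)

    if len(order) > 1:
        trend = centroids[order[-1], 0] - centroids[order[0], 0]
        direction = ("left-to-right" if trend > 0
                     else "right-to-left" if trend < 0 else "unknown")
    else:
        direction = "unknown"
    return ToothOrdering(order, direction)


# -- step 2: unary costs -------------------------------------------------


def _softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def select_arch(instances: PredictedInstances) -> str:
    """Pick upper vs lower by total softmax probability mass (ties: upper)."""
    logits = instances.logit_matrix()
    if len(logits) == 0:
        raise ValidationError("no predicted instances")
    if not np.isfinite(logits).all():
        raise ValidationError("logits must be finite")
    probs = _softmax(logits)
    upper_mass = float(probs[:, :16].sum())
    lower_mass = float(probs[:, 16:].sum())
    return fdi.UPPER if upper_mass >= lower_mass else fdi.LOWER


def unary_costs(instances: PredictedInstances, arch: str,
                ordering: ToothOrdering) -> np.ndarray:
    """-log softmax over the selected arch's 16 labels, rows in
    ordering-sequence position, columns in canonical arch order."""
    logits = instances.logit_matrix()
    if not np.isfinite(logits).all():
        raise ValidationError("logits must be finite")
    arch_slice = slice(0, 16) if arch == fdi.UPPER else slice(16, 32)
    restricted = logits[np.array(ordering.order)][:, arch_slice]
    probs = _softmax(restricted)
    # clamp underflowed probabilities so costs stay finite
    return -np.log(np.clip(probs, np.finfo(np.float64).tiny, None))


# -- step 3: Gaussian offset prior ---------------------------------------


@dataclass
class _FittedPair:
    mu: np.ndarray
    sigma: np.ndarray
    k: int
    inv: np.ndarray = field(init=False)
    logdet: float = field(init=False)

    def __post_init__(self) -> None:
        self.inv = np.linalg.inv(self.sigma)
        sign, logdet = np.linalg.slogdet(self.sigma)
        if sign <= 0:
            raise ValidationError("covariance not positive definite")
        self.logdet = float(logdet)

    def neg_log_density(self, delta: np.ndarray) -> float:
        d = np.asarray(delta, dtype=np.float64) - self.mu
        return 0.5 * (3.0 * _LOG_2PI + self.logdet + float(d @ self.inv @ d))


@dataclass
class OffsetModel:
    """Per-FDI-pair centroid-offset statistics.

    Unfitted: raw offset lists per ordered label pair plus the per-arch
    pooled same-FDI offsets.  After :func:`fit_offset_model`: a mean
    and ridge-regularized covariance per pair with at least one sample;
    pairs never observed fall back to the pooled-arch density floored
    at ``fallback_floor``.
    """

    offsets: Dict[Tuple[int, int], List[np.ndarray]] = field(
        default_factory=dict)
    same_fdi: Dict[str, List[np.ndarray]] = field(
        default_factory=lambda: {fdi.UPPER: [], fdi.LOWER: []})
    ridge: float = 0.01               # mm^2, added to every covariance
    fallback_floor: float = 50.0
    shrink_threshold: int = 4         # pairs with fewer samples shrink
    fitted: Dict[Tuple[int, int], _FittedPair] = field(default_factory=dict)
    pooled: Dict[str, Optional[_FittedPair]] = field(
        default_factory=lambda: {fdi.UPPER: None, fdi.LOWER: None})

    def add_offset(self, pair: Tuple[int, int], offset: np.ndarray) -> None:
        self.offsets.setdefault(pair, []).append(
            np.asarray(offset, dtype=np.float64))

    def pair_samples(self, pair: Tuple[int, int]) -> List[np.ndarray]:
        i, j = pair
        if i == j:
            return self.same_fdi[fdi.arch_of(i)]
        return self.offsets.get(pair, [])

    def is_fitted(self, pair: Tuple[int, int]) -> bool:
        return pair in self.fitted

    def pair_cost(self, pair: Tuple[int, int], delta: np.ndarray) -> float:
        """-log Gaussian density of the observed offset under the pair's
        model, or the pooled/floored fallback for unobserved pairs."""
        if pair in self.fitted:
            return self.fitted[pair].neg_log_density(delta)
        pooled = self.pooled[fdi.arch_of(pair[0])]
        if pooled is None:
            return self.fallback_floor
        return max(pooled.neg_log_density(delta), self.fallback_floor)

    # -- serialization --------------------------------------------------

    def to_json(self) -> str:
        pairs = {}
        for (i, j), fit in sorted(self.fitted.items()):
            pairs[f"{i}-{j}"] = {
                "mu": fit.mu.tolist(),
                "sigma": fit.sigma.tolist(),
                "k": fit.k,
            }
        pooled = {
            arch: None if fit is None else {
                "mu": fit.mu.tolist(), "sigma": fit.sigma.tolist(),
                "k": fit.k}
            for arch, fit in self.pooled.items()
        }
        return json.dumps({
            "arch_pairs": pairs,
            "pooled": pooled,
            "ridge": self.ridge,
            "fallback_cost": self.fallback_floor,
        }, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "OffsetModel":
        data = json.loads(text)
        model = cls(ridge=data["ridge"], fallback_floor=data["fallback_cost"])
        for key, entry in data["arch_pairs"].items():
            i, j = (int(p) for p in key.split("-"))
            model.fitted[(i, j)] = _FittedPair(
                np.array(entry["mu"]), np.array(entry["sigma"]),
                int(entry["k"]))
        for arch, entry in data.get("pooled", {}).items():
            if entry is not None:
                model.pooled[arch] = _FittedPair(
                    np.array(entry["mu"]), np.array(entry["sigma"]),
                    int(entry["k"]))
        return model


def _mirror_offset(offset: np.ndarray) -> np.ndarray:
    return offset * np.array([-1.0, 1.0, 1.0])


def collect_offsets(scans: Sequence[AnnotatedScan],
                    model: Optional[OffsetModel] = None) -> OffsetModel:
    """Collect centroid offsets from annotated scans in standard pose.

    For every ordered pair of co-occurring labels the offset
    centroid(j) - centroid(i) is stored under (i, j) and its mirror
    (x negated) under the reflected pair.  Disconnected components of a
    single annotated tooth contribute same-FDI offsets, pooled per arch
    and shared by every (i, i) pair of that arch.
    """
    if model is None:
        model = OffsetModel()
    for scan in scans:
        labels = scan.present_labels()
        centroids = {l: scan.centroid_of_label(l) for l in labels}
        for a in labels:
            for b in labels:
                if a == b:
                    continue
                offset = centroids[b] - centroids[a]
                model.add_offset((a, b), offset)
                model.add_offset((fdi.mirror_fdi(a), fdi.mirror_fdi(b)),
                                 _mirror_offset(offset))
        for label in labels:
            mask = scan.vertex_fdi == label
            pts = scan.points[mask]
            faces = None
            if scan.faces is not None:
                keep = np.flatnonzero(mask)
                index_map = -np.ones(len(scan.points), dtype=np.int64)
                index_map[keep] = np.arange(len(keep))
                face_ok = mask[scan.faces].all(axis=1)
                faces = index_map[scan.faces[face_ok]]
            comp = connected_components(pts, faces)
            n_comp = comp.max() + 1 if len(comp) else 0
            if n_comp < 2:
                continue
            comp_centroids = [pts[comp == c].mean(axis=0)
                              for c in range(n_comp)]
            for a in range(n_comp):
                for b in range(n_comp):
                    if a == b:
                        continue
                    offset = comp_centroids[b] - comp_centroids[a]
                    model.same_fdi[scan.arch].append(offset)
                    model.same_fdi[scan.arch].append(_mirror_offset(offset))
    return model


def fit_offset_model(model: OffsetModel,
                     ridge: Optional[float] = None) -> OffsetModel:
    """Fit a multivariate Gaussian N(mu, Sigma) per offset set.

    mu is the sample mean and Sigma the maximum-likelihood covariance
    (divide by k) plus ``ridge`` times the identity; pairs with fewer
    than ``shrink_threshold`` samples blend their covariance with the
    pooled within-arch covariance first.  Pairs with no samples are
    left unfitted and use the fallback cost.
    """
    if ridge is not None:
        if ridge < 0:
            raise ValidationError("ridge must be nonnegative")
        model.ridge = ridge
    model.fitted = {}
    pooled_cov: Dict[str, Optional[np.ndarray]] = {}
    for arch in (fdi.UPPER, fdi.LOWER):
        arch_labels = set(fdi.arch_sequence(arch).labels)
        pool = [o for (i, _), lst in model.offsets.items()
                if i in arch_labels for o in lst]
        pool.extend(model.same_fdi[arch])
        if pool:
            arr = np.array(pool)
            mu = arr.mean(axis=0)
            centred = arr - mu
            cov = centred.T @ centred / len(arr)
            pooled_cov[arch] = cov
            model.pooled[arch] = _FittedPair(
                mu, cov + model.ridge * np.eye(3), len(arr))
        else:
            pooled_cov[arch] = None
            model.pooled[arch] = None

    for arch in (fdi.UPPER, fdi.LOWER):
        seq = fdi.arch_sequence(arch).labels
        for i in seq:
            for j in seq:
                samples = model.pair_samples((i, j))
                k = len(samples)
                if k == 0:
                    continue
                arr = np.array(samples)
                mu = arr.mean(axis=0)
                centred = arr - mu
                cov = centred.T @ centred / k
                if k < model.shrink_threshold and pooled_cov[arch] is not None:
                    lam = k / model.shrink_threshold
                    cov = lam * cov + (1.0 - lam) * pooled_cov[arch]
                sigma = cov + model.ridge * np.eye(3)
                model.fitted[(i, j)] = _FittedPair(mu, sigma, k)
    return model


def pair_costs(centroids: np.ndarray, ordering: ToothOrdering,
               model: OffsetModel, arch: str) -> np.ndarray:
    """(T-1) x 16 x 16 pairwise costs for consecutive teeth.

    Entry [t, i, j] is the -log Gaussian density of the observed offset
    centroid(t+1) - centroid(t) under the prior for labelling tooth t
    as arch label i and tooth t+1 as label j.
    """
    centroids = np.asarray(centroids, dtype=np.float64)
    seq = fdi.arch_sequence(arch).labels
    t_count = len(ordering.order)
    costs = np.empty((max(t_count - 1, 0), 16, 16))
    for t in range(t_count - 1):
        delta = (centroids[ordering.order[t + 1]]
                 - centroids[ordering.order[t]])
        for a, label_i in enumerate(seq):
            for b, label_j in enumerate(seq):
                costs[t, a, b] = model.pair_cost((label_i, label_j), delta)
    return costs


# -- step 4: minimum-cost sequence DP ------------------------------------


def optimal_fdi_sequence(costs: CostTables) -> LabelAssignment:
    """Minimum-cost label sequence by forward dynamic programming.

    Minimizes sum_t unary[t, l_t] + sum_t pairwise[t, l_t, l_{t+1}] over
    all 16^T label sequences in O(T * 16^2); repeated labels are
    permitted.  Ties break toward the lower canonical label index.
    """
    t_count = len(costs.unary)
    if t_count == 0:
        raise ValidationError("empty cost tables")
    seq = fdi.arch_sequence(costs.arch).labels
    best = costs.unary[0].copy()
    predecessors = np.zeros((t_count - 1, 16), dtype=np.int64)
    for t in range(1, t_count):
        through = best[:, None] + costs.pairwise[t - 1]
        predecessors[t - 1] = np.argmin(through, axis=0)
        best = through.min(axis=0) + costs.unary[t]
    final = int(np.argmin(best))
    total = float(best[final])
    indices = [final]
    for t in range(t_count - 2, -1, -1):
        indices.append(int(predecessors[t, indices[-1]]))
    indices.reverse()
    return LabelAssignment(
        labels=[seq[i] for i in indices],
        total_cost=total,
        predecessors=predecessors if t_count > 1 else None,
        arch=costs.arch,
    )


def relabel(instances: PredictedInstances,
            model: OffsetModel) -> LabelAssignment:
    """Full postprocessing: arch selection, ordering, costs, DP.

    Returns one FDI label per predicted instance in the original
    instance indexing.
    """
    arch = select_arch(instances)
    centroids = instances.centroids()
    ordering = order_teeth(centroids)
    unary = unary_costs(instances, arch, ordering)
    pairwise = pair_costs(centroids, ordering, model, arch)
    assignment = optimal_fdi_sequence(CostTables(arch, unary, pairwise))
    by_instance = [0] * len(ordering.order)
    for position, instance_index in enumerate(ordering.order):
        by_instance[instance_index] = assignment.labels[position]
    return LabelAssignment(
        labels=by_instance,
        total_cost=assignment.total_cost,
        predecessors=assignment.predecessors,
        ordering=ordering,
        arch=arch,
    )
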