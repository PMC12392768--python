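import itertools

import numpy as np
import pytest

from fdiarch import fdi, postprocess, synthetic
from fdiarch.errors import ValidationError
from fdiarch.postprocess import (CostTables, OffsetModel, _FittedPair,
                                 collect_offsets, fit_offset_model,
                                 optimal_fdi_sequence, order_teeth,
                                 pair_costs, relabel, select_arch,
                                 unary_costs)
from fdiarch.scan import AnnotatedScan, PredictedInstances, PredictedTooth


def brute_force_sequence(unary, pairwise):
    """Exhaustive minimum over all 16^T label sequences (the DP oracle)."""
    t = len(unary)
    best_cost, best_labels = np.inf, None
    for labels in itertools.product(range(16), repeat=t):
        cost = sum(unary[i][labels[i]] for i in range(t))
        cost += sum(pairwise[i][labels[i]][labels[i + 1]]
                    for i in range(t - 1))
        if cost < best_cost - 1e-12:
            best_cost, best_labels = cost, labels
    return best_cost, best_labels


def _mock(centroids, logits):
    teeth = [PredictedTooth(np.array([i]), c, l)
             for i, (c, l) in enumerate(zip(centroids, logits))]
    return PredictedInstances(teeth, np.arange(len(teeth)))


def _peaked(label, height=5.0):
    logits = np.zeros(32)
    logits[fdi.ALL_LABELS.index(label)] = height
    return logits


# -- ordering ------------------------------------------------------------


def test_order_single_tooth():
    ordering = order_teeth(np.array([[1.0, 2.0, 3.0]]))
    assert ordering.order == [0]


def test_order_rejects_empty():
    with pytest.raises(ValidationError):
        order_teeth(np.zeros((0, 3)))


def test_order_matches_polar_angle_sort(upper_scan, lower_scan):
    """On generated arches the greedy cosine ordering equals sorting the
    centroids by xy polar angle."""
    for scan in (upper_scan, lower_scan):
        centroids = np.array([scan.centroid_of_instance(i)
                              for i in scan.instance_ids()])
        ordering = order_teeth(centroids)
        assert ordering.order[0] == int(
            np.lexsort((centroids[:, 0], centroids[:, 1]))[-1])
        angles = np.unwrap(np.arctan2(centroids[:, 1], centroids[:, 0]))
        by_angle = list(np.argsort(angles))
        assert ordering.order in (by_angle, by_angle[::-1])


def test_order_starts_most_posterior(upper_scan):
    rng = np.random.default_rng(0)
    centroids = np.array([upper_scan.centroid_of_instance(i)
                          for i in upper_scan.instance_ids()])
    for _ in range(10):
        perm = rng.permutation(len(centroids))
        ordering = order_teeth(centroids[perm])
        assert centroids[perm][ordering.order[0], 1] == centroids[:, 1].max()


# -- arch selection and unary costs --------------------------------------


def test_select_arch_pure_cases():
    upper = _mock(np.zeros((2, 3)), [_peaked(11), _peaked(26)])
    lower = _mock(np.zeros((2, 3)), [_peaked(36), _peaked(41)])
    assert select_arch(upper) == "upper"
    assert select_arch(lower) == "lower"


def test_select_arch_equals_mass_comparison():
    rng = np.random.default_rng(4)
    for _ in range(20):
        logits = rng.normal(size=(5, 32))
        pred = _mock(np.zeros((5, 3)), logits)
        probs = np.exp(logits) / np.exp(logits).sum(axis=1, keepdims=True)
        expected = ("upper" if probs[:, :16].sum() >= probs[:, 16:].sum()
                    else "lower")
        assert select_arch(pred) == expected


def test_unary_costs_uniform_logits():
    pred = _mock(np.zeros((3, 3)), [np.zeros(32)] * 3)
    ordering = order_teeth(np.arange(9.0).reshape(3, 3))
    costs = unary_costs(pred, "upper", ordering)
    assert costs.shape == (3, 16)
    assert np.allclose(costs, np.log(16.0))


def test_unary_costs_saturate_on_dominant_logit():
    logits = np.zeros(32)
    logits[fdi.UPPER_SEQUENCE.index(14)] = 1e3
    pred = _mock(np.zeros((1, 3)), [logits])
    costs = unary_costs(pred, "upper", order_teeth(np.zeros((1, 3))))
    assert costs[0, fdi.UPPER_SEQUENCE.index(14)] == pytest.approx(0.0,
                                                                   abs=1e-6)
    assert (np.delete(costs[0], fdi.UPPER_SEQUENCE.index(14)) > 100).all()


def test_unary_costs_rows_are_normalized():
    rng = np.random.default_rng(7)
    logits = rng.normal(scale=3.0, size=(6, 32))
    pred = _mock(rng.normal(size=(6, 3)), logits)
    costs = unary_costs(pred, "lower", order_teeth(rng.normal(size=(6, 3))))
    assert np.allclose(np.exp(-costs).sum(axis=1), 1.0, atol=1e-9)


# -- offset collection and fitting ---------------------------------------


def _point_scan(label_points, arch):
    """Scan with one vertex cluster per (label, points) entry."""
    points, instances, labels = [], [], []
    for idx, (label, pts) in enumerate(label_points):
        for p in pts:
            points.append(p)
            instances.append(idx)
            labels.append(label)
    return AnnotatedScan(np.array(points, float), None,
                         np.array(instances), np.array(labels), arch)


def test_collect_offsets_subtraction_and_mirroring():
    scan = _point_scan([(11, [[-5.0, -20.0, 0.0]]),
                        (21, [[5.0, -20.0, 0.0]])], "upper")
    model = collect_offsets([scan])
    direct = model.offsets[(11, 21)]
    assert any(np.allclose(o, [10, 0, 0]) for o in direct)
    reflected = model.offsets[(21, 11)]
    assert any(np.allclose(o, [-10, 0, 0]) for o in reflected)
    # mirror of the direct (11,21) offset also lands on (21,11)
    assert len(reflected) == 2


def test_collect_offsets_same_fdi_components():
    """A tooth with two disconnected patches 3 mm apart yields a
    same-FDI offset of norm 3, shared by every (i, i) upper pair."""
    cluster_a = [[0.0, 0.0, 0.0], [0.05, 0.0, 0.0], [0.0, 0.05, 0.0]]
    cluster_b = [[3.0, 0.0, 0.0], [3.05, 0.0, 0.0], [3.0, 0.05, 0.0]]
    scan = _point_scan([(11, cluster_a + cluster_b)], "upper")
    model = collect_offsets([scan])
    pool = model.same_fdi["upper"]
    norms = [np.linalg.norm(o) for o in pool]
    assert any(abs(n - 3.0) < 0.1 for n in norms)
    fit_offset_model(model)
    assert model.is_fitted((14, 14))
    assert model.is_fitted((27, 27))
    assert not model.is_fitted((36, 36))


def test_collect_offsets_mirror_equivariance(upper_scan):
    """Collecting from a scan and from its x-negated mirror gives the
    same offset sets up to the pair-mirroring map."""
    mirrored = upper_scan.copy()
    mirrored.points = mirrored.points * np.array([-1.0, 1.0, 1.0])
    mirrored.vertex_fdi = np.array(
        [fdi.mirror_fdi(l) if l else 0 for l in upper_scan.vertex_fdi])
    a = collect_offsets([upper_scan])
    b = collect_offsets([mirrored])
    assert set(a.offsets) == set(b.offsets)
    for pair in a.offsets:
        lhs = np.sort(np.round(np.array(a.offsets[pair]), 9), axis=0)
        rhs = np.sort(np.round(np.array(b.offsets[pair]), 9), axis=0)
        assert np.allclose(lhs, rhs)


def test_fit_offset_model_mean_and_fallback():
    model = OffsetModel()
    model.add_offset((11, 21), np.array([1.0, 0.0, 0.0]))
    model.add_offset((11, 21), np.array([3.0, 0.0, 0.0]))
    fit_offset_model(model, ridge=0.01)
    fit = model.fitted[(11, 21)]
    assert np.allclose(fit.mu, [2.0, 0.0, 0.0])
    assert fit.k == 2
    assert not model.is_fitted((11, 22))
    # unobserved pair: pooled density floored at the fallback constant
    assert model.pair_cost((11, 22), np.zeros(3)) >= model.fallback_floor


def test_fit_offset_model_rejects_negative_ridge():
    with pytest.raises(ValidationError):
        fit_offset_model(OffsetModel(), ridge=-1.0)


def test_gaussian_parameter_recovery():
    """500 draws from a known trivariate normal recover mu within 0.2 mm
    and Sigma within 0.5 Frobenius."""
    rng = np.random.default_rng(0)
    mu0 = np.array([7.0, -1.0, 0.5])
    sigma0 = np.array([[1.0, 0.3, 0.0], [0.3, 2.0, 0.1], [0.0, 0.1, 0.5]])
    model = OffsetModel()
    for draw in rng.multivariate_normal(mu0, sigma0, size=500):
        model.add_offset((16, 15), draw)
    fit_offset_model(model, ridge=0.01)
    fit = model.fitted[(16, 15)]
    assert np.linalg.norm(fit.mu - mu0) < 0.2
    assert np.linalg.norm(fit.sigma - sigma0) < 0.5


def test_model_json_round_trip(offset_model):
    restored = OffsetModel.from_json(offset_model.to_json())
    assert set(restored.fitted) == set(offset_model.fitted)
    delta = np.array([6.0, 1.0, 0.0])
    for pair in [(11, 21), (16, 15), (24, 25)]:
        assert restored.pair_cost(pair, delta) == pytest.approx(
            offset_model.pair_cost(pair, delta), rel=1e-9)


# -- pairwise costs ------------------------------------------------------


def _unit_gaussian_model(mu=(10.0, 0.0, 0.0)):
    model = OffsetModel()
    model.fitted[(11, 21)] = _FittedPair(np.array(mu, float), np.eye(3), 5)
    return model


def test_pair_cost_closed_form_at_mean():
    model = _unit_gaussian_model()
    cost = model.pair_cost((11, 21), np.array([10.0, 0.0, 0.0]))
    assert cost == pytest.approx(1.5 * np.log(2 * np.pi), abs=1e-9)
    shifted = model.pair_cost((11, 21), np.array([11.0, 0.0, 0.0]))
    assert shifted == pytest.approx(1.5 * np.log(2 * np.pi) + 0.5, abs=1e-9)


def test_pair_costs_dimensions(offset_model, upper_scan):
    centroids = np.array([upper_scan.centroid_of_instance(i)
                          for i in upper_scan.instance_ids()])
    ordering = order_teeth(centroids)
    costs = pair_costs(centroids, ordering, offset_model, "upper")
    assert costs.shape == (len(centroids) - 1, 16, 16)
    assert np.isfinite(costs).all()


def test_pair_cost_is_normalized_density():
    """Numerically integrating exp(-cost) over a grid around mu
    approximates 1 (sanity of the Gaussian log-density)."""
    model = _unit_gaussian_model()
    step = 0.25
    axis = np.arange(-4.0, 4.0 + step, step)
    grid = np.stack(np.meshgrid(axis, axis, axis, indexing="ij"), axis=-1)
    deltas = grid.reshape(-1, 3) + np.array([10.0, 0.0, 0.0])
    densities = [np.exp(-model.pair_cost((11, 21), d)) for d in deltas]
    integral = float(np.sum(densities)) * step ** 3
    assert abs(integral - 1.0) < 0.1


# -- dynamic program -----------------------------------------------------


def test_dp_single_tooth_is_unary_argmin():
    rng = np.random.default_rng(0)
    unary = rng.random((1, 16))
    tables = CostTables("upper", unary, np.zeros((0, 16, 16)))
    out = optimal_fdi_sequence(tables)
    assert out.labels == [fdi.UPPER_SEQUENCE[int(np.argmin(unary[0]))]]
    assert out.total_cost == pytest.approx(unary[0].min())


def test_dp_matches_brute_force_t3():
    rng = np.random.default_rng(1)
    for _ in range(50):
        unary = rng.random((3, 16)) * 5
        pairwise = rng.random((2, 16, 16)) * 5
        out = optimal_fdi_sequence(CostTables("upper", unary, pairwise))
        cost, labels = brute_force_sequence(unary, pairwise)
        assert out.total_cost == pytest.approx(cost, rel=1e-12)
        assert tuple(fdi.UPPER_SEQUENCE.index(l) for l in out.labels) == \
            labels


def test_dp_dominates_random_sequences():
    rng = np.random.default_rng(2)
    for _ in range(20):
        t = 5
        unary = rng.random((t, 16)) * 5
        pairwise = rng.random((t - 1, 16, 16)) * 5
        out = optimal_fdi_sequence(CostTables("lower", unary, pairwise))
        for _ in range(200):
            labels = rng.integers(0, 16, size=t)
            cost = unary[np.arange(t), labels].sum() + pairwise[
                np.arange(t - 1), labels[:-1], labels[1:]].sum()
            assert out.total_cost <= cost + 1e-9


def test_dp_breaks_ties_toward_lower_label_index():
    unary = np.zeros((2, 16))
    pairwise = np.zeros((1, 16, 16))
    out = optimal_fdi_sequence(CostTables("upper", unary, pairwise))
    assert out.labels == [18, 18]       # first label of the sequence


def test_dp_total_cost_is_recomputable():
    rng = np.random.default_rng(3)
    unary = rng.random((6, 16))
    pairwise = rng.random((5, 16, 16))
    out = optimal_fdi_sequence(CostTables("upper", unary, pairwise))
    idx = [fdi.UPPER_SEQUENCE.index(l) for l in out.labels]
    recomputed = sum(unary[t][idx[t]] for t in range(6)) + sum(
        pairwise[t][idx[t]][idx[t + 1]] for t in range(5))
    assert out.total_cost == pytest.approx(recomputed, rel=1e-12)


def test_dp_rejects_empty_tables():
    with pytest.raises(ValidationError):
        optimal_fdi_sequence(CostTables("upper", np.zeros((0, 16)),
                                        np.zeros((0, 16, 16))))


# -- full relabeling -----------------------------------------------------


def test_relabel_zero_noise_closure(upper_scan, offset_model):
    pred = synthetic.perturb_predictions(upper_scan,
                                         synthetic.NoiseConfig(seed=0))
    out = relabel(pred, offset_model)
    truth = [upper_scan.label_of_instance(t.source_instance)
             for t in pred.instances]
    assert out.labels == truth
    assert out.arch == "upper"


def test_relabel_single_instance_reduces_to_argmax(offset_model):
    pred = _mock(np.array([[0.0, -20.0, 2.0]]), [_peaked(13)])
    out = relabel(pred, offset_model)
    assert out.labels == [13]


def test_relabel_fixes_swapped_neighbour_labels(upper_scan, offset_model):
    """Two adjacent teeth with confidently swapped logits are restored to
    the anatomically consistent sequence by the pair prior."""
    pred = synthetic.perturb_predictions(upper_scan,
                                         synthetic.NoiseConfig(seed=0))
    i14 = next(i for i, t in enumerate(pred.instances)
               if t.argmax_label() == 14)
    i15 = next(i for i, t in enumerate(pred.instances)
               if t.argmax_label() == 15)
    pred.instances[i14].logits, pred.instances[i15].logits = \
        pred.instances[i15].logits, pred.instances[i14].logits
    out = relabel(pred, offset_model)
    assert out.labels[i14] == 14 and out.labels[i15] == 15


def test_relabel_never_below_argmax_accuracy(upper_scan, offset_model):
    """Postprocessing accuracy is at least per-tooth argmax accuracy on
    every seeded noisy arch (the mechanism behind the ablation gain)."""
    for seed in range(20):
        noise = synthetic.NoiseConfig(centroid_sigma_mm=0.5,
                                      label_confusion_rate=0.15, seed=seed)
        pred = synthetic.perturb_predictions(upper_scan, noise)
        out = relabel(pred, offset_model)
        truth = [upper_scan.label_of_instance(t.source_instance)
                 for t in pred.instances]
        dp_acc = np.mean([a == b for a, b in zip(out.labels, truth)])
        argmax_acc = np.mean([t.argmax_label() == b
                              for t, b in zip(pred.instances, truth)])
        assert dp_acc >= argmax_acc
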