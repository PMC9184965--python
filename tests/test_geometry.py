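"""Rest points, manifolds, basins and decision graphs."""

import numpy as np
import pytest

from waddyn import (
    LandscapeModel,
    RiemannianMetric,
    basin_of,
    decision_graph,
    find_rest_points,
    make_family,
    unstable_manifold,
)
from waddyn.geometry import UNDECIDABLE, branch_destinations

from conftest import random_spd_metrics


@pytest.fixture(scope="module")
def cusp_model():
    return LandscapeModel(make_family("cusp1d"))


def test_cusp_rest_points_match_closed_form(cusp_model):
    # double-well normal form at a=-1, b=0: minima at x=+-1, saddle at 0
    rps = find_rest_points(cusp_model, theta=[-1.0, 0.0])
    pos = sorted(round(float(rp.position[0]), 6) for rp in rps)
    assert pos == [-1.0, 0.0, 1.0]
    kinds = {round(float(rp.position[0])): rp.kind for rp in rps}
    assert kinds[-1] == "attractor" and kinds[1] == "attractor"
    assert kinds[0] == "saddle1"
    for rp in rps:
        assert abs(rp.position[1]) < 1e-8  # the embedding is a y-parabola


def test_poincare_hopf_count_holds(flip_model, rng):
    # confining potential in the plane: #attractors - #saddles + #repellors = 1
    for _ in range(8):
        theta = rng.uniform(-3, 3, size=2)
        rps = find_rest_points(flip_model, theta=theta)
        n_att = sum(rp.kind == "attractor" for rp in rps)
        n_sad = sum(rp.kind == "saddle1" for rp in rps)
        n_rep = sum(rp.kind == "repellor" for rp in rps)
        assert n_att - n_sad + n_rep == 1


def test_rest_points_invariant_under_metric(flip_model):
    # the metric reshapes trajectories but never moves rest points or
    # changes their Morse classification
    theta = [-1.0, 0.3]
    base = find_rest_points(flip_model, theta=theta)
    base_set = sorted((round(float(p), 6) for rp in base for p in rp.position))
    base_kinds = sorted(rp.kind for rp in base)
    for metric in random_spd_metrics(seed=13, n=5):
        model = LandscapeModel(flip_model.family, metric=metric)
        rps = find_rest_points(model, theta=theta)
        assert sorted(rp.kind for rp in rps) == base_kinds
        pos = sorted((round(float(p), 6) for rp in rps for p in rp.position))
        assert pos == base_set


def test_unstable_manifold_reaches_two_attractors(cusp_model):
    rps = find_rest_points(cusp_model, theta=[-1.0, 0.0])
    saddle = next(rp for rp in rps if rp.kind == "saddle1")
    b1, b2 = unstable_manifold(cusp_model, saddle, theta=[-1.0, 0.0], rest_points=rps)
    dests = {b1.destination, b2.destination}
    atts = {rp.id for rp in rps if rp.kind == "attractor"}
    assert dests == atts


def test_basin_assignment_respects_symmetry(cusp_model):
    theta = [-1.0, 0.0]
    rps = find_rest_points(cusp_model, theta=theta)
    by_x = {round(float(rp.position[0])): rp.id for rp in rps}
    assert basin_of(cusp_model, [0.4, 0.3], theta=theta, rest_points=rps) == by_x[1]
    assert basin_of(cusp_model, [-0.4, -0.3], theta=theta, rest_points=rps) == by_x[-1]
    assert basin_of(cusp_model, [0.0, 0.0], theta=theta, rest_points=rps) == UNDECIDABLE


def test_decision_graph_of_double_well(cusp_model):
    dg = decision_graph(cusp_model, theta=[-1.0, 0.0])
    assert len(dg.nodes) == 2
    assert len(dg.edges) == 1
    assert dg.complete


def test_decision_graph_of_tristable_flip(flip_model):
    # slightly off the symmetry axis the three attractors form a path graph;
    # exactly on the axis the progenitor's saddle connects to the downstream
    # saddle (a flip configuration) and its edge disappears
    dg = decision_graph(flip_model, theta=[-1.0, 0.1])
    assert len(dg.nodes) == 3
    assert len(dg.edges) == 2
    degrees = sorted(d for _, d in dg.graph.degree)
    assert degrees == [1, 1, 2]
    on_flip = decision_graph(flip_model, theta=[-1.0, 0.0])
    assert len(on_flip.nodes) == 3
    assert len(on_flip.edges) == 1


def test_box2_metrics_flip_connection_without_moving_rest_points():
    # the worked two-metric example: identical potential and rest points,
    # opposite connection of the central saddle
    family = make_family("box2_example")
    g_minus = RiemannianMetric.constant(np.array([[1.0, -0.6], [-0.6, 1.0]]))
    g_plus = RiemannianMetric.constant(np.array([[1.0, 0.6], [0.6, 1.0]]))
    m1 = LandscapeModel(family, metric=g_minus)
    m2 = LandscapeModel(family, metric=g_plus)
    rps1 = find_rest_points(m1)
    rps2 = find_rest_points(m2)
    p1 = np.array(sorted(map(tuple, np.round([rp.position for rp in rps1], 8))))
    p2 = np.array(sorted(map(tuple, np.round([rp.position for rp in rps2], 8))))
    assert np.allclose(p1, p2)
    e1 = set(map(tuple, map(sorted, decision_graph(m1, rest_points=rps1).edges)))
    e2 = set(map(tuple, map(sorted, decision_graph(m2, rest_points=rps2).edges)))
    assert e1 != e2


def test_branch_destinations_cover_all_saddles(flip_model):
    dests, rps = branch_destinations(flip_model, theta=[-1.0, 0.0])
    saddles = [rp for rp in rps if rp.kind == "saddle1"]
    assert set(dests) == {rp.id for rp in saddles}
    for pair in dests.values():
        assert len(pair) == 2
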