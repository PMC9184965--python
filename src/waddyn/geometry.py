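"""Rest points, unstable manifolds, basins and the decision graph.

The landscape's decision structure is carried by its rest points: attractors
(cell states), index-1 saddles (whose one-dimensional unstable manifolds are
the escape routes between states) and repellors.  The decision graph has the
attractors as nodes and one edge per pair of attractors joined by at least
one index-1 saddle; it lists every transition the system can make, whether
driven by a bifurcation or by noise.

Morse indices are computed from the Hessian of the potential alone.  By
Sylvester's law of inertia the count of negative eigenvalues of ``H`` equals
the count of positive real parts of the flow linearization ``-G^{-1}H`` for
any symmetric positive-definite ``G``, so the classification is independent
of the metric, while the *routes* (branch destinations) are not.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import networkx as nx
import scipy.linalg

from .families import LandscapeModel
from .flow import ATTRACTOR_RADIUS, integrate, relax_batch, vector_field

__all__ = [
    "RestPoint",
    "ManifoldBranch",
    "DecisionGraph",
    "find_rest_points",
    "unstable_manifold",
    "basin_of",
    "decision_graph",
    "RestPointSearchError",
    "EscapedError",
    "UNDECIDABLE",
]

GRAD_TOL = 1e-8
UNDECIDABLE = "undecidable"


class RestPointSearchError(RuntimeError):
    """No rest point found -- impossible for a confining potential."""


class EscapedError(RuntimeError):
    """A trajectory failed to converge to any attractor."""


_KINDS = {0: "attractor", 1: "saddle1", 2: "repellor"}


@dataclass(frozen=True)
class RestPoint:
    """A critical point of the potential with its Morse classification."""

    id: str
    position: np.ndarray
    morse_index: int
    kind: str
    hessian_eigs: np.ndarray
    potential: float

    @property
    def is_attractor(self) -> bool:
        return self.kind == "attractor"


@dataclass(frozen=True)
class ManifoldBranch:
    """One branch of an index-1 saddle's unstable manifold."""

    source_saddle: str
    direction_sign: int
    polyline: np.ndarray
    destination: str  # attractor id, "escaped" or "near_saddle"


def _newton_batch(family, theta, X, n_iter=80, cap=0.5):
    """Damped Newton iteration on the gradient from a batch of starts."""
    X = np.array(X, float, copy=True)
    for _ in range(n_iter):
        G = family.gradient(X, theta)
        H = family.hessian(X, theta)
        det = H[:, 0, 0] * H[:, 1, 1] - H[:, 0, 1] * H[:, 1, 0]
        bad = np.abs(det) < 1e-12
        det = np.where(bad, 1.0, det)
        dx = (H[:, 1, 1] * G[:, 0] - H[:, 0, 1] * G[:, 1]) / det
        dy = (-H[:, 1, 0] * G[:, 0] + H[:, 0, 0] * G[:, 1]) / det
        step = np.stack([dx, dy], axis=-1)
        step[bad] = 0.1  # nudge off degenerate points
        norm = np.linalg.norm(step, axis=-1, keepdims=True)
        step = step * np.minimum(1.0, cap / np.maximum(norm, 1e-300))
        X = X - step
    return X


def find_rest_points(
    model: LandscapeModel,
    theta=None,
    grid_n: int = 12,
    dedup_tol: float = 1e-5,
    domain_box=None,
) -> list[RestPoint]:
    """Locate and classify all rest points by multistart Newton.

    Newton iterations start from a ``grid_n`` x ``grid_n`` lattice over the
    family's domain box, converge to critical points of any index, and are
    deduplicated at ``dedup_tol``.  For a confining potential the Morse
    indices must satisfy the Poincare-Hopf count ``#att - #saddle + #rep = 1``;
    when the lattice misses a point (small repellor islands, typically) the
    search is retried on a denser lattice until the count closes.  The result
    is sorted by potential value and labelled ``r0, r1, ...`` in that order.
    """
    if grid_n < 8:
        raise ValueError("grid_n must be >= 8")
    th = model.theta if theta is None else np.atleast_1d(np.asarray(theta, float))
    family = model.family
    box = family.domain_box if domain_box is None else np.asarray(domain_box, float)

    pts = None
    n = grid_n
    while True:
        xs = np.linspace(box[0, 0], box[0, 1], n)
        ys = np.linspace(box[1, 0], box[1, 1], n)
        starts = np.stack(np.meshgrid(xs, ys), axis=-1).reshape(-1, 2)
        X = _newton_batch(family, th, starts)

        gnorm = np.linalg.norm(family.gradient(X, th), axis=-1)
        inside = np.all((X >= box[:, 0] - 1e-9) & (X <= box[:, 1] + 1e-9), axis=-1)
        X = X[(gnorm < GRAD_TOL) & inside]
        if X.shape[0] == 0:
            if n < 64:
                n *= 2
                continue
            raise RestPointSearchError(
                "no rest points converged; confined potentials have >= 1"
            )

        # greedy dedup
        kept: list[np.ndarray] = []
        for p in X:
            if not any(np.linalg.norm(p - q) < max(dedup_tol, 1e-8) for q in kept):
                kept.append(p)
        pts = np.asarray(kept)
        eigs_chk = np.linalg.eigvalsh(family.hessian(pts, th))
        idx_sum = int(np.sum((-1) ** np.sum(eigs_chk < 0, axis=1)))
        if idx_sum == 1 or n >= 64:
            break
        n *= 2

    H = family.hessian(pts, th)
    eigs = np.linalg.eigvalsh(H)
    pot = family.evaluate(pts, th)
    order = np.argsort(pot)
    out = []
    for rank, i in enumerate(order):
        idx = int(np.sum(eigs[i] < 0))
        out.append(
            RestPoint(
                id=f"r{rank}",
                position=pts[i].copy(),
                morse_index=idx,
                kind=_KINDS.get(idx, f"index{idx}"),
                hessian_eigs=eigs[i].copy(),
                potential=float(pot[i]),
            )
        )
    return out


def _unstable_direction(model: LandscapeModel, saddle: RestPoint, theta=None) -> np.ndarray:
    """Unit eigenvector of ``-G^{-1}H`` with positive eigenvalue at the saddle."""
    th = model.theta if theta is None else theta
    H = model.family.hessian(saddle.position, th)
    G = model.metric.evaluate(saddle.position)
    A = -np.linalg.solve(G, H)
    w, V = scipy.linalg.eig(A)
    k = int(np.argmax(w.real))
    if w.real[k] <= 0:
        raise ValueError(f"rest point {saddle.id} has no unstable direction")
    u = V[:, k].real
    return u / np.linalg.norm(u)


def _classify_endpoint(x, rest_points, radius=ATTRACTOR_RADIUS):
    for rp in rest_points:
        if np.linalg.norm(x - rp.position) < radius:
            return rp.id if rp.is_attractor else "near_saddle"
    return "escaped"


def unstable_manifold(
    model: LandscapeModel,
    saddle: RestPoint,
    theta=None,
    rest_points=None,
    eps: float = 1e-4,
    t_max: float = 400.0,
) -> tuple[ManifoldBranch, ManifoldBranch]:
    """Both branches of the 1D unstable manifold of an index-1 saddle.

    Each branch starts at ``position +/- eps * u`` where ``u`` is the unstable
    eigendirection of the linearized flow, is integrated until convergence and
    reports the attractor it lands on (or ``escaped`` / ``near_saddle``).
    """
    if saddle.kind != "saddle1":
        raise ValueError(f"{saddle.id} is not an index-1 saddle")
    th = model.theta if theta is None else theta
    if rest_points is None:
        rest_points = find_rest_points(model, theta=th)
    u = _unstable_direction(model, saddle, theta=th)
    branches = []
    for sign in (+1, -1):
        x0 = saddle.position + sign * eps * u
        traj = integrate(model.with_theta(th), x0, t_end=t_max)
        dest = "escaped"
        if traj.terminal_flag == "converged":
            dest = _classify_endpoint(traj.final_state, rest_points)
        elif traj.terminal_flag == "max_time":
            dest = _classify_endpoint(traj.final_state, rest_points)
        branches.append(
            ManifoldBranch(
                source_saddle=saddle.id,
                direction_sign=sign,
                polyline=traj.states,
                destination=dest,
            )
        )
    return branches[0], branches[1]


def basin_of(model: LandscapeModel, x, theta=None, rest_points=None, t_max: float = 400.0) -> str:
    """Identify the attractor whose basin contains ``x`` under frozen ``theta``.

    Points within 1e-6 of a saddle are reported as :data:`UNDECIDABLE`
    rather than assigned by integrator luck.
    """
    th = model.theta if theta is None else theta
    if rest_points is None:
        rest_points = find_rest_points(model, theta=th)
    x = np.asarray(x, float)
    for rp in rest_points:
        if rp.kind != "attractor" and np.linalg.norm(x - rp.position) < 1e-6:
            return UNDECIDABLE
    traj = integrate(model.with_theta(th), x, t_end=t_max)
    if traj.terminal_flag == "escaped_domain":
        raise EscapedError("trajectory left the domain box")
    dest = _classify_endpoint(traj.final_state, rest_points)
    if dest in ("escaped", "near_saddle"):
        if dest == "near_saddle":
            return UNDECIDABLE
        raise EscapedError("trajectory did not converge to an attractor")
    return dest


def branch_destinations(model: LandscapeModel, theta=None, rest_points=None, eps: float = 1e-4):
    """Fast vectorized destinations of every saddle branch (endpoints only).

    Returns ``{saddle_id: (dest_plus, dest_minus)}`` using the same seeding as
    :func:`unstable_manifold` but a batched relaxation instead of per-branch
    adaptive integration.
    """
    th = model.theta if theta is None else theta
    if rest_points is None:
        rest_points = find_rest_points(model, theta=th)
    saddles = [rp for rp in rest_points if rp.kind == "saddle1"]
    if not saddles:
        return {}, rest_points
    starts = []
    for s in saddles:
        u = _unstable_direction(model, s, theta=th)
        starts.append(s.position + eps * u)
        starts.append(s.position - eps * u)
    finals = relax_batch(model, np.asarray(starts), theta=th)
    out = {}
    for i, s in enumerate(saddles):
        dp = _classify_endpoint(finals[2 * i], rest_points, radius=ATTRACTOR_RADIUS)
        dm = _classify_endpoint(finals[2 * i + 1], rest_points, radius=ATTRACTOR_RADIUS)
        out[s.id] = (dp, dm)
    return out, rest_points


@dataclass
class DecisionGraph:
    """Attractors as nodes; deduplicated index-1 saddle connections as edges."""

    graph: nx.Graph
    saddle_map: dict = field(default_factory=dict)  # (id_a, id_b) sorted -> [saddle ids]
    complete: bool = True
    positions: dict = field(default_factory=dict)

    @property
    def nodes(self):
        return list(self.graph.nodes)

    @property
    def edges(self):
        return [tuple(sorted(e)) for e in self.graph.edges]

    def to_json_dict(self) -> dict:
        return {
            "nodes": sorted(self.graph.nodes),
            "edges": sorted(tuple(sorted(e)) for e in self.graph.edges),
            "saddle_map": {f"{a}--{b}": v for (a, b), v in sorted(self.saddle_map.items())},
            "complete": self.complete,
            "positions": {k: list(map(float, v)) for k, v in self.positions.items()},
        }

    def to_dot(self) -> str:
        lines = ["graph decision {"]
        for n in sorted(self.graph.nodes):
            lines.append(f'  "{n}";')
        for a, b in sorted(tuple(sorted(e)) for e in self.graph.edges):
            saddles = ",".join(self.saddle_map.get((a, b), []))
            lines.append(f'  "{a}" -- "{b}" [label="{saddles}"];')
        lines.append("}")
        return "\n".join(lines)


def decision_graph(model: LandscapeModel, theta=None, rest_points=None) -> DecisionGraph:
    """Build the decision graph at frozen parameters.

    One edge is added per index-1 saddle whose two branches reach two distinct
    attractors; multiple saddles joining the same pair collapse onto a single
    edge, and saddles whose branches both reach the same attractor contribute
    no edge (they stay in ``saddle_map`` for bookkeeping).  Any branch that
    escapes marks the graph incomplete.
    """
    th = model.theta if theta is None else theta
    dests, rest_points = branch_destinations(model, theta=th, rest_points=rest_points)
    g = nx.Graph()
    positions = {}
    for rp in rest_points:
        if rp.is_attractor:
            g.add_node(rp.id)
            positions[rp.id] = rp.position
    saddle_map: dict = {}
    complete = True
    for sid, (dp, dm) in dests.items():
        if "escaped" in (dp, dm):
            complete = False
            continue
        if "near_saddle" in (dp, dm):
            # measure-zero heteroclinic configuration; record, no edge
            continue
        key = tuple(sorted((dp, dm)))
        saddle_map.setdefault(key, []).append(sid)
        if dp != dm:
            g.add_edge(*key)
    return DecisionGraph(graph=g, saddle_map=saddle_map, complete=complete, positions=positions)
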