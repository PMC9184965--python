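"""Fold curves, cusps, flip curves and the two-parameter bifurcation atlas.

In a generic two-parameter landscape family only two kinds of codimension-one
events change the decision structure:

* **fold** (saddle-node) bifurcations -- an attractor-saddle (or
  saddle-repellor) pair collides and annihilates; these occur on *fold
  curves* in the parameter plane, and pairs of fold curves meet at *cusp*
  points (standard or dual);
* **flip** (heteroclinic) bifurcations -- the one-dimensional unstable
  manifold of a source saddle brushes the stable manifold of a sink saddle
  and its destination attractor switches; these occur on *flip curves*,
  which terminate where one of the two saddles is destroyed on a fold curve.

The atlas traces all such curves over a parameter box and partitions the box
into regions of qualitatively equivalent landscapes, labelling the decision
archetypes (monostable, bistable, binary choice, binary flip, other
tristable arrangements).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .families import LandscapeModel, PotentialFamily, RiemannianMetric
from .geometry import RestPoint, branch_destinations, find_rest_points

__all__ = [
    "FoldCurve",
    "CuspPoint",
    "FlipCurve",
    "BifurcationSet",
    "fold_residual",
    "trace_fold_curve",
    "detect_cusps",
    "locate_flip",
    "trace_flip_curve",
    "build_atlas",
    "NoFlipError",
    "FoldInterferenceError",
]

FOLD_TOL = 1e-7
FLIP_PARAM_TOL = 1e-6
FLIP_APPROACH_TOL = 1e-3

#: mechanism labels for the two generic codimension-one decision events
MECH_FOLD = "rest_point_collision"
MECH_FLIP = "connection_change"


class NoFlipError(RuntimeError):
    """The tracked branch has the same destination at both segment ends."""


class FoldInterferenceError(RuntimeError):
    """The tracked saddle disappeared (fold) inside the search segment."""


# --------------------------------------------------------------------------
# fold residual and continuation
# --------------------------------------------------------------------------

def fold_residual(family: PotentialFamily, x, theta) -> tuple[float, float]:
    """Residual pair ``(|grad F|, det H)``; both vanish exactly at a fold."""
    g = family.gradient(x, theta)
    h = family.hessian(x, theta)
    return float(np.linalg.norm(g)), float(np.linalg.det(h))


def _fold_system(family, z):
    """Augmented fold equations R(x, y, a, b) = (F_x, F_y, det H)."""
    x, th = z[:2], z[2:]
    g = family.gradient(x, th)
    h = family.hessian(x, th)
    return np.array([g[0], g[1], np.linalg.det(h)])


def _fold_jacobian(family, z, h_fd=1e-6):
    """Central finite-difference Jacobian of the fold system, shape (3, 4)."""
    J = np.empty((3, 4))
    for j in range(4):
        e = np.zeros(4)
        e[j] = h_fd
        J[:, j] = (_fold_system(family, z + e) - _fold_system(family, z - e)) / (2 * h_fd)
    return J


def _fold_newton(family, z, tol=1e-12, n_iter=40):
    """Gauss-Newton (minimal-norm) solve of the underdetermined fold system."""
    z = np.asarray(z, float).copy()
    for _ in range(n_iter):
        r = _fold_system(family, z)
        if np.linalg.norm(r) < tol:
            return z, True
        J = _fold_jacobian(family, z)
        step, *_ = np.linalg.lstsq(J, r, rcond=None)
        if not np.all(np.isfinite(step)):
            return z, False
        n = np.linalg.norm(step)
        if n > 0.5:
            step *= 0.5 / n
        z = z - step
    return z, np.linalg.norm(_fold_system(family, z)) < 1e-8


def _fold_tangent(family, z, prev=None):
    """Unit null vector of the fold Jacobian, oriented to follow ``prev``."""
    J = _fold_jacobian(family, z)
    _, _, vt = np.linalg.svd(J)
    t = vt[-1]
    t = t / np.linalg.norm(t)
    if prev is not None and np.dot(t, prev) < 0:
        t = -t
    return t


@dataclass
class FoldCurve:
    """A continuation-traced fold curve.

    ``points`` are the parameter-space samples (a, b); ``degenerate_states``
    the corresponding colliding-pair locations in phase space.
    """

    points: np.ndarray  # (n, 2) parameter samples
    degenerate_states: np.ndarray  # (n, 2) phase-space samples
    closed: bool = False
    mechanism: str = MECH_FOLD
    involved_attractor: str | None = None

    def __len__(self):
        return self.points.shape[0]


def _trace_direction(family, z0, box, step, t0, max_steps):
    zs = [z0.copy()]
    t = t0.copy()
    h = step
    z = z0.copy()
    closed = False
    for _ in range(max_steps):
        t = _fold_tangent(family, z, prev=t)
        pred = z + h * t
        # corrector: Newton with arclength constraint
        zc = pred.copy()
        ok = False
        for _ in range(25):
            r = _fold_system(family, zc)
            c = np.dot(t, zc - pred)
            rr = np.append(r, c)
            if np.linalg.norm(rr) < 1e-12:
                ok = True
                break
            J = np.vstack([_fold_jacobian(family, zc), t])
            try:
                dz = np.linalg.solve(J, rr)
            except np.linalg.LinAlgError:
                break
            zc = zc - dz
        if not ok and np.linalg.norm(_fold_system(family, zc)) < 1e-9:
            ok = True
        if not ok:
            h *= 0.5
            if h < step / 64:
                break  # truncated: corrector divergence
            continue
        h = min(step, h * 1.5)
        z = zc
        zs.append(z.copy())
        th = z[2:]
        if np.any(th < box[:, 0] - 1e-9) or np.any(th > box[:, 1] + 1e-9):
            break
        if len(zs) > 10 and np.linalg.norm(z - z0) < step:
            closed = True
            break
    return zs, closed


def trace_fold_curve(
    family: PotentialFamily,
    seed_point,
    box=None,
    step: float = 0.02,
    max_steps: int = 4000,
) -> FoldCurve:
    """Pseudo-arclength continuation of the fold set from a seed.

    ``seed_point`` is ``(x, theta)`` with ``fold_residual`` below 1e-6.  The
    curve is traced in both directions through the augmented space
    ``(x, y, a, b)`` and terminates at the parameter-box boundary, after
    closing a loop, or on corrector failure (truncated with the points found).
    """
    x, th = seed_point
    box = np.asarray(family.param_box if box is None else box, float)
    z0 = np.concatenate([np.asarray(x, float), np.asarray(th, float)])
    res = np.linalg.norm(_fold_system(family, z0))
    if res > 1e-6:
        z0, ok = _fold_newton(family, z0)
        if not ok:
            raise ValueError("seed does not satisfy the fold equations")
    else:
        z0, _ = _fold_newton(family, z0)

    t0 = _fold_tangent(family, z0)
    fwd, closed_f = _trace_direction(family, z0, box, step, t0, max_steps)
    if closed_f:
        zs = fwd
        closed = True
    else:
        bwd, closed_b = _trace_direction(family, z0, box, step, -t0, max_steps)
        zs = list(reversed(bwd[1:])) + fwd
        closed = closed_b
    arr = np.asarray(zs)
    return FoldCurve(points=arr[:, 2:].copy(), degenerate_states=arr[:, :2].copy(), closed=closed)


# --------------------------------------------------------------------------
# cusp detection and classification
# --------------------------------------------------------------------------

@dataclass
class CuspPoint:
    location: np.ndarray  # (a, b)
    kind: str  # standard | dual
    state: np.ndarray  # degenerate phase point
    meeting_curves: list = field(default_factory=list)


def _kernel_direction(family, x, theta, prev=None):
    """Unit eigenvector of H for its smallest-|eigenvalue| (the fold kernel)."""
    h = family.hessian(x, theta)
    w, v = np.linalg.eigh(h)
    k = int(np.argmin(np.abs(w)))
    u = v[:, k]
    if prev is not None and np.dot(u, prev) < 0:
        u = -u
    return u


def _directional_d3(family, x, theta, u, h=1e-2):
    """Third directional derivative of F along u (five-point stencil)."""
    f = lambda s: float(family.evaluate(np.asarray(x) + s * h * u, theta))
    return (-f(-2) + 2 * f(-1) - 2 * f(1) + f(2)) / (2 * h**3)


def _directional_d4(family, x, theta, u, h=5e-2):
    """Fourth directional derivative of F along u."""
    f = lambda s: float(family.evaluate(np.asarray(x) + s * h * u, theta))
    return (f(-2) - 4 * f(-1) + 6 * f(0) - 4 * f(1) + f(2)) / h**4


def detect_cusps(curve: FoldCurve, family: PotentialFamily, rng=None) -> list[CuspPoint]:
    """Locate and classify cusp points on a traced fold curve.

    A cusp is a point of the fold curve where the cubic directional derivative
    of the potential along the Hessian kernel changes sign; it is refined by
    bisection between adjacent curve samples.  Classification follows the
    local normal form: a positive quartic term along the kernel (minima
    flanking a restricted maximum inside the cusp region) is a *standard*
    cusp, a negative one is a *dual* cusp, cross-checked by probing the
    middle member of the colliding rest-point triple just inside the region.
    """
    if len(curve) < 10:
        raise ValueError("fold curve has too few samples for cusp detection")
    rng = np.random.default_rng(0) if rng is None else rng
    n = len(curve)
    u_prev = None
    c3 = np.empty(n)
    us = np.empty((n, 2))
    for i in range(n):
        u = _kernel_direction(family, curve.degenerate_states[i], curve.points[i], prev=u_prev)
        us[i] = u
        u_prev = u
        c3[i] = _directional_d3(family, curve.degenerate_states[i], curve.points[i], u)

    cusps: list[CuspPoint] = []
    for i in np.flatnonzero(np.sign(c3[:-1]) * np.sign(c3[1:]) < 0):
        za = np.concatenate([curve.degenerate_states[i], curve.points[i]])
        zb = np.concatenate([curve.degenerate_states[i + 1], curve.points[i + 1]])
        ca = c3[i]
        for _ in range(60):
            zm = 0.5 * (za + zb)
            zm, ok = _fold_newton(family, zm)
            if not ok:
                break
            um = _kernel_direction(family, zm[:2], zm[2:], prev=us[i])
            cm = _directional_d3(family, zm[:2], zm[2:], um)
            if np.sign(cm) == np.sign(ca):
                za, ca = zm, cm
            else:
                zb = zm
            if np.linalg.norm(zb - za) < 1e-10:
                break
        zc = 0.5 * (za + zb)
        uc = _kernel_direction(family, zc[:2], zc[2:], prev=us[i])
        d4 = _directional_d4(family, zc[:2], zc[2:], uc)
        kind = "standard" if d4 > 0 else "dual"
        probe_kind = _classify_cusp_by_probe(family, zc, uc, rng)
        if probe_kind is not None:
            kind = probe_kind
        cusps.append(CuspPoint(location=zc[2:].copy(), kind=kind, state=zc[:2].copy()))
    return cusps


def _classify_cusp_by_probe(family, zc, u, rng, radius=0.08, n_angles=24, n_jitter=8):
    """Probe parameter circles around a cusp; classify by the colliding triple.

    Inside the cusp region three rest points coalesce toward the degenerate
    state.  Ordered along the kernel direction, a restricted *maximum* in the
    middle marks a standard cusp and a restricted *minimum* a dual cusp.
    Probes falling on a curve (wrong local count) are re-drawn with jitter.
    """
    x_c, th_c = zc[:2], zc[2:]
    model = LandscapeModel(family, RiemannianMetric.identity(family.dim), theta=th_c * 0)

    def local_triple(th):
        try:
            rps = find_rest_points(model, theta=th, grid_n=16)
        except Exception:
            return None
        near = [rp for rp in rps if np.linalg.norm(rp.position - x_c) < 0.7]
        if len(near) != 3:
            return None
        return sorted(near, key=lambda rp: float(np.dot(rp.position - x_c, u)))

    for trial in range(n_jitter):
        r = radius * (1.0 + 0.3 * trial)
        angles = np.linspace(0, 2 * np.pi, n_angles, endpoint=False)
        if trial:
            angles = angles + rng.uniform(0, 2 * np.pi / n_angles)
        for ang in angles:
            th = th_c + r * np.array([np.cos(ang), np.sin(ang)])
            triple = local_triple(th)
            if triple is None:
                continue
            mid = triple[1]
            curv = float(u @ family.hessian(mid.position, th) @ u)
            if abs(curv) < 1e-10:
                continue
            return "standard" if curv < 0 else "dual"
    return None


# --------------------------------------------------------------------------
# flip bifurcations
# --------------------------------------------------------------------------

@dataclass
class FlipCurve:
    points: np.ndarray  # (n, 2)
    endpoints: tuple = ("box_boundary", "box_boundary")  # source_end | sink_end | box_boundary
    mechanism: str = MECH_FLIP


def _match_rest_point(rest_points, position, kind=None, radius=1.0):
    cands = [rp for rp in rest_points if kind is None or rp.kind == kind]
    if not cands:
        return None
    d = [np.linalg.norm(rp.position - position) for rp in cands]
    k = int(np.argmin(d))
    return cands[k] if d[k] < radius else None


class _SaddleBranchTracker:
    """Follow one unstable branch of one saddle across parameter changes.

    Tracks the saddle by position continuity and the branch by sign
    continuity of the unstable eigendirection; reports the branch's
    destination attractor *position* so destinations can be compared across
    nearby parameter values without relying on volatile ids.
    """

    def __init__(self, model: LandscapeModel, saddle_pos, branch_dir):
        self.model = model
        self.saddle_pos = np.asarray(saddle_pos, float)
        self.branch_dir = np.asarray(branch_dir, float)
        self.branch_dir /= np.linalg.norm(self.branch_dir)

    def probe(self, theta, update=False, with_approach=False):
        """Return (saddle RestPoint, destination position, min approach to other saddles).

        The closest-approach distance (branch trajectory to the other
        saddles) needs a resolved trajectory and is only computed when
        ``with_approach`` is set; otherwise ``inf`` is returned in its place.
        """
        rps = find_rest_points(self.model, theta=theta)
        saddle = _match_rest_point(rps, self.saddle_pos, kind="saddle1")
        if saddle is None:
            raise FoldInterferenceError(
                f"tracked saddle vanished near theta={np.round(theta, 4)}"
            )
        from .geometry import _unstable_direction
        from .flow import relax_batch

        u = _unstable_direction(self.model, saddle, theta=theta)
        if np.dot(u, self.branch_dir) < 0:
            u = -u
        x0 = saddle.position + 1e-4 * u
        final = relax_batch(self.model, x0[None, :], theta=theta)[0]
        atts = [rp for rp in rps if rp.is_attractor]
        dest = min(atts, key=lambda rp: np.linalg.norm(rp.position - final), default=None)
        if dest is None or np.linalg.norm(dest.position - final) > 1e-2:
            dest_pos = None
        else:
            dest_pos = dest.position
        approach = np.inf
        if with_approach:
            others = [rp for rp in rps if rp.kind == "saddle1" and rp.id != saddle.id]
            if others:
                from .flow import integrate

                traj = integrate(self.model.with_theta(theta), x0, t_end=200.0)
                pts = traj.states
                for o in others:
                    approach = min(
                        approach, float(np.min(np.linalg.norm(pts - o.position, axis=1)))
                    )
        if update:
            self.saddle_pos = saddle.position.copy()
            self.branch_dir = u
        return saddle, dest_pos, approach


def locate_flip(
    family: PotentialFamily,
    theta_a,
    theta_b,
    source_saddle_pos,
    branch_dir,
    metric: RiemannianMetric | None = None,
    tol: float = FLIP_PARAM_TOL,
    verify: bool = True,
):
    """Bisect a parameter segment for the flip of a tracked saddle branch.

    The branch destination must differ between the segment's endpoints; the
    returned parameter ``theta*`` brackets the destination switch to width
    ``tol`` and (with ``verify``) the branch's closest approach to the sink
    saddle is checked to be below ``FLIP_APPROACH_TOL`` there.
    """
    metric = RiemannianMetric.identity(family.dim) if metric is None else metric
    model = LandscapeModel(family, metric)
    theta_a = np.asarray(theta_a, float)
    theta_b = np.asarray(theta_b, float)
    tracker = _SaddleBranchTracker(model, source_saddle_pos, branch_dir)
    _, dest_a, _ = tracker.probe(theta_a)
    _, dest_b, _ = tracker.probe(theta_b)
    if dest_a is None or dest_b is None:
        raise NoFlipError("branch destination unresolved at a segment endpoint")
    if np.linalg.norm(dest_a - dest_b) < 0.5:
        raise NoFlipError("same destination attractor at both segment endpoints")
    lo, hi = theta_a, theta_b
    while np.linalg.norm(hi - lo) > tol:
        mid = 0.5 * (lo + hi)
        _, dest_m, _ = tracker.probe(mid, update=True)
        if dest_m is not None and np.linalg.norm(dest_m - dest_a) < np.linalg.norm(dest_m - dest_b):
            lo = mid
        else:
            hi = mid
    theta_star = 0.5 * (lo + hi)
    if verify:
        # a destination switch caused by a fold crossing (pair annihilation on
        # the branch) is not a flip: reject if any rest point is near-degenerate
        rps = find_rest_points(model, theta=theta_star)
        min_det = min(abs(float(np.prod(rp.hessian_eigs))) for rp in rps)
        if min_det < 1e-2:
            raise FoldInterferenceError(
                f"near-degenerate rest point (|det H|={min_det:.2e}) at candidate flip"
            )
        _, _, approach = tracker.probe(theta_star, with_approach=True)
        if not approach < FLIP_APPROACH_TOL:
            raise NoFlipError(
                f"no close saddle-saddle approach at candidate flip (closest {approach:.2e})"
            )
    return theta_star, tracker


def trace_flip_curve(
    family: PotentialFamily,
    theta_star,
    source_saddle_pos,
    branch_dir,
    box=None,
    step: float = 0.1,
    metric: RiemannianMetric | None = None,
    max_steps: int = 400,
) -> FlipCurve:
    """Continue a flip curve by repeated bisection along transverse sweeps.

    From each accepted point the curve advances by ``step`` along its local
    tangent and re-bisects on a perpendicular sweep.  An end is labelled
    ``source_end`` or ``sink_end`` when the respective saddle approaches a
    fold (its Hessian determinant heading to zero), otherwise
    ``box_boundary``.
    """
    metric = RiemannianMetric.identity(family.dim) if metric is None else metric
    box = np.asarray(family.param_box if box is None else box, float)
    model = LandscapeModel(family, metric)
    theta_star = np.asarray(theta_star, float)

    def endpoint_label(theta, tracker):
        try:
            rps = find_rest_points(model, theta=theta)
        except Exception:
            return "box_boundary"
        saddle = _match_rest_point(rps, tracker.saddle_pos, kind="saddle1")
        if saddle is None:
            return "source_end"
        dets = []
        for rp in rps:
            if rp.kind == "saddle1":
                dets.append((abs(float(np.prod(rp.hessian_eigs))), rp.id == saddle.id))
        dets.sort()
        if dets and dets[0][0] < 5e-2:
            return "source_end" if dets[0][1] else "sink_end"
        return "box_boundary"

    halves = []
    for direction in (+1.0, -1.0):
        pts = [theta_star.copy()]
        tracker = _SaddleBranchTracker(model, source_saddle_pos, branch_dir)
        tracker.probe(theta_star, update=True)
        tangent = None
        label = "box_boundary"
        local_step = step
        for _ in range(max_steps):
            cur = pts[-1]
            if tangent is None:
                # initial tangent: try axis directions for the one along which
                # the flip persists; thereafter the tangent is oriented along
                # the direction of travel and is used as-is
                cands = [direction * np.array([1.0, 0.0]), direction * np.array([0.0, 1.0])]
            else:
                cands = [tangent]
            advanced = False
            for t in cands:
                t = t / np.linalg.norm(t)
                nrm = np.array([-t[1], t[0]])
                centre = cur + local_step * t
                a_end = centre + 0.75 * local_step * nrm
                b_end = centre - 0.75 * local_step * nrm
                try:
                    th_new, _ = locate_flip(
                        family,
                        a_end,
                        b_end,
                        tracker.saddle_pos,
                        tracker.branch_dir,
                        metric=metric,
                        tol=1e-4,
                        verify=False,
                    )
                except (NoFlipError, FoldInterferenceError):
                    continue
                # a hit at the very edge of the sweep means the bisection ran
                # off one end (unresolved destination), not a genuine flip
                edge = min(np.linalg.norm(th_new - a_end), np.linalg.norm(th_new - b_end))
                if edge < 0.02 * np.linalg.norm(a_end - b_end):
                    continue
                tangent = (th_new - cur) / max(np.linalg.norm(th_new - cur), 1e-12)
                try:
                    tracker.probe(th_new, update=True)
                except FoldInterferenceError:
                    label = "source_end"
                    break
                pts.append(th_new)
                advanced = True
                break
            if advanced:
                local_step = min(step, local_step * 1.5)
            else:
                # creep toward the true endpoint with a finer step before
                # declaring the curve terminated
                local_step *= 0.5
                if local_step >= step / 16:
                    continue
                label = endpoint_label(pts[-1], tracker)
                break
            if np.any(pts[-1] < box[:, 0]) or np.any(pts[-1] > box[:, 1]):
                label = "box_boundary"
                break
        halves.append((pts, label))
    back, lab_back = halves[1]
    fwd, lab_fwd = halves[0]
    pts = list(reversed(back[1:])) + fwd
    return FlipCurve(points=np.asarray(pts), endpoints=(lab_back, lab_fwd))


# --------------------------------------------------------------------------
# atlas assembly
# --------------------------------------------------------------------------

@dataclass
class Region:
    label: str
    grid_nodes: np.ndarray  # (k, 2) parameter samples in this region
    n_attractors: int
    decision_code: str
    archetype: str = "unlabelled"
    ambiguous: bool = False


@dataclass
class BifurcationSet:
    fold_curves: list
    flip_curves: list
    cusp_points: list
    regions: list
    box: np.ndarray

    @property
    def mechanisms(self) -> set:
        out = {c.mechanism for c in self.fold_curves}
        out |= {c.mechanism for c in self.flip_curves}
        return out

    def to_json_dict(self) -> dict:
        return {
            "box": self.box.tolist(),
            "mechanisms": sorted(self.mechanisms),
            "fold_curves": [
                {
                    "points": c.points.tolist(),
                    "degenerate_states": c.degenerate_states.tolist(),
                    "closed": bool(c.closed),
                    "mechanism": c.mechanism,
                }
                for c in self.fold_curves
            ],
            "flip_curves": [
                {
                    "points": c.points.tolist(),
                    "endpoints": list(c.endpoints),
                    "mechanism": c.mechanism,
                }
                for c in self.flip_curves
            ],
            "cusp_points": [
                {"location": c.location.tolist(), "kind": c.kind} for c in self.cusp_points
            ],
            "regions": [
                {
                    "label": r.label,
                    "n_attractors": r.n_attractors,
                    "archetype": r.archetype,
                    "ambiguous": bool(r.ambiguous),
                    "grid_nodes": r.grid_nodes.tolist(),
                }
                for r in self.regions
            ],
        }

    def plot(self, ax=None):
        """Render curves and cusp points (requires matplotlib)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        for c in self.fold_curves:
            ax.plot(c.points[:, 0], c.points[:, 1], "-", color="tab:blue")
        for c in self.flip_curves:
            ax.plot(c.points[:, 0], c.points[:, 1], "--", color="tab:purple")
        for c in self.cusp_points:
            ax.plot(*c.location, "o", color="tab:red")
        ax.set_xlim(*self.box[0])
        ax.set_ylim(*self.box[1])
        ax.set_xlabel("a")
        ax.set_ylabel("b")
        return ax


def _labelled_edges(model, theta, registry, radius=0.75):
    """Decision-graph edge set with attractor labels stable across the grid.

    ``registry`` maps a persistent label to the last seen position of that
    attractor; attractors are matched by proximity and new labels are issued
    in discovery order.
    """
    dests, rps = branch_destinations(model, theta=theta)
    atts = {rp.id: rp for rp in rps if rp.is_attractor}

    def global_label(rp):
        best, best_d = None, np.inf
        for lab, pos in registry.items():
            d = np.linalg.norm(rp.position - pos)
            if d < best_d:
                best, best_d = lab, d
        if best is not None and best_d < radius:
            registry[best] = rp.position.copy()
            return best
        lab = f"A{len(registry)}"
        registry[lab] = rp.position.copy()
        return lab

    labels = {rid: global_label(rp) for rid, rp in atts.items()}
    edges = set()
    ok = True
    for sid, (dp, dm) in dests.items():
        if dp in labels and dm in labels:
            if dp != dm:
                edges.add(tuple(sorted((labels[dp], labels[dm]))))
        else:
            ok = False
    return frozenset(edges), len(atts), rps, ok


def _cross2(u, v):
    """z-component of the cross product of batches of 2-vectors."""
    return u[..., 0] * v[..., 1] - u[..., 1] * v[..., 0]


def _segments_cross(p, q, curve_pts):
    """Does segment p-q cross the polyline? Vectorized orientation test."""
    a = curve_pts[:-1]
    b = curve_pts[1:]
    d1 = _cross2(q - p, a - p)
    d2 = _cross2(q - p, b - p)
    d3 = _cross2(b - a, p - a)
    d4 = _cross2(b - a, q - a)
    return bool(np.any((d1 * d2 < 0) & (d3 * d4 < 0)))


def build_atlas(
    family: PotentialFamily,
    box=None,
    resolution: int = 15,
    metric: RiemannianMetric | None = None,
    fold_step: float = 0.02,
    flip_step: float = 0.15,
) -> BifurcationSet:
    """Assemble the full bifurcation set over a parameter box.

    The box is scanned on a ``resolution`` x ``resolution`` grid.  Fold seeds
    come from Gauss-Newton projection of each grid point's most degenerate
    rest point onto the fold set (this finds components far smaller than the
    grid spacing); flip seeds come from labelled-decision-graph differences
    between adjacent grid nodes with equal attractor counts.  Regions are the
    connected components of the grid graph cut by the traced curves, probed
    for consistency and labelled with archetypes.
    """
    metric = RiemannianMetric.identity(family.dim) if metric is None else metric
    box = np.asarray(family.param_box if box is None else box, float)
    model = LandscapeModel(family, metric)
    n = resolution
    # irrationally offset grid: nodes never fall on rational symmetry lines
    # of the box (e.g. its midlines), where bifurcation curves tend to lie
    phi = 0.5 * (np.sqrt(5) - 1)
    avals = box[0, 0] + (np.arange(n) + phi) * (box[0, 1] - box[0, 0]) / n
    bvals = box[1, 0] + (np.arange(n) + phi) * (box[1, 1] - box[1, 0]) / n

    registry: dict = {}
    edges_grid = {}
    sig_grid = {}
    rps_grid = {}
    complete_grid = {}
    # serpentine scan: consecutive nodes are grid neighbours, so attractor
    # positions drift by at most one spacing and registry labels stay attached
    for i, a in enumerate(avals):
        js = range(n) if i % 2 == 0 else range(n - 1, -1, -1)
        for j in js:
            b = bvals[j]
            edges, natt, rps, ok = _labelled_edges(model, np.array([a, b]), registry)
            kinds = [rp.kind for rp in rps]
            edges_grid[(i, j)] = edges
            sig_grid[(i, j)] = (
                natt,
                kinds.count("saddle1"),
                kinds.count("repellor"),
            )
            rps_grid[(i, j)] = rps
            complete_grid[(i, j)] = ok

    # ---- fold curves ----------------------------------------------------
    fold_curves: list[FoldCurve] = []

    def near_existing_fold(th, tol):
        for c in fold_curves:
            if np.min(np.linalg.norm(c.points - th, axis=1)) < tol:
                return True
        return False

    for (i, j), rps in rps_grid.items():
        th = np.array([avals[i], bvals[j]])
        rp = min(rps, key=lambda r: abs(float(np.prod(r.hessian_eigs))))
        z0 = np.concatenate([rp.position, th])
        z, ok = _fold_newton(family, z0)
        if not ok:
            continue
        th_f = z[2:]
        if np.any(th_f < box[:, 0] - 1e-6) or np.any(th_f > box[:, 1] + 1e-6):
            continue
        if near_existing_fold(th_f, 2 * fold_step):
            continue
        try:
            curve = trace_fold_curve(family, (z[:2], th_f), box=box, step=fold_step)
        except ValueError:
            continue
        if curve.closed and len(curve) < 120:
            # small closed component (e.g. a deltoid): retrace finely so its
            # cusps are resolved
            curve = trace_fold_curve(
                family, (z[:2], th_f), box=box, step=max(fold_step / 10, 1e-4)
            )
        if len(curve) >= 3:
            fold_curves.append(curve)

    # ---- cusp points -----------------------------------------------------
    cusp_points: list[CuspPoint] = []
    for c in fold_curves:
        if len(c) >= 10:
            cusp_points.extend(detect_cusps(c, family))

    # ---- flip curves -----------------------------------------------------
    flip_curves: list[FlipCurve] = []

    def near_existing_flip(th, tol):
        for c in flip_curves:
            if np.min(np.linalg.norm(c.points - th, axis=1)) < tol:
                return True
        return False

    pairs = [((i, j), (i + 1, j)) for i in range(n - 1) for j in range(n)]
    pairs += [((i, j), (i, j + 1)) for i in range(n) for j in range(n - 1)]
    for u_idx, v_idx in pairs:
        if sig_grid[u_idx] != sig_grid[v_idx]:
            continue
        if not (complete_grid[u_idx] and complete_grid[v_idx]):
            continue
        if edges_grid[u_idx] == edges_grid[v_idx]:
            continue
        th_u = np.array([avals[u_idx[0]], bvals[u_idx[1]]])
        th_v = np.array([avals[v_idx[0]], bvals[v_idx[1]]])
        if near_existing_flip(0.5 * (th_u + th_v), np.linalg.norm(th_v - th_u)):
            continue
        # pick the saddle whose branch destination changes: try each saddle
        found = None
        from .geometry import _unstable_direction

        for rp in rps_grid[u_idx]:
            if rp.kind != "saddle1":
                continue
            u_dir = _unstable_direction(model, rp, theta=th_u)
            for sgn in (+1.0, -1.0):
                try:
                    th_star, tracker = locate_flip(
                        family, th_u, th_v, rp.position, sgn * u_dir, metric=metric
                    )
                    found = (th_star, rp.position, sgn * u_dir)
                    break
                except (NoFlipError, FoldInterferenceError):
                    continue
            if found:
                break
        if not found:
            continue
        th_star, spos, sdir = found
        if near_existing_flip(th_star, flip_step):
            continue
        curve = trace_flip_curve(
            family, th_star, spos, sdir, box=box, step=flip_step, metric=metric
        )
        if len(curve.points) < 2:
            continue
        # drop retraces of an already-known curve (e.g. the other branch of
        # the same saddle flipping on the same locus)
        overlap = 0
        for c in flip_curves:
            d = np.linalg.norm(curve.points[:, None, :] - c.points[None, :, :], axis=2)
            overlap = max(overlap, float(np.mean(d.min(axis=1) < flip_step)))
        if overlap > 0.5:
            continue
        flip_curves.append(curve)

    # ---- regions ---------------------------------------------------------
    all_polylines = [c.points for c in fold_curves if len(c) >= 2]

    span = max(box[0, 1] - box[0, 0], box[1, 1] - box[1, 0])

    def _snap_to_folds(poly):
        """Close the small gaps left at flip-curve endpoints.

        Flip tracing stops one step short of the fold (or box edge) on which
        the curve terminates; the residual gap would otherwise leave the two
        sides of the flip curve connected in the region graph.  Endpoints are
        extended onto the nearest fold curve when one is close, otherwise
        pushed through the box boundary along the final tangent.
        """
        pts = [poly[i] for i in range(len(poly))]
        for end, idx in ((0, 0), (1, len(pts) - 1)):
            p = pts[idx]
            best, bd = None, np.inf
            for fc in fold_curves:
                d = np.linalg.norm(fc.points - p, axis=1)
                k = int(np.argmin(d))
                if d[k] < bd:
                    best, bd = fc.points[k], d[k]
            ext = None
            if best is not None and bd < 3 * flip_step:
                ext = best
            else:
                d_box = min(
                    p[0] - box[0, 0], box[0, 1] - p[0], p[1] - box[1, 0], box[1, 1] - p[1]
                )
                if d_box < 3 * flip_step and len(pts) >= 2:
                    t = p - pts[idx - 1 if end else idx + 1]
                    nt = np.linalg.norm(t)
                    if nt > 0:
                        ext = p + (2 * d_box + 0.05 * span) * t / nt
            if ext is not None:
                if end == 0:
                    pts.insert(0, ext)
                else:
                    pts.append(ext)
        return np.asarray(pts)

    flip_polylines = [_snap_to_folds(c.points) for c in flip_curves if len(c.points) >= 2]

    # flip seeds lie exactly on the grid lines they were seeded from, which
    # makes the strict segment-crossing test degenerate; nudge such vertices
    def _nudged(polys):
        out = [np.array(poly, float, copy=True) for poly in polys]
        for poly in out:
            for vals, col in ((avals, 0), (bvals, 1)):
                hits = np.isclose(poly[:, col][:, None], vals[None, :], atol=1e-6).any(axis=1)
                poly[hits, col] += 1e-5 * span
        return out

    fold_polylines = _nudged(all_polylines)
    flip_polylines = _nudged(flip_polylines)

    def grid_pt(idx):
        return np.array([avals[idx[0]], bvals[idx[1]]])

    def separated(u_idx, v_idx, polys):
        p, q = grid_pt(u_idx), grid_pt(v_idx)
        return any(_segments_cross(p, q, poly) for poly in polys)

    # regions: connected components of the grid graph with equal rest-point
    # signature, cut by fold curves only (the rest-point structure is
    # constant inside); flip curves may cross a region's interior
    parent = {k: k for k in sig_grid}

    def find(k):
        while parent[k] != k:
            parent[k] = parent[parent[k]]
            k = parent[k]
        return k

    for u_idx, v_idx in pairs:
        if sig_grid[u_idx] == sig_grid[v_idx] and not separated(u_idx, v_idx, fold_polylines):
            parent[find(u_idx)] = find(v_idx)

    comps: dict = {}
    for k in sig_grid:
        comps.setdefault(find(k), []).append(k)

    def code(edges, natt):
        return f"n{natt}|" + ";".join(sorted(f"{a}-{b}" for a, b in edges))

    regions = []
    crossed_flags = []
    for root, nodes in sorted(comps.items()):
        natt = sig_grid[nodes[0]][0]
        node_set = set(nodes)
        crossed = any(
            u in node_set and v in node_set and separated(u, v, flip_polylines)
            for u, v in pairs
        )
        probes = nodes[:: max(1, len(nodes) // 3)][:3]
        codes = {code(edges_grid[p], sig_grid[p][0]) for p in probes}
        # probe codes legitimately differ across a crossing flip curve
        ambiguous = len(codes) > 1 and not crossed
        pts = np.array([[avals[i], bvals[j]] for i, j in nodes])
        regions.append(
            Region(
                label=f"R{len(regions)}",
                grid_nodes=pts,
                n_attractors=natt,
                decision_code=sorted(codes)[0],
                ambiguous=ambiguous,
            )
        )
        crossed_flags.append(crossed)

    # ---- archetypes ------------------------------------------------------
    spacing = max(
        (box[0, 1] - box[0, 0]) / (n - 1),
        (box[1, 1] - box[1, 0]) / (n - 1),
    )
    # per-axis spacings for anisotropic boxes
    d_ab = np.array([(box[0, 1] - box[0, 0]) / n, (box[1, 1] - box[1, 0]) / n])
    for r, crossed_by_flip in zip(regions, crossed_flags):
        if r.ambiguous:
            r.archetype = "ambiguous"
            continue
        if r.n_attractors == 1:
            r.archetype = "monostable"
        elif r.n_attractors == 2:
            r.archetype = "bistable"
        elif r.n_attractors == 3:
            dual_on_boundary = any(
                c.kind == "dual"
                and np.min(np.linalg.norm((r.grid_nodes - c.location) / d_ab, axis=1)) < 2.5
                for c in cusp_points
            )
            if crossed_by_flip:
                r.archetype = "binary_flip"
            elif dual_on_boundary:
                r.archetype = "binary_choice"
            else:
                r.archetype = "tristable_other"
        else:
            r.archetype = f"{r.n_attractors}_attractors"

    return BifurcationSet(
        fold_curves=fold_curves,
        flip_curves=flip_curves,
        cusp_points=cusp_points,
        regions=regions,
        box=box,
    )
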