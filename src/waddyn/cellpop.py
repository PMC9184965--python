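"""Stochastic cell populations on a landscape and their fate statistics.

A population of cells is integrated through a (possibly time-dependent)
landscape with additive noise; at chosen recording times each cell is
assigned a *fate* by relaxing its state deterministically to an attractor of
the instantaneous landscape.  Fate names are kept consistent across
conditions and times through a position-based attractor registry, so
proportions can be compared and fitted across an experiment.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import __version__
from .families import LandscapeModel, SignalPath
from .flow import _metric_solver, relax_batch
from .geometry import find_rest_points

__all__ = [
    "PopulationCondition",
    "FateRegistry",
    "FateTable",
    "simulate_population",
    "fate_proportions",
    "synth_dataset",
]

#: states further than this from every attractor after relaxation are
#: reported as undecided rather than force-assigned
UNDECIDED = "undecided"
FATE_MATCH_RADIUS = 0.75


@dataclass
class PopulationCondition:
    """One experimental condition: a named signal protocol.

    ``theta_fn`` (``t -> theta`` of shape ``(n_params,)`` or
    ``(n_cells, n_params)``) overrides ``path`` and allows per-cell signals.
    """

    name: str
    path: SignalPath | None = None
    theta_fn: object | None = None
    t_end: float | None = None

    def theta_at(self, t: float, n_cells: int) -> np.ndarray:
        if self.theta_fn is not None:
            th = np.asarray(self.theta_fn(t), float)
        elif self.path is not None:
            th = self.path(t)
        else:
            raise ValueError(f"condition {self.name!r} has neither path nor theta_fn")
        if th.ndim == 1:
            return th
        if th.shape[0] != n_cells:
            raise ValueError(
                f"per-cell theta for condition {self.name!r} has leading size "
                f"{th.shape[0]}, expected {n_cells}"
            )
        return th

    @property
    def duration(self) -> float:
        if self.t_end is not None:
            return float(self.t_end)
        if self.path is not None:
            return float(self.path.t_end)
        raise ValueError(f"condition {self.name!r} needs an explicit t_end")


class FateRegistry:
    """Stable fate names for attractors matched by position proximity.

    Attractors seen within ``radius`` of a known fate's last position take
    that fate's name (and refresh the stored position); otherwise a new name
    ``fate_k`` is issued in discovery order.
    """

    def __init__(self, radius: float = FATE_MATCH_RADIUS):
        self.radius = radius
        self._positions: dict[str, np.ndarray] = {}

    def name_of(self, position) -> str:
        position = np.asarray(position, float)
        best, best_d = None, np.inf
        for name, pos in self._positions.items():
            d = float(np.linalg.norm(position - pos))
            if d < best_d:
                best, best_d = name, d
        if best is not None and best_d < self.radius:
            self._positions[best] = position.copy()
            return best
        name = f"fate_{len(self._positions)}"
        self._positions[name] = position.copy()
        return name

    @property
    def fates(self) -> list:
        return list(self._positions)


@dataclass
class FateTable:
    """Per-cell fate assignments with provenance metadata."""

    frame: pd.DataFrame  # condition, time, cell, x1, x2, fate
    metadata: dict = field(default_factory=dict)

    def proportions(self) -> pd.DataFrame:
        return fate_proportions(self.frame)

    def to_csv(self, path) -> None:
        """Write the table as CSV with a JSON metadata sidecar."""
        self.frame.to_csv(path, index=False)
        side = str(path) + ".meta.json"
        with open(side, "w") as fh:
            json.dump(self.metadata, fh, indent=1, default=str)

    @classmethod
    def from_csv(cls, path) -> "FateTable":
        frame = pd.read_csv(path)
        meta = {}
        try:
            with open(str(path) + ".meta.json") as fh:
                meta = json.load(fh)
        except FileNotFoundError:
            pass
        return cls(frame=frame, metadata=meta)


def _label_states(model, X, theta_ref, registry):
    """Relax recorded states at frozen parameters and name their fates.

    ``theta_ref`` may be one parameter vector for the whole batch or one row
    per cell; all cells are relaxed in one batched call either way.  A cell's
    relaxed state is accepted as an attractor when its gradient has (almost)
    vanished and the Hessian there is positive definite; the fate name then
    comes from the position registry.  Cells whose relaxation stalls away
    from an attractor (flat stretches, near-degenerate points) stay
    undecided rather than being force-assigned.
    """
    theta_ref = np.asarray(theta_ref, float)
    n = X.shape[0]
    fates = np.array([UNDECIDED] * n, dtype=object)
    # a 0.1 move cap keeps the capped midpoint rule's per-step error around
    # 1e-3, far below both attractor spacing and the naming radius
    final = relax_batch(model, X, theta=theta_ref, v_tol=1e-5, max_move=0.1, dt=0.3)
    grad = model.family.gradient(final, theta_ref)
    hess = model.family.hessian(final, theta_ref)
    # positive definite iff positive trace and determinant (symmetric 2x2)
    det = hess[..., 0, 0] * hess[..., 1, 1] - hess[..., 0, 1] * hess[..., 1, 0]
    tr = hess[..., 0, 0] + hess[..., 1, 1]
    at_attractor = (np.linalg.norm(grad, axis=-1) < 1e-4) & (det > 0) & (tr > 0)
    # cells in one basin relax to identical positions (to ~1e-4); name each
    # distinct relaxed position once instead of each cell
    idx = np.flatnonzero(at_attractor)
    if idx.size:
        uniq, inv = np.unique(np.round(final[idx], 2), axis=0, return_inverse=True)
        names = np.array(
            [registry.name_of(final[idx[inv == g][0]]) for g in range(uniq.shape[0])],
            dtype=object,
        )
        fates[idx] = names[inv]
    return fates


def simulate_population(
    model: LandscapeModel,
    conditions,
    n_cells: int = 200,
    x0_center=None,
    x0_spread: float = 0.1,
    dt: float = 0.01,
    seed: int = 0,
    record_times=None,
    registry: FateRegistry | None = None,
) -> FateTable:
    """Simulate a noisy population per condition and label fates.

    Each condition draws its own independent random stream derived from the
    master ``seed`` (results per condition do not depend on which other
    conditions are run).  ``x0_center`` defaults to the attractor of the
    initial landscape with the highest potential (the progenitor-like
    state); cells start in an isotropic Gaussian ball around it.
    ``record_times`` defaults to each condition's end time.  Per-cell fates
    are assigned by deterministic relaxation at the recorded instant;
    unassignable cells are ``undecided``.
    """
    conditions = list(conditions)
    if not conditions:
        raise ValueError("need at least one condition")
    names = [c.name for c in conditions]
    if len(set(names)) != len(names):
        raise ValueError("condition names must be unique")
    registry = FateRegistry() if registry is None else registry
    rows = []
    ss = np.random.SeedSequence(seed)
    streams = ss.spawn(len(conditions))
    for cond, stream in zip(conditions, streams):
        rng = np.random.default_rng(stream)
        theta0 = np.atleast_2d(cond.theta_at(0.0, n_cells))[0]
        if x0_center is None:
            rps = find_rest_points(model, theta=theta0)
            atts = [rp for rp in rps if rp.is_attractor]
            if not atts:
                raise ValueError(
                    f"no attractor at t=0 for condition {cond.name!r}; "
                    "pass x0_center explicitly"
                )
            start = max(atts, key=lambda rp: rp.potential).position
        else:
            start = np.asarray(x0_center, float)
        X = start[None, :] + x0_spread * rng.standard_normal((n_cells, model.family.dim))
        t_end = cond.duration
        rec = [t_end] if record_times is None else sorted(record_times)
        n_steps = int(round(t_end / dt))
        rec_steps = {int(round(t / dt)): t for t in rec if t <= t_end + 1e-9}
        t = 0.0
        if 0 in rec_steps:
            rows.append((cond, rec_steps[0], X.copy()))
        solver = _metric_solver(model)
        noise = model.sigma * np.sqrt(dt)
        for k in range(n_steps):
            theta = cond.theta_at(t, n_cells)
            X = X + dt * solver(X, model.family.gradient(X, theta))
            if model.sigma > 0:
                X = X + noise * rng.standard_normal(X.shape)
            t = (k + 1) * dt
            if (k + 1) in rec_steps:
                rows.append((cond, rec_steps[k + 1], X.copy()))

    records = []
    for cond, t_rec, X in rows:
        theta_ref = cond.theta_at(t_rec, X.shape[0])
        fates = _label_states(model, X, theta_ref, registry)
        for i in range(X.shape[0]):
            records.append(
                {
                    "condition": cond.name,
                    "time": t_rec,
                    "cell": i,
                    "x1": X[i, 0],
                    "x2": X[i, 1],
                    "fate": fates[i],
                }
            )
    frame = pd.DataFrame.from_records(records)
    meta = {
        "seed": seed,
        "n_cells": n_cells,
        "dt": dt,
        "sigma": model.sigma,
        "family": model.family.name,
        "package_version": __version__,
        "fate_positions": {
            k: v.tolist() for k, v in registry._positions.items()
        },
    }
    return FateTable(frame=frame, metadata=meta)


def pulse_theta_fn(
    theta_base,
    amplitudes,
    component: int = 1,
    t_up: float = 2.0,
    t_hold: float = 20.0,
    t_down: float = 2.0,
):
    """Per-cell trapezoidal signal pulse added to one parameter component.

    Cell ``i`` receives ``theta_base`` plus ``amplitudes[i]`` on the chosen
    component, ramped up over ``t_up``, held for ``t_hold`` and ramped back
    down over ``t_down``; afterwards the signal stays at baseline.  Returns
    ``(theta_fn, t_off)`` where ``t_off`` is the instant the pulse ends.
    """
    theta_base = np.asarray(theta_base, float)
    amplitudes = np.asarray(amplitudes, float)
    t1, t2, t3 = t_up, t_up + t_hold, t_up + t_hold + t_down

    def theta_fn(t):
        if t <= t1:
            w = t / t1 if t1 > 0 else 1.0
        elif t <= t2:
            w = 1.0
        elif t <= t3:
            w = (t3 - t) / t_down if t_down > 0 else 0.0
        else:
            w = 0.0
        th = np.broadcast_to(theta_base, (amplitudes.size, theta_base.size)).copy()
        th[:, component] += amplitudes * w
        return th

    return theta_fn, t3


def fate_proportions(frame: pd.DataFrame) -> pd.DataFrame:
    """Fraction of cells per fate for each (condition, time).

    Returns a tidy frame with columns condition, time, fate, proportion, n.
    """
    out = []
    for (cond, t), grp in frame.groupby(["condition", "time"], sort=True):
        n = len(grp)
        for fate, cnt in grp["fate"].value_counts().items():
            out.append(
                {
                    "condition": cond,
                    "time": t,
                    "fate": fate,
                    "proportion": cnt / n,
                    "n": n,
                }
            )
    return pd.DataFrame(out)


def synth_dataset(proportions: pd.DataFrame, n_per_condition: int, seed: int = 0) -> pd.DataFrame:
    """Resample observed fate counts from proportions (multinomial noise).

    Produces a synthetic measured dataset with the same tidy layout as
    :func:`fate_proportions`, with ``n`` set to ``n_per_condition``.
    """
    rng = np.random.default_rng(seed)
    out = []
    for (cond, t), grp in proportions.groupby(["condition", "time"], sort=True):
        p = grp["proportion"].to_numpy()
        p = p / p.sum()
        counts = rng.multinomial(n_per_condition, p)
        for fate, cnt in zip(grp["fate"], counts):
            out.append(
                {
                    "condition": cond,
                    "time": t,
                    "fate": fate,
                    "proportion": cnt / n_per_condition,
                    "n": n_per_condition,
                }
            )
    return pd.DataFrame(out)
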