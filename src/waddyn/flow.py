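"""Time evolution of a landscape model.

Deterministic trajectories solve ``x' = -G(x)^{-1} grad F(x, theta(t))`` with
an adaptive Runge-Kutta integrator; the potential is a Lyapunov function of
this flow whenever the parameters are frozen, so potential values along such
trajectories never increase (up to integrator tolerance).  Stochastic
trajectories add isotropic additive Gaussian noise of amplitude ``sigma`` and
are integrated with fixed-step Euler-Maruyama.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp

from .families import LandscapeModel, SignalPath

__all__ = ["Trajectory", "vector_field", "integrate", "simulate_sde"]

#: speed below which a trajectory is declared converged to a rest point
V_CONVERGED = 1e-8
#: radius within which a converged state is attributed to an attractor
ATTRACTOR_RADIUS = 1e-3


@dataclass
class Trajectory:
    """Sampled solution of the flow with its parameter trace."""

    times: np.ndarray
    states: np.ndarray  # (n_times, dim)
    theta_trace: np.ndarray  # (n_times, n_params)
    terminal_flag: str  # converged | max_time | escaped_domain

    @property
    def final_state(self) -> np.ndarray:
        return self.states[-1]

    def to_frame(self):
        import pandas as pd

        dim = self.states.shape[1]
        data = {"t": self.times}
        for j in range(dim):
            data[f"x{j + 1}"] = self.states[:, j]
        for j in range(self.theta_trace.shape[1]):
            data[f"theta{j + 1}"] = self.theta_trace[:, j]
        return pd.DataFrame(data)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def _metric_solver(model: LandscapeModel):
    """Return a function mapping a batch of gradients at points to velocities."""
    if model.metric.is_constant:
        g = model.metric.constant_matrix()
        if np.allclose(g, np.eye(model.family.dim)):
            return lambda x, grad: -grad
        ginv = np.linalg.inv(g)
        return lambda x, grad: -grad @ ginv.T
    metric = model.metric

    def solve(x, grad):
        gmat = metric.evaluate(x)
        return -np.linalg.solve(gmat, grad[..., None])[..., 0]

    return solve


def vector_field(model: LandscapeModel, x, theta=None) -> np.ndarray:
    """Velocity ``v`` solving ``G(x) v = -grad F(x, theta)``.

    Accepts batched phase points of shape ``(..., dim)``.
    """
    th = model.theta if theta is None else theta
    x = np.asarray(x, float)
    grad = model.family.gradient(x, th)
    return _metric_solver(model)(x, grad)


def _escape_box(model: LandscapeModel) -> np.ndarray:
    """Domain box inflated by a factor 2 about its centre."""
    box = model.family.domain_box
    centre = box.mean(axis=1)
    half = (box[:, 1] - box[:, 0]) / 2.0
    return np.stack([centre - 2 * half, centre + 2 * half], axis=1)


def integrate(
    model: LandscapeModel,
    x0,
    path: SignalPath | None = None,
    t_end: float | None = None,
    tol: float = 1e-8,
    max_step: float = np.inf,
) -> Trajectory:
    """Adaptive-step deterministic trajectory from ``x0``.

    With no ``path`` the model's own (frozen) parameters are used.  The run
    terminates early when the speed drops below ``V_CONVERGED`` (flag
    ``converged``) or when the state leaves the doubled domain box (flag
    ``escaped_domain``).
    """
    if path is None:
        path = SignalPath.constant(model.theta, t_end=t_end if t_end else 1.0)
    if t_end is None:
        t_end = path.t_end
    if t_end <= 0:
        raise ValueError("t_end must be positive")
    solver = _metric_solver(model)
    family = model.family
    esc = _escape_box(model)

    def rhs(t, y):
        return solver(y, family.gradient(y, path(t)))

    def ev_converged(t, y):
        return float(np.linalg.norm(rhs(t, y))) - V_CONVERGED

    ev_converged.terminal = True
    ev_converged.direction = -1

    def ev_escaped(t, y):
        return float(np.min(np.minimum(y - esc[:, 0], esc[:, 1] - y)))

    ev_escaped.terminal = True
    ev_escaped.direction = -1

    sol = solve_ivp(
        rhs,
        (0.0, float(t_end)),
        np.asarray(x0, float),
        method="RK45",
        rtol=tol,
        atol=tol,
        max_step=max_step,
        events=[ev_converged, ev_escaped],
        dense_output=False,
    )
    flag = "max_time"
    if sol.t_events[0].size:
        flag = "converged"
    elif sol.t_events[1].size:
        flag = "escaped_domain"
    times = sol.t
    states = sol.y.T
    return Trajectory(times, states, path(times), flag)


def simulate_sde(
    model: LandscapeModel,
    x0,
    path: SignalPath | None = None,
    t_end: float | None = None,
    dt: float = 1e-3,
    seed: int = 0,
    record_every: int = 1,
) -> Trajectory:
    """Euler-Maruyama trajectory with isotropic additive noise.

    The drift is the metric gradient field; the diffusion is ``sigma`` times
    unit-variance white noise on each coordinate (the noise is not
    metric-transformed).  Identical seeds give identical trajectories.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if path is None:
        path = SignalPath.constant(model.theta, t_end=t_end if t_end else 1.0)
    if t_end is None:
        t_end = path.t_end
    rng = np.random.default_rng(seed)
    n_steps = int(round(t_end / dt))
    solver = _metric_solver(model)
    family = model.family
    x = np.asarray(x0, float).copy()
    sqdt = np.sqrt(dt) * model.sigma

    times = [0.0]
    states = [x.copy()]
    t = 0.0
    for k in range(n_steps):
        v = solver(x, family.gradient(x, path(t)))
        x = x + dt * v
        if model.sigma > 0:
            x = x + sqdt * rng.standard_normal(x.shape)
        t = (k + 1) * dt
        if (k + 1) % record_every == 0 or k == n_steps - 1:
            times.append(t)
            states.append(x.copy())
    times = np.asarray(times)
    states = np.asarray(states)
    return Trajectory(times, states, path(times), "max_time")


def sde_step_batch(model: LandscapeModel, X, theta, dt: float, rng) -> np.ndarray:
    """One Euler-Maruyama step for a batch of states (internal fast path)."""
    solver = _metric_solver(model)
    V = solver(X, model.family.gradient(X, theta))
    X = X + dt * V
    if model.sigma > 0:
        X = X + model.sigma * np.sqrt(dt) * rng.standard_normal(X.shape)
    return X


def relax_batch(
    model: LandscapeModel,
    X,
    theta=None,
    max_steps: int = 4000,
    dt: float = 0.05,
    max_move: float = 0.05,
    v_tol: float = 1e-8,
) -> np.ndarray:
    """Flow a batch of points downhill to (near) rest with a capped midpoint rule.

    Used for basin assignment and branch destinations where only the endpoint
    matters.  The per-point step is limited so no point moves more than
    ``max_move`` per step, which keeps the stiff confining region stable.
    A point also counts as converged when its local step collapses to the
    potential's rounding floor (no further descent is representable).

    ``theta`` may be a single parameter vector or one row per point.
    """
    th = model.theta if theta is None else np.asarray(theta, float)
    per_point = th.ndim == 2
    solver = _metric_solver(model)
    family = model.family
    X = np.array(X, float, copy=True)
    if per_point and th.shape[0] != X.shape[0]:
        raise ValueError("per-point theta must have one row per point")
    active = np.ones(X.shape[0], dtype=bool)
    h_loc = np.full(X.shape[0], dt)
    for _ in range(max_steps):
        if not active.any():
            break
        Xa = X[active]
        ha = h_loc[active]
        tha = th[active] if per_point else th
        V = solver(Xa, family.gradient(Xa, tha))
        speed = np.linalg.norm(V, axis=-1)
        done = (speed < v_tol) | (ha < dt * 1e-6)
        h = np.minimum(ha, max_move / np.maximum(speed, 1e-300))[:, None]
        Xm = Xa + 0.5 * h * V
        Vm = solver(Xm, family.gradient(Xm, tha))
        Xnew = Xa + h * Vm
        # enforce descent of the Lyapunov potential; halve the local step on failure
        rose = family.evaluate(Xnew, tha) > family.evaluate(Xa, tha)
        Xnew[rose] = Xa[rose]
        # the local step may grow well beyond dt (important in shallow wells,
        # where the linear convergence rate scales with the step); stability
        # is maintained by the descent check above and the max_move cap
        ha = np.where(rose, ha * 0.5, np.minimum(ha * 1.2, 40 * dt))
        Xnew[done] = Xa[done]
        X[active] = Xnew
        h_loc[active] = ha
        idx = np.flatnonzero(active)
        active[idx[done]] = False
    return X
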