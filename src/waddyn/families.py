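"""Potential families, Riemannian metrics and the composite landscape model.

A landscape model couples three ingredients:

* a *potential family* ``F(x; theta)`` -- a smooth confining function of the
  phase point ``x`` (two-dimensional here) depending on one or two unfolding
  parameters that stand in for extrinsic signals;
* a *Riemannian metric* ``G(x)`` -- a symmetric positive-definite matrix field
  that converts the potential into dynamics ``x' = -G(x)^{-1} grad F(x, theta)``;
* a scalar noise amplitude ``sigma`` for stochastic simulation.

The built-in catalogue contains the canonical unfoldings used throughout the
package: the compactified elliptic umbilic, a fixed worked example of it with
two different metrics, and the standard-cusp and dual-cusp normal forms
embedded in two dimensions.  All catalogue potentials are polynomials with a
quartic-or-higher confining term, so gradients and Hessians are exact and all
rest points sit inside a bounded box.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "PotentialFamily",
    "RiemannianMetric",
    "LandscapeModel",
    "SignalPath",
    "make_family",
    "eval_metric",
    "eval_potential",
    "eval_gradient",
    "eval_hessian",
    "CATALOGUE",
    "MetricError",
    "UnknownFamilyError",
]

Array = np.ndarray


class UnknownFamilyError(KeyError):
    """Requested family name is not in the built-in catalogue."""


class MetricError(ValueError):
    """A metric matrix failed the symmetric-positive-definite check."""


def _as_points(x: Sequence[float] | Array, dim: int) -> Array:
    """Coerce ``x`` to a float array whose last axis is the phase dimension."""
    arr = np.asarray(x, dtype=float)
    if arr.shape == () or arr.shape[-1] != dim:
        raise ValueError(f"expected phase points with last axis {dim}, got shape {arr.shape}")
    return arr


@dataclass(frozen=True)
class PotentialFamily:
    """A parametrized potential ``F(x; theta)`` with exact derivatives.

    ``evaluate``, ``gradient`` and ``hessian`` accept phase points of shape
    ``(..., dim)`` plus a parameter vector of length ``n_params`` and return
    arrays of shape ``(...)``, ``(..., dim)`` and ``(..., dim, dim)``.
    """

    name: str
    n_params: int
    _evaluate: Callable[[Array, Array], Array]
    _gradient: Callable[[Array, Array], Array]
    _hessian: Callable[[Array, Array], Array]
    domain_box: Array
    param_box: Array
    dim: int = 2

    def _theta(self, theta: Sequence[float] | None) -> Array:
        """Validate a parameter vector, or a batch of them (last axis n_params)."""
        th = np.zeros(self.n_params) if theta is None else np.atleast_1d(np.asarray(theta, float))
        if th.ndim == 0 or th.shape[-1] != self.n_params:
            raise ValueError(
                f"family {self.name!r} takes {self.n_params} parameters, got {th.shape}"
            )
        return th

    def evaluate(self, x, theta=None) -> Array:
        return self._evaluate(_as_points(x, self.dim), self._theta(theta))

    def gradient(self, x, theta=None) -> Array:
        return self._gradient(_as_points(x, self.dim), self._theta(theta))

    def hessian(self, x, theta=None) -> Array:
        return self._hessian(_as_points(x, self.dim), self._theta(theta))


def _stack_sym2(axx, axy, ayy) -> Array:
    """Assemble a symmetric 2x2 matrix field from its three components."""
    axx, axy, ayy = np.broadcast_arrays(axx, axy, ayy)
    out = np.empty(axx.shape + (2, 2))
    out[..., 0, 0] = axx
    out[..., 0, 1] = axy
    out[..., 1, 0] = axy
    out[..., 1, 1] = ayy
    return out


# --------------------------------------------------------------------------
# catalogue definitions
# --------------------------------------------------------------------------

def _elliptic_umbilic(a_fixed=None, b_fixed=None, param_box=None, name="elliptic_umbilic"):
    """Compactified elliptic umbilic: x^3 - 2xy^2 - 0.4x^2 + ax + by + (x^4+y^4)/4.

    The quartic term confines the phase space; without it the cubic umbilic
    germ sends trajectories to infinity.  ``a_fixed``/``b_fixed`` freeze the
    unfolding parameters (used by the Box-2 style worked example).
    """
    fixed = a_fixed is not None

    def split(theta):
        if fixed:
            return a_fixed, b_fixed
        # supports a single (2,) vector or a per-point batch (..., 2)
        return theta[..., 0], theta[..., 1]

    def ev(x, theta):
        a, b = split(theta)
        X, Y = x[..., 0], x[..., 1]
        return (
            X**3 - 2.0 * X * Y**2 - 0.4 * X**2 + a * X + b * Y + 0.25 * (X**4 + Y**4)
        )

    def gr(x, theta):
        a, b = split(theta)
        X, Y = x[..., 0], x[..., 1]
        gx = 3.0 * X**2 - 2.0 * Y**2 - 0.8 * X + a + X**3
        gy = -4.0 * X * Y + b + Y**3
        return np.stack([gx, gy], axis=-1)

    def he(x, theta):
        X, Y = x[..., 0], x[..., 1]
        return _stack_sym2(6.0 * X - 0.8 + 3.0 * X**2, -4.0 * Y, -4.0 * X + 3.0 * Y**2)

    return PotentialFamily(
        name=name,
        n_params=0 if fixed else 2,
        _evaluate=ev,
        _gradient=gr,
        _hessian=he,
        domain_box=np.array([[-6.0, 6.0], [-6.0, 6.0]]),
        param_box=np.array([[-3.0, 3.0], [-3.0, 3.0]]) if param_box is None else np.asarray(param_box, float),
    )


def _cusp1d():
    """Standard cusp unfolding x^4/4 + a x^2/2 + b x, embedded with + y^2/2."""

    def ev(x, theta):
        a, b = theta[..., 0], theta[..., 1]
        X, Y = x[..., 0], x[..., 1]
        return 0.25 * X**4 + 0.5 * a * X**2 + b * X + 0.5 * Y**2

    def gr(x, theta):
        a, b = theta[..., 0], theta[..., 1]
        X, Y = x[..., 0], x[..., 1]
        return np.stack([X**3 + a * X + b, Y], axis=-1)

    def he(x, theta):
        a = theta[..., 0]
        X = x[..., 0]
        return _stack_sym2(3.0 * X**2 + a, np.zeros_like(X), np.ones_like(X))

    return PotentialFamily(
        name="cusp1d",
        n_params=2,
        _evaluate=ev,
        _gradient=gr,
        _hessian=he,
        domain_box=np.array([[-4.0, 4.0], [-2.0, 2.0]]),
        param_box=np.array([[-3.0, 3.0], [-3.0, 3.0]]),
    )


def _dual_cusp1d():
    """Dual cusp with sextic confinement: x^6/6 - x^4/4 + a x^2/2 + b x + y^2/2.

    The reversed-sign quartic makes the interior of the dual cusp tristable:
    a central attractor flanked by two saddles, with confining peripheral
    attractors supplied by the sextic term.
    """

    def ev(x, theta):
        a, b = theta[..., 0], theta[..., 1]
        X, Y = x[..., 0], x[..., 1]
        return X**6 / 6.0 - 0.25 * X**4 + 0.5 * a * X**2 + b * X + 0.5 * Y**2

    def gr(x, theta):
        a, b = theta[..., 0], theta[..., 1]
        X, Y = x[..., 0], x[..., 1]
        return np.stack([X**5 - X**3 + a * X + b, Y], axis=-1)

    def he(x, theta):
        a = theta[..., 0]
        X = x[..., 0]
        return _stack_sym2(5.0 * X**4 - 3.0 * X**2 + a, np.zeros_like(X), np.ones_like(X))

    return PotentialFamily(
        name="dual_cusp1d",
        n_params=2,
        _evaluate=ev,
        _gradient=gr,
        _hessian=he,
        domain_box=np.array([[-3.0, 3.0], [-2.0, 2.0]]),
        param_box=np.array([[-3.0, 3.0], [-3.0, 3.0]]),
    )


def _catalogue_builders():
    return {
        "elliptic_umbilic": lambda **kw: _elliptic_umbilic(**kw),
        "box2_example": lambda **kw: _elliptic_umbilic(
            a_fixed=-3.0, b_fixed=-1.0, name="box2_example", **kw
        ),
        "cusp1d": lambda **kw: _cusp1d(**kw),
        "dual_cusp1d": lambda **kw: _dual_cusp1d(**kw),
        # parameter window of the symmetric binary-flip landscape around its
        # organising centre: contains the closed fold loop with its three
        # cusps, the flip curve along b = 0 and the flip's termination on the
        # fold loop
        "flip_with_cusp": lambda **kw: _elliptic_umbilic(
            name="flip_with_cusp",
            param_box=np.array([[-0.5, 0.3], [-0.2, 0.2]]),
            **kw,
        ),
    }


CATALOGUE = tuple(sorted(_catalogue_builders()))


def make_family(name: str, **options) -> PotentialFamily:
    """Return a catalogue potential family by name.

    Raises :class:`UnknownFamilyError` listing the valid names otherwise.
    Options (e.g. ``param_box``) override the catalogue defaults.
    """
    builders = _catalogue_builders()
    if name not in builders:
        raise UnknownFamilyError(
            f"unknown family {name!r}; catalogue: {', '.join(CATALOGUE)}"
        )
    return builders[name](**options)


# --------------------------------------------------------------------------
# metrics
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class RiemannianMetric:
    """A field of symmetric positive-definite matrices ``G(x)``.

    The metric reshapes trajectories (and hence which attractor a saddle's
    unstable manifold reaches) without moving rest points or changing their
    Morse indices.
    """

    func: Callable[[Array], Array]
    is_constant: bool
    dim: int = 2

    @staticmethod
    def identity(dim: int = 2) -> "RiemannianMetric":
        eye = np.eye(dim)

        def f(x):
            x = np.asarray(x, float)
            return np.broadcast_to(eye, x.shape[:-1] + (dim, dim))

        return RiemannianMetric(func=f, is_constant=True, dim=dim)

    @staticmethod
    def constant(matrix) -> "RiemannianMetric":
        mat = np.asarray(matrix, float)
        _check_spd(mat)

        def f(x):
            x = np.asarray(x, float)
            return np.broadcast_to(mat, x.shape[:-1] + mat.shape)

        return RiemannianMetric(func=f, is_constant=True, dim=mat.shape[0])

    def evaluate(self, x) -> Array:
        return eval_metric(self, x)

    def constant_matrix(self) -> Array:
        if not self.is_constant:
            raise ValueError("metric is not constant")
        return np.asarray(self.func(np.zeros(self.dim)), float)


def _check_spd(mat: Array) -> None:
    if not np.allclose(mat, np.swapaxes(mat, -1, -2), atol=1e-10):
        raise MetricError("metric matrix is not symmetric")
    eigs = np.linalg.eigvalsh(mat)
    lo = float(np.min(eigs))
    if lo <= 0.0:
        raise MetricError(f"metric is not positive definite (eigenvalue {lo:g} <= 0)")


def eval_metric(metric: RiemannianMetric, x) -> Array:
    """Evaluate ``G(x)`` and validate symmetry and positive-definiteness."""
    g = np.asarray(metric.func(np.asarray(x, float)), float)
    _check_spd(g)
    return g


# --------------------------------------------------------------------------
# model + signal paths
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class LandscapeModel:
    """Potential family + metric + current parameters + noise amplitude."""

    family: PotentialFamily
    metric: RiemannianMetric = field(default_factory=RiemannianMetric.identity)
    theta: Array = None
    sigma: float = 0.0

    def __post_init__(self):
        th = self.family._theta(self.theta)
        object.__setattr__(self, "theta", th)
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        if self.metric.dim != self.family.dim:
            raise ValueError("metric and family dimensions differ")

    def with_theta(self, theta) -> "LandscapeModel":
        return LandscapeModel(self.family, self.metric, theta, self.sigma)


@dataclass(frozen=True)
class SignalPath:
    """Piecewise-linear parameter schedule theta(t).

    Signals enter the model only through the unfolding parameters, so a
    time course of signals is a path in parameter space.
    """

    t_grid: Array
    theta_knots: Array  # shape (len(t_grid), n_params)

    def __post_init__(self):
        t = np.asarray(self.t_grid, float)
        k = np.atleast_2d(np.asarray(self.theta_knots, float))
        if k.shape[0] != t.shape[0]:
            raise ValueError("t_grid and theta_knots lengths differ")
        if t.ndim != 1 or t.size < 1 or np.any(np.diff(t) <= 0):
            raise ValueError("t_grid must be strictly increasing")
        object.__setattr__(self, "t_grid", t)
        object.__setattr__(self, "theta_knots", k)

    @staticmethod
    def constant(theta, t_end: float = 1.0) -> "SignalPath":
        th = np.atleast_1d(np.asarray(theta, float))
        return SignalPath(np.array([0.0, t_end]), np.stack([th, th]))

    @property
    def t_end(self) -> float:
        return float(self.t_grid[-1])

    def theta_of_t(self, t) -> Array:
        """Linear interpolation, clamped outside the knot range."""
        t = np.asarray(t, float)
        k = self.theta_knots.shape[1]
        if k == 0:
            return np.zeros(t.shape + (0,))
        cols = [np.interp(t, self.t_grid, self.theta_knots[:, j]) for j in range(k)]
        return np.stack(cols, axis=-1)

    def __call__(self, t) -> Array:
        return self.theta_of_t(t)


def eval_potential(family: PotentialFamily, x, theta=None) -> Array:
    return family.evaluate(x, theta)


def eval_gradient(family: PotentialFamily, x, theta=None) -> Array:
    return family.gradient(x, theta)


def eval_hessian(family: PotentialFamily, x, theta=None) -> Array:
    return family.hessian(x, theta)


def finite_difference_gradient(family: PotentialFamily, x, theta=None, h: float = 1e-5) -> Array:
    """Order-2 central-difference gradient; fallback/oracle for user families."""
    x = np.asarray(x, float)
    out = np.empty_like(x)
    for j in range(family.dim):
        e = np.zeros(family.dim)
        e[j] = h
        out[..., j] = (family.evaluate(x + e, theta) - family.evaluate(x - e, theta)) / (2 * h)
    return out


def finite_difference_hessian(family: PotentialFamily, x, theta=None, h: float = 1e-4) -> Array:
    """Central-difference Hessian of the potential."""
    x = np.asarray(x, float)
    d = family.dim
    out = np.empty(x.shape[:-1] + (d, d))
    f0 = family.evaluate(x, theta)
    for i in range(d):
        ei = np.zeros(d)
        ei[i] = h
        out[..., i, i] = (
            family.evaluate(x + ei, theta) - 2 * f0 + family.evaluate(x - ei, theta)
        ) / h**2
        for j in range(i + 1, d):
            ej = np.zeros(d)
            ej[j] = h
            mixed = (
                family.evaluate(x + ei + ej, theta)
                - family.evaluate(x + ei - ej, theta)
                - family.evaluate(x - ei + ej, theta)
                + family.evaluate(x - ei - ej, theta)
            ) / (4 * h**2)
            out[..., i, j] = mixed
            out[..., j, i] = mixed
    return out
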