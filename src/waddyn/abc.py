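"""Likelihood-free fitting of landscape parameters to fate proportions.

Approximate Bayesian computation with sequential Monte Carlo (ABC-SMC):
generation 0 samples the prior; each later generation resamples the previous
particles by weight, perturbs them with a Gaussian kernel whose per-parameter
variance is twice the weighted sample variance, and accepts particles whose
simulated fate proportions fall within a shrinking tolerance (a fixed
quantile of the previous generation's accepted distances).  Every particle's
simulation uses a seed derived deterministically from the master seed, so a
fixed seed gives an identical posterior.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import __version__

__all__ = [
    "PriorSpec",
    "Posterior",
    "AlignmentError",
    "distance",
    "abc_smc",
    "posterior_summary",
    "split_by_condition",
]


class AlignmentError(ValueError):
    """Observed and simulated tables do not share comparable keys."""


@dataclass(frozen=True)
class PriorSpec:
    """Independent uniform priors, one per free parameter."""

    names: tuple
    lows: np.ndarray
    highs: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "lows", np.asarray(self.lows, float))
        object.__setattr__(self, "highs", np.asarray(self.highs, float))
        object.__setattr__(self, "names", tuple(self.names))
        if not (len(self.names) == self.lows.size == self.highs.size):
            raise ValueError("names, lows and highs must have equal length")
        if not np.all(self.lows < self.highs):
            bad = [self.names[i] for i in np.flatnonzero(~(self.lows < self.highs))]
            raise ValueError(f"lower bound must be below upper bound for: {bad}")

    @property
    def dim(self) -> int:
        return len(self.names)

    @property
    def widths(self) -> np.ndarray:
        return self.highs - self.lows

    def sample(self, rng, n: int) -> np.ndarray:
        return rng.uniform(self.lows, self.highs, size=(n, self.dim))

    def contains(self, params) -> bool:
        params = np.asarray(params, float)
        return bool(np.all(params >= self.lows) and np.all(params <= self.highs))


def _proportions_frame(table) -> pd.DataFrame:
    """Accept a FateTable, a per-cell frame, or a tidy proportions frame."""
    frame = getattr(table, "frame", table)
    if not isinstance(frame, pd.DataFrame):
        raise TypeError("expected a FateTable or DataFrame")
    if "proportion" in frame.columns:
        return frame
    from .cellpop import fate_proportions

    return fate_proportions(frame)


def distance(observed, simulated) -> float:
    """Mean absolute difference of fate proportions over matched keys.

    Keys are (condition, time, fate) triples; the key set is the union of
    both tables, with a missing fate within a shared (condition, time) group
    read as proportion zero.  A (condition, time) group present in one table
    but absent from the other cannot be compared at all and raises
    :class:`AlignmentError` naming the missing groups.  Symmetric.
    """
    obs = _proportions_frame(observed)
    sim = _proportions_frame(simulated)

    def key_map(frame):
        return {
            (r.condition, r.time, r.fate): float(r.proportion)
            for r in frame.itertuples(index=False)
        }

    def groups(frame):
        return {(r.condition, r.time) for r in frame.itertuples(index=False)}

    g_obs, g_sim = groups(obs), groups(sim)
    if g_obs != g_sim:
        missing = sorted(g_obs ^ g_sim)
        raise AlignmentError(
            f"unmatched (condition, time) groups between tables: {missing}"
        )
    m_obs, m_sim = key_map(obs), key_map(sim)
    keys = set(m_obs) | set(m_sim)
    diffs = [abs(m_obs.get(k, 0.0) - m_sim.get(k, 0.0)) for k in sorted(keys)]
    return float(np.mean(diffs))


@dataclass
class Posterior:
    """Weighted ABC-SMC particle approximation of the posterior."""

    names: tuple
    particles: np.ndarray  # (n_particles, dim)
    weights: np.ndarray  # sums to 1
    distances: np.ndarray
    epsilon_history: list
    acceptance_rates: list
    seed: int
    status: str = "ok"  # ok | early_stop
    metadata: dict = field(default_factory=dict)

    def mean(self) -> np.ndarray:
        return self.weights @ self.particles

    def variance(self) -> np.ndarray:
        mu = self.mean()
        return self.weights @ (self.particles - mu) ** 2

    def ess(self) -> float:
        return float(1.0 / np.sum(self.weights**2))

    def to_csv(self, path) -> None:
        """Particles + weights as CSV with a JSON metadata sidecar."""
        frame = pd.DataFrame(self.particles, columns=list(self.names))
        frame["weight"] = self.weights
        frame["distance"] = self.distances
        frame.to_csv(path, index=False)
        side = str(path) + ".meta.json"
        meta = {
            "seed": self.seed,
            "status": self.status,
            "epsilon_history": [
                None if not np.isfinite(e) else float(e) for e in self.epsilon_history
            ],
            "acceptance_rates": [float(a) for a in self.acceptance_rates],
            "package_version": __version__,
            **self.metadata,
        }
        with open(side, "w") as fh:
            json.dump(meta, fh, indent=1, default=str)


def abc_smc(
    simulate,
    observed,
    priors: PriorSpec,
    n_particles: int = 200,
    n_generations: int = 4,
    quantile: float = 0.3,
    seed: int = 0,
    min_acceptance: float = 1e-3,
    max_draws_per_particle: int = 2000,
) -> Posterior:
    """Standard ABC-SMC posterior for a simulator of fate proportions.

    ``simulate(params, sim_seed)`` must return a fate table (or tidy
    proportions frame) comparable with ``observed`` under :func:`distance`;
    simulations whose tables cannot be aligned count as infinitely distant.
    Generation tolerances are the ``quantile`` of the previous generation's
    accepted distances; the perturbation kernel is an independent Gaussian
    with per-parameter variance twice the weighted sample variance.  If a
    generation's acceptance rate falls below ``min_acceptance`` the run
    stops early with ``status='early_stop'`` and the last completed
    generation is returned.
    """
    if n_particles < 50:
        raise ValueError("n_particles must be at least 50")
    if not 0 < quantile < 1:
        raise ValueError("quantile must lie strictly between 0 and 1")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    sim_counter = 0

    def run_sim(params):
        nonlocal sim_counter
        s = np.random.SeedSequence((seed, 1, sim_counter))
        sim_counter += 1
        sim_seed = int(s.generate_state(1)[0] % (2**31))
        try:
            sim = simulate(params, sim_seed)
            return distance(observed, sim)
        except AlignmentError:
            return np.inf

    obs_frame = _proportions_frame(observed)  # validate once up front
    del obs_frame

    eps_history: list = []
    acc_rates: list = []
    particles = weights = dists = None
    status = "ok"
    for gen in range(n_generations):
        if gen == 0:
            eps = np.inf
            new_particles = priors.sample(rng, n_particles)
            new_dists = np.array([run_sim(p) for p in new_particles])
            new_weights = np.full(n_particles, 1.0 / n_particles)
            acc_rates.append(1.0)
        else:
            finite = dists[np.isfinite(dists)]
            if finite.size == 0:
                status = "early_stop"
                break
            eps = float(np.quantile(finite, quantile))
            mu = weights @ particles
            var = weights @ (particles - mu) ** 2
            kernel_sd = np.sqrt(np.maximum(2.0 * var, 1e-24))
            new_particles = np.empty_like(particles)
            new_weights = np.empty(n_particles)
            new_dists = np.empty(n_particles)
            draws = 0
            accepted = 0
            while accepted < n_particles:
                j = rng.choice(n_particles, p=weights)
                cand = particles[j] + kernel_sd * rng.standard_normal(priors.dim)
                draws += 1
                if not priors.contains(cand):
                    continue
                d = run_sim(cand)
                if d <= eps:
                    kern = np.exp(
                        -0.5
                        * np.sum(
                            ((cand[None, :] - particles) / kernel_sd[None, :]) ** 2,
                            axis=1,
                        )
                    )
                    denom = float(weights @ kern)
                    new_particles[accepted] = cand
                    new_weights[accepted] = 1.0 / max(denom, 1e-300)
                    new_dists[accepted] = d
                    accepted += 1
                if draws >= max_draws_per_particle * n_particles:
                    break
                if draws >= 1000 and accepted / draws < min_acceptance:
                    break
            if accepted < n_particles:
                status = "early_stop"
                acc_rates.append(accepted / max(draws, 1))
                break
            acc_rates.append(accepted / draws)
        eps_history.append(eps)
        particles, dists = new_particles, new_dists
        weights = new_weights / new_weights.sum()

    if particles is None:
        raise RuntimeError("ABC-SMC produced no completed generation")
    return Posterior(
        names=priors.names,
        particles=particles,
        weights=weights,
        distances=dists,
        epsilon_history=eps_history,
        acceptance_rates=acc_rates,
        seed=seed,
        status=status,
        metadata={
            "n_particles": n_particles,
            "n_generations_requested": n_generations,
            "quantile": quantile,
            "prior_lows": priors.lows.tolist(),
            "prior_highs": priors.highs.tolist(),
        },
    )


def posterior_summary(posterior: Posterior) -> pd.DataFrame:
    """Weighted mean, variance and 95% interval per parameter, plus ESS."""
    w = posterior.weights
    if posterior.particles.size == 0 or not np.isfinite(posterior.ess()) or posterior.ess() <= 0:
        raise ValueError("posterior has zero effective sample size")
    rows = []
    mu = posterior.mean()
    var = posterior.variance()
    for k, name in enumerate(posterior.names):
        x = posterior.particles[:, k]
        order = np.argsort(x)
        cw = np.cumsum(w[order])
        lo = x[order][np.searchsorted(cw, 0.025)]
        hi = x[order][min(np.searchsorted(cw, 0.975), x.size - 1)]
        rows.append(
            {
                "parameter": name,
                "mean": mu[k],
                "variance": var[k],
                "ci_low": lo,
                "ci_high": hi,
                "ess": posterior.ess(),
            }
        )
    return pd.DataFrame(rows)


def split_by_condition(table, test_conditions):
    """Split a fate table into (fit, holdout) by condition name."""
    frame = getattr(table, "frame", table)
    test_conditions = set(test_conditions)
    known = set(frame["condition"].unique())
    unknown = sorted(test_conditions - known)
    if unknown:
        raise ValueError(f"unknown conditions requested for holdout: {unknown}")
    mask = frame["condition"].isin(test_conditions)
    return frame[~mask].reset_index(drop=True), frame[mask].reset_index(drop=True)
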