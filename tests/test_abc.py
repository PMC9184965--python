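"""ABC-SMC fitting: distance, priors, posterior invariants."""

import numpy as np
import pandas as pd
import pytest

from waddyn.abc import (
    AlignmentError,
    Posterior,
    PriorSpec,
    abc_smc,
    distance,
    posterior_summary,
    split_by_condition,
)


def _props(rows):
    return pd.DataFrame(rows, columns=["condition", "time", "fate", "proportion", "n"])


def test_distance_zero_for_identical_tables():
    t = _props([("c", 1.0, "a", 0.6, 10), ("c", 1.0, "b", 0.4, 10)])
    assert distance(t, t.copy()) == 0.0


def test_distance_is_symmetric_and_counts_missing_fates_as_zero():
    t1 = _props([("c", 1.0, "a", 1.0, 10)])
    t2 = _props([("c", 1.0, "b", 1.0, 10)])
    # disjoint single fates: |1-0| and |0-1| over two keys -> mean 1
    assert distance(t1, t2) == pytest.approx(1.0)
    assert distance(t1, t2) == distance(t2, t1)


def test_distance_simple_shift():
    t1 = _props([("c", 1.0, "a", 0.6, 10), ("c", 1.0, "b", 0.4, 10)])
    t2 = _props([("c", 1.0, "a", 0.5, 10), ("c", 1.0, "b", 0.5, 10)])
    assert distance(t1, t2) == pytest.approx(0.1)


def test_distance_alignment_error_names_missing_groups():
    t1 = _props([("c1", 1.0, "a", 1.0, 10)])
    t2 = _props([("c2", 1.0, "a", 1.0, 10)])
    with pytest.raises(AlignmentError) as err:
        distance(t1, t2)
    assert "c1" in str(err.value) and "c2" in str(err.value)


def test_prior_spec_validation_and_sampling(rng):
    with pytest.raises(ValueError):
        PriorSpec(("a",), [1.0], [0.5])
    priors = PriorSpec(("a", "b"), [-1.0, 0.0], [1.0, 2.0])
    draws = priors.sample(rng, 100)
    assert draws.shape == (100, 2)
    assert np.all(draws >= priors.lows) and np.all(draws <= priors.highs)
    assert priors.contains([0.0, 1.0]) and not priors.contains([0.0, 3.0])


# a cheap analytic simulator: one condition, two fates, p(a) = logistic(theta)
def _toy_simulator(params, seed):
    rng = np.random.default_rng(seed)
    p = 1.0 / (1.0 + np.exp(-3.0 * float(params[0])))
    k = rng.binomial(400, p)
    return _props(
        [("c", 1.0, "hi", k / 400, 400), ("c", 1.0, "lo", 1 - k / 400, 400)]
    )


@pytest.fixture(scope="module")
def toy_posterior():
    observed = _toy_simulator([0.4], seed=123)
    priors = PriorSpec(("theta",), [-1.0], [1.0])
    return abc_smc(
        _toy_simulator, observed, priors, n_particles=60, n_generations=3, seed=7
    )


def test_smc_posterior_invariants(toy_posterior):
    post = toy_posterior
    assert post.particles.shape == (60, 1)
    assert np.isclose(post.weights.sum(), 1.0, atol=1e-12)
    assert np.all(post.weights >= 0)
    eps = [e for e in post.epsilon_history if np.isfinite(e)]
    assert all(b <= a + 1e-12 for a, b in zip(eps, eps[1:]))
    assert len(post.acceptance_rates) == 3
    assert post.status == "ok"
    assert post.seed == 7


def test_smc_concentrates_near_truth(toy_posterior):
    mean = float(toy_posterior.mean()[0])
    prior_sd = 2.0 / np.sqrt(12)
    assert abs(mean - 0.4) < prior_sd / 2
    assert float(toy_posterior.variance()[0]) < prior_sd**2


def test_smc_deterministic_under_seed():
    observed = _toy_simulator([0.4], seed=123)
    priors = PriorSpec(("theta",), [-1.0], [1.0])
    p1 = abc_smc(_toy_simulator, observed, priors, n_particles=50, n_generations=2, seed=5)
    p2 = abc_smc(_toy_simulator, observed, priors, n_particles=50, n_generations=2, seed=5)
    assert np.array_equal(p1.particles, p2.particles)
    assert np.array_equal(p1.weights, p2.weights)


def test_smc_rejects_small_populations():
    observed = _toy_simulator([0.0], seed=1)
    priors = PriorSpec(("theta",), [-1.0], [1.0])
    with pytest.raises(ValueError):
        abc_smc(_toy_simulator, observed, priors, n_particles=10)


def test_unalignable_simulator_stops_early_with_prior():
    # a simulator whose conditions never match the observations cannot be
    # compared: all distances are infinite and the run stops after the prior
    observed = _props([("real", 1.0, "a", 1.0, 10)])

    def bad_simulator(params, seed):
        return _props([("other", 1.0, "a", 1.0, 10)])

    priors = PriorSpec(("theta",), [0.0], [1.0])
    post = abc_smc(bad_simulator, observed, priors, n_particles=50, n_generations=3, seed=2)
    assert post.status == "early_stop"
    assert np.isclose(post.weights.sum(), 1.0)
    # the surviving generation is the prior sample
    assert np.allclose(post.weights, 1.0 / 50)


def test_posterior_summary_contents(toy_posterior):
    summary = posterior_summary(toy_posterior)
    row = summary.iloc[0]
    assert row.parameter == "theta"
    assert row.ci_low <= row["mean"] <= row.ci_high
    assert row.ess > 1.0
    assert np.isclose(row.ess, toy_posterior.ess())


def test_posterior_summary_rejects_degenerate():
    post = Posterior(
        names=("a",),
        particles=np.zeros((0, 1)),
        weights=np.zeros(0),
        distances=np.zeros(0),
        epsilon_history=[],
        acceptance_rates=[],
        seed=0,
    )
    with pytest.raises(ValueError):
        posterior_summary(post)


def test_posterior_csv_round_trip(tmp_path, toy_posterior):
    path = tmp_path / "posterior.csv"
    toy_posterior.to_csv(path)
    frame = pd.read_csv(path)
    assert list(frame.columns) == ["theta", "weight", "distance"]
    assert np.allclose(frame.theta, toy_posterior.particles[:, 0])
    import json

    meta = json.load(open(str(path) + ".meta.json"))
    assert meta["seed"] == toy_posterior.seed
    assert "epsilon_history" in meta and "package_version" in meta


def test_split_by_condition():
    frame = _props(
        [("c1", 1.0, "a", 0.5, 10), ("c2", 1.0, "a", 0.6, 10), ("c3", 1.0, "a", 0.7, 10)]
    )
    fit, holdout = split_by_condition(frame, ["c2"])
    assert set(fit.condition) == {"c1", "c3"}
    assert set(holdout.condition) == {"c2"}
    with pytest.raises(ValueError) as err:
        split_by_condition(frame, ["missing"])
    assert "missing" in str(err.value)
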