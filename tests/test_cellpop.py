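"""Population simulation, fate labeling and proportion tables."""

import numpy as np
import pandas as pd
import pytest

from waddyn import (
    FateRegistry,
    FateTable,
    LandscapeModel,
    PopulationCondition,
    SignalPath,
    fate_proportions,
    make_family,
    simulate_population,
    synth_dataset,
)
from waddyn.cellpop import UNDECIDED, pulse_theta_fn


@pytest.fixture(scope="module")
def double_well_model():
    return LandscapeModel(make_family("cusp1d"), theta=[-1.0, 0.0], sigma=0.1)


def _constant_condition(theta, t_end=2.0, name="hold"):
    return PopulationCondition(name=name, path=SignalPath.constant(theta, t_end=t_end))


def test_registry_names_by_proximity():
    reg = FateRegistry(radius=0.5)
    a = reg.name_of([1.0, 0.0])
    b = reg.name_of([-1.0, 0.0])
    assert (a, b) == ("fate_0", "fate_1")
    assert reg.name_of([1.05, 0.02]) == "fate_0"  # within radius
    assert reg.name_of([0.0, 2.0]) == "fate_2"  # new attractor
    assert reg.fates == ["fate_0", "fate_1", "fate_2"]


def test_population_is_deterministic_under_seed(double_well_model):
    cond = _constant_condition([-1.0, 0.0])
    t1 = simulate_population(double_well_model, [cond], n_cells=40, dt=0.01, seed=9)
    t2 = simulate_population(double_well_model, [cond], n_cells=40, dt=0.01, seed=9)
    t3 = simulate_population(double_well_model, [cond], n_cells=40, dt=0.01, seed=10)
    pd.testing.assert_frame_equal(t1.frame, t2.frame)
    assert not t1.frame.equals(t3.frame)


def test_per_condition_streams_are_independent(double_well_model):
    # a condition's results do not depend on which other conditions run
    c1 = _constant_condition([-1.0, 0.0], name="one")
    c2 = _constant_condition([-1.0, 0.3], name="two")
    alone = simulate_population(double_well_model, [c1], n_cells=30, dt=0.01, seed=4)
    both = simulate_population(double_well_model, [c1, c2], n_cells=30, dt=0.01, seed=4)
    got = both.frame[both.frame.condition == "one"].reset_index(drop=True)
    pd.testing.assert_frame_equal(alone.frame, got)


def test_fates_split_between_wells(double_well_model):
    # symmetric double well, start at the saddle: both fates occupied
    cond = _constant_condition([-1.0, 0.0], t_end=4.0)
    table = simulate_population(
        double_well_model, [cond], n_cells=200, x0_center=[0.0, 0.0], dt=0.01, seed=1
    )
    props = table.proportions()
    assert set(props.fate) <= {"fate_0", "fate_1", UNDECIDED}
    occupied = props[props.fate != UNDECIDED]
    assert len(occupied) == 2
    assert (occupied.proportion > 0.3).all()


def test_biased_well_shifts_proportions(double_well_model):
    reg = FateRegistry()
    reg.name_of([1.0, 0.0])
    reg.name_of([-1.0, 0.0])
    out = {}
    for b in (0.0, -0.3):
        cond = _constant_condition([-1.0, b], t_end=4.0)
        table = simulate_population(
            double_well_model.with_theta([-1.0, b]),
            [cond],
            n_cells=200,
            x0_center=[0.0, 0.0],
            dt=0.01,
            seed=2,
            registry=reg,
        )
        props = table.proportions()
        sel = props[props.fate == "fate_0"]
        out[b] = float(sel.proportion.iloc[0]) if len(sel) else 0.0
    # b < 0 lowers the potential of the positive-x well: more cells commit there
    assert out[-0.3] > out[0.0] + 0.2


def test_proportions_sum_to_one(double_well_model):
    cond = _constant_condition([-1.0, 0.0])
    table = simulate_population(double_well_model, [cond], n_cells=50, dt=0.01, seed=3)
    props = table.proportions()
    for (_, _), grp in props.groupby(["condition", "time"]):
        assert np.isclose(grp.proportion.sum(), 1.0)
        assert (grp.n == 50).all()


def test_record_times_and_metadata(double_well_model):
    cond = _constant_condition([-1.0, 0.0], t_end=2.0)
    table = simulate_population(
        double_well_model, [cond], n_cells=10, dt=0.01, seed=5, record_times=[1.0, 2.0]
    )
    assert sorted(table.frame.time.unique()) == [1.0, 2.0]
    assert table.metadata["seed"] == 5
    assert table.metadata["n_cells"] == 10
    assert "package_version" in table.metadata


def test_fate_table_round_trips(tmp_path, double_well_model):
    cond = _constant_condition([-1.0, 0.0])
    table = simulate_population(double_well_model, [cond], n_cells=15, dt=0.01, seed=6)
    path = tmp_path / "fates.csv"
    table.to_csv(path)
    loaded = FateTable.from_csv(path)
    pd.testing.assert_frame_equal(table.frame, loaded.frame)
    assert loaded.metadata["seed"] == 6


def test_per_cell_theta_groups(double_well_model):
    # two sub-populations with opposite bias must commit to opposite wells
    n = 40
    b_cells = np.repeat([-0.3, 0.3], n // 2)

    def theta_fn(t):
        th = np.empty((n, 2))
        th[:, 0] = -1.0
        th[:, 1] = b_cells
        return th

    cond = PopulationCondition(name="split", theta_fn=theta_fn, t_end=4.0)
    reg = FateRegistry()
    reg.name_of([1.0, 0.0])
    reg.name_of([-1.0, 0.0])
    table = simulate_population(
        double_well_model, [cond], n_cells=n, x0_center=[0.0, 0.0], x0_spread=0.01,
        dt=0.01, seed=8, registry=reg,
    )
    f = table.frame
    neg = f[f.cell < n // 2].fate.value_counts()
    pos = f[f.cell >= n // 2].fate.value_counts()
    assert neg.idxmax() == "fate_0"  # b=-0.3 tilts to positive well
    assert pos.idxmax() == "fate_1"


def test_pulse_theta_fn_profile():
    amps = np.array([0.0, 1.0])
    fn, t_off = pulse_theta_fn([0.5, 0.0], amps, component=1, t_up=1.0, t_hold=2.0, t_down=1.0)
    assert t_off == 4.0
    assert np.allclose(fn(0.0)[:, 1], [0.0, 0.0])
    assert np.allclose(fn(0.5)[:, 1], [0.0, 0.5])  # half-way up the ramp
    assert np.allclose(fn(2.0)[:, 1], [0.0, 1.0])  # on the plateau
    assert np.allclose(fn(10.0)[:, 1], [0.0, 0.0])  # back at baseline
    assert np.allclose(fn(2.0)[:, 0], [0.5, 0.5])  # other component untouched


def test_fate_proportions_tidy_shape():
    frame = pd.DataFrame(
        {
            "condition": ["c"] * 4,
            "time": [1.0] * 4,
            "cell": range(4),
            "x1": 0.0,
            "x2": 0.0,
            "fate": ["a", "a", "b", UNDECIDED],
        }
    )
    props = fate_proportions(frame)
    by_fate = dict(zip(props.fate, props.proportion))
    assert by_fate == {"a": 0.5, "b": 0.25, UNDECIDED: 0.25}


def test_synth_dataset_resamples_deterministically():
    props = pd.DataFrame(
        {
            "condition": ["c", "c"],
            "time": [1.0, 1.0],
            "fate": ["a", "b"],
            "proportion": [0.7, 0.3],
            "n": [100, 100],
        }
    )
    s1 = synth_dataset(props, n_per_condition=50, seed=3)
    s2 = synth_dataset(props, n_per_condition=50, seed=3)
    pd.testing.assert_frame_equal(s1, s2)
    assert np.isclose(s1.proportion.sum(), 1.0)
    assert (s1.n == 50).all()


def test_duplicate_condition_names_rejected(double_well_model):
    c = _constant_condition([-1.0, 0.0], name="x")
    with pytest.raises(ValueError):
        simulate_population(double_well_model, [c, c], n_cells=5, seed=0)
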