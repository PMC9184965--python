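"""Worked population scenarios on the catalogue landscapes.

These are the canonical experiments the package is designed around, packaged
as reusable functions so scripts, tests and documentation run the exact same
protocols:

* a *commitment ramp* on the symmetric binary-flip landscape: the progenitor
  attractor is destroyed by a fold and each cell commits to one of two
  symmetric fates, with a signal offset ``b`` biasing the split;
* a *signal-sensitivity fit* scenario: several experimental conditions whose
  offset depends linearly on a signal level, used to recover the baseline and
  sensitivity parameters from fate proportions;
* a *positional-information pulse* on the dual-cusp landscape: a transient
  signal pushes cells across one or two fold curves and the resulting fates
  persist after the signal returns to baseline.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .cellpop import (
    FateRegistry,
    FateTable,
    PopulationCondition,
    pulse_theta_fn,
    simulate_population,
)
from .families import LandscapeModel, SignalPath, make_family

__all__ = [
    "commitment_ramp_table",
    "committed_split",
    "signal_ramp_simulator",
    "well_choice_simulator",
    "positional_pulse_table",
    "pulse_persistence",
    "FLIP_FATE_UP",
    "FLIP_FATE_DOWN",
    "DUAL_CUSP_OUTER_FOLD_B",
]

#: approximate committed-attractor positions of the binary-flip landscape at
#: the end of the commitment ramp (a = -6); used to pin fate names
FLIP_FATE_UP = (2.2, 2.97)
FLIP_FATE_DOWN = (2.2, -2.97)
FLIP_PROGENITOR = (-2.8, 0.0)

#: commitment ramp: the control parameter a runs from tristable (-2) past the
#: progenitor-destroying fold to -6, then holds while cells settle
RAMP_A_START, RAMP_A_END = -2.0, -6.0
RAMP_T, HOLD_T = 3.0, 1.5

#: the outer fold of the dual-cusp landscape at a = 0.15 sits at |b| ~ 0.0724
#: (the inner fold at |b| ~ 0.023); a pulse beyond the outer fold crosses two
#: fold curves on its way out
DUAL_CUSP_A = 0.15
DUAL_CUSP_INNER_FOLD_B = 0.023
DUAL_CUSP_OUTER_FOLD_B = 0.0724


def _flip_registry() -> FateRegistry:
    reg = FateRegistry()
    reg.name_of(FLIP_FATE_UP)
    reg.name_of(FLIP_FATE_DOWN)
    reg.name_of(FLIP_PROGENITOR)
    return reg


def _ramp_path(b: float) -> SignalPath:
    return SignalPath(
        np.array([0.0, RAMP_T, RAMP_T + HOLD_T]),
        np.array([[RAMP_A_START, b], [RAMP_A_END, b], [RAMP_A_END, b]]),
    )


def commitment_ramp_table(
    offsets,
    n_cells: int = 400,
    sigma: float = 0.2,
    dt: float = 0.02,
    seed: int = 0,
) -> FateTable:
    """Run the commitment ramp once per signal offset ``b``.

    Returns one fate table with a condition per offset (named ``b=<value>``),
    using a shared fate registry so the two committed fates carry the same
    names in every condition (``fate_0`` = upper, ``fate_1`` = lower).
    """
    family = make_family("elliptic_umbilic")
    model = LandscapeModel(family, sigma=sigma)
    conditions = [
        PopulationCondition(name=f"b={b:g}", path=_ramp_path(float(b))) for b in offsets
    ]
    return simulate_population(
        model,
        conditions,
        n_cells=n_cells,
        dt=dt,
        seed=seed,
        x0_center=FLIP_PROGENITOR,
        registry=_flip_registry(),
    )


def committed_split(table: FateTable) -> pd.DataFrame:
    """Fraction of committed cells in the upper fate, per condition.

    Cells that are still in the progenitor state or undecided are excluded
    from the denominator; columns: condition, upper_fraction, n_committed.
    """
    rows = []
    for cond, grp in table.frame.groupby("condition", sort=False):
        committed = grp[grp.fate.isin(["fate_0", "fate_1"])]
        n = len(committed)
        up = int((committed.fate == "fate_0").sum())
        rows.append(
            {
                "condition": cond,
                "upper_fraction": up / n if n else np.nan,
                "n_committed": n,
            }
        )
    return pd.DataFrame(rows)


def signal_ramp_simulator(
    signals=(-1.0, 0.0, 1.0),
    n_per_condition: int = 100,
    sigma: float = 0.25,
    dt: float = 0.02,
):
    """Simulator mapping (baseline, sensitivity) to a multi-condition table.

    Condition ``s`` applies the commitment ramp with offset
    ``b = baseline + sensitivity * s``.  All conditions run as one population
    with per-cell parameters (the offset is constant per cell) and are split
    back by cell index afterwards; fate names are pinned by a pre-seeded
    registry so tables from different parameter draws align.
    Returns ``simulate(params, seed) -> FateTable`` for likelihood-free
    fitting.
    """
    signals = np.asarray(signals, float)
    family = make_family("elliptic_umbilic")
    model = LandscapeModel(family, sigma=sigma)
    n_cells = int(n_per_condition * signals.size)
    names = np.repeat([f"s={s:g}" for s in signals], n_per_condition)
    t_end = RAMP_T + HOLD_T

    def simulate(params, seed) -> FateTable:
        b0, b1 = float(params[0]), float(params[1])
        b_cells = np.repeat(b0 + b1 * signals, n_per_condition)

        def theta_fn(t):
            a = RAMP_A_START + (RAMP_A_END - RAMP_A_START) * min(t, RAMP_T) / RAMP_T
            th = np.empty((n_cells, 2))
            th[:, 0] = a
            th[:, 1] = b_cells
            return th

        cond = PopulationCondition(name="ramp", theta_fn=theta_fn, t_end=t_end)
        table = simulate_population(
            model,
            [cond],
            n_cells=n_cells,
            dt=dt,
            seed=seed,
            x0_center=FLIP_PROGENITOR,
            registry=_flip_registry(),
        )
        table.frame["condition"] = names[table.frame["cell"].to_numpy()]
        return table

    return simulate


def well_choice_simulator(
    signals=(-1.0, 0.0, 1.0),
    n_per_condition: int = 300,
    sigma: float = 0.4,
    dt: float = 0.02,
    t_end: float = 3.0,
):
    """Simulator for a graded binary decision on the double-well landscape.

    Cells start at the saddle of the symmetric double well (cusp family at
    a = -1) and fall into one of the two wells; the tilt ``b = baseline +
    sensitivity * s`` biases the choice, and at moderate noise the committed
    fraction responds smoothly (close to linearly) to ``b`` across
    ``|b| <= 0.3``.  This graded dose-response makes (baseline, sensitivity)
    well identified from fate proportions, unlike the switch-like commitment
    ramp.  Returns ``simulate(params, seed) -> FateTable``; ``fate_0`` is the
    positive well, ``fate_1`` the negative well.
    """
    signals = np.asarray(signals, float)
    family = make_family("cusp1d")
    model = LandscapeModel(family, sigma=sigma)
    n_cells = int(n_per_condition * signals.size)
    names = np.repeat([f"s={s:g}" for s in signals], n_per_condition)

    def simulate(params, seed) -> FateTable:
        b0, b1 = float(params[0]), float(params[1])
        b_cells = np.repeat(b0 + b1 * signals, n_per_condition)

        def theta_fn(t):
            th = np.empty((n_cells, 2))
            th[:, 0] = -1.0
            th[:, 1] = b_cells
            return th

        registry = FateRegistry()
        registry.name_of((1.0, 0.0))
        registry.name_of((-1.0, 0.0))
        cond = PopulationCondition(name="choice", theta_fn=theta_fn, t_end=t_end)
        table = simulate_population(
            model,
            [cond],
            n_cells=n_cells,
            dt=dt,
            seed=seed,
            x0_center=(0.0, 0.0),
            x0_spread=0.02,
            registry=registry,
        )
        table.frame["condition"] = names[table.frame["cell"].to_numpy()]
        return table

    return simulate


def positional_pulse_table(
    amplitudes,
    n_cells: int | None = None,
    sigma: float = 0.02,
    dt: float = 0.01,
    seed: int = 0,
    settle_after: float = 20.0,
) -> tuple[FateTable, float]:
    """Transient signal pulse on the tristable dual-cusp landscape.

    Each cell starts in the central attractor and receives a trapezoidal
    pulse of its own amplitude on the tilt parameter (2 up / 20 hold / 2
    down); fates are recorded ``settle_after`` time units after the signal
    has returned to baseline.  Returns the fate table and the pulse end time.
    Fate names are pinned: ``fate_0`` = positive-side, ``fate_1`` = central,
    ``fate_2`` = negative-side attractor.
    """
    amplitudes = np.asarray(amplitudes, float)
    if n_cells is None:
        n_cells = amplitudes.size
    if amplitudes.size != n_cells:
        raise ValueError("one pulse amplitude per cell is required")
    family = make_family("dual_cusp1d")
    model = LandscapeModel(family, sigma=sigma)
    theta_fn, t_off = pulse_theta_fn(
        np.array([DUAL_CUSP_A, 0.0]), amplitudes, component=1,
        t_up=2.0, t_hold=20.0, t_down=2.0,
    )
    cond = PopulationCondition(name="pulse", theta_fn=theta_fn, t_end=t_off + settle_after)
    registry = FateRegistry(radius=0.3)
    registry.name_of((0.9, 0.0))
    registry.name_of((0.0, 0.0))
    registry.name_of((-0.9, 0.0))
    table = simulate_population(
        model,
        [cond],
        n_cells=n_cells,
        dt=dt,
        seed=seed,
        x0_center=(0.0, 0.0),
        x0_spread=0.02,
        registry=registry,
    )
    return table, t_off


def pulse_persistence(table: FateTable, amplitudes) -> float:
    """Fraction of double-fold-crossing cells not back in the central fate.

    A pulse amplitude beyond the outer fold carries the cell across both fold
    curves; persistence is the fraction of those cells found outside the
    central attractor after the signal has returned to baseline.
    """
    amplitudes = np.asarray(amplitudes, float)
    frame = table.frame
    final = frame[frame.time == frame.time.max()].sort_values("cell")
    crossed = np.abs(amplitudes) > DUAL_CUSP_OUTER_FOLD_B
    if not crossed.any():
        raise ValueError("no cell's pulse crosses both fold curves")
    moved = (final.fate != "fate_1").to_numpy()
    return float(moved[crossed].mean())
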