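"""In-silico treatment experiments: schedule comparison, dose grids and
treatment-break forecasts, all over matched initial states."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .params import ChemoResponse, GrowthParams
from .pk import Schedule, vehicle_schedule, with_break
from .simulate import SimConfig, Trajectory, simulate


def compare_schedules(growth: GrowthParams, chemo: ChemoResponse,
                      pk_by_drug: dict, schedules: dict,
                      v0: float, k0: float,
                      config: SimConfig | None = None):
    """Simulate each schedule from the same (v0, k0) and tabulate final
    volumes and percent reduction relative to the vehicle run.

    Returns (trajectories, table): the table has one row per schedule,
    sorted by final tumour volume, with columns ``final_v_mm3``,
    ``final_k_mm3`` and ``pct_reduction_vs_vehicle`` where
    reduction = 100 (1 - V_treated(t_end) / V_vehicle(t_end)).
    """
    schedules = dict(schedules)
    horizon = max(s.horizon for s in schedules.values())
    if "vehicle" not in schedules:
        schedules["vehicle"] = vehicle_schedule(horizon)
    trajectories = {name: simulate(growth, chemo, sched, pk_by_drug,
                                   v0, k0, config)
                    for name, sched in schedules.items()}
    v_vehicle = float(trajectories["vehicle"].v[-1])
    rows = []
    for name, traj in trajectories.items():
        v_end = float(traj.v[-1])
        rows.append({"schedule": name, "final_v_mm3": v_end,
                     "final_k_mm3": float(traj.k[-1]),
                     "pct_reduction_vs_vehicle":
                         100.0 * (1.0 - v_end / v_vehicle)})
    table = pd.DataFrame(rows).sort_values(
        "final_v_mm3", ignore_index=True)
    return trajectories, table


def dose_heatmap(growth: GrowthParams, chemo: ChemoResponse,
                 pk_by_drug: dict, bvz_doses, folfox_doses,
                 schedule_template: Schedule, v0: float, k0: float,
                 config: SimConfig | None = None) -> pd.DataFrame:
    """Percent tumour reduction vs vehicle on a bvz x FOLFOX dose grid.

    Entry (i, j) rescales every administration in ``schedule_template``
    to (bvz_doses[i], folfox_doses[j]); the (0, 0) corner is the
    vehicle itself."""
    bvz_doses = np.asarray(bvz_doses, dtype=float)
    folfox_doses = np.asarray(folfox_doses, dtype=float)
    vehicle = simulate(growth, chemo, vehicle_schedule(
        schedule_template.horizon), pk_by_drug, v0, k0, config)
    v_vehicle = float(vehicle.v[-1])
    grid = np.empty((bvz_doses.size, folfox_doses.size))
    for i, db in enumerate(bvz_doses):
        for j, df_ in enumerate(folfox_doses):
            sched = schedule_template.scaled(bvz_dose=float(db),
                                             folfox_dose=float(df_))
            traj = simulate(growth, chemo, sched, pk_by_drug, v0, k0, config)
            grid[i, j] = 100.0 * (1.0 - float(traj.v[-1]) / v_vehicle)
    return pd.DataFrame(grid,
                        index=pd.Index(bvz_doses, name="bvz_dose_mg"),
                        columns=pd.Index(folfox_doses, name="folfox_dose_mg"))


def break_forecast(growth: GrowthParams, chemo: ChemoResponse,
                   pk_by_drug: dict, schedule: Schedule,
                   break_start: float, break_len: float,
                   v0: float, k0: float,
                   config: SimConfig | None = None) -> Trajectory:
    """Forecast under a treatment break: administrations from
    ``break_start`` onward are deferred by ``break_len`` days and the
    horizon extended accordingly."""
    broken = with_break(schedule, break_start, break_len)
    return simulate(growth, chemo, broken, pk_by_drug, v0, k0, config)
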