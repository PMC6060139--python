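"""Forward simulation of the forced tumour/vasculature system.

Two integration paths share one interface:

* the reference path, scipy ``solve_ivp`` (LSODA by default, BDF
  available), integrated piecewise between infusion kink times so the
  non-smooth forcing never degrades the step controller; and
* a compiled fixed-grid Runge-Kutta path (``fast=True``) used by the
  inference engine, cross-validated against the reference in tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.interpolate import PchipInterpolator

from . import _fast
from .model import DomainError
from .params import ChemoResponse, ChemoVariant, GrowthParams
from .pk import Drug, Schedule, concentration, pk_constants


class SimulationError(RuntimeError):
    """Integration failed or the state left the model domain.  Reported
    (so inference can reject the proposal) rather than crashing."""


@dataclass(frozen=True)
class SimConfig:
    """Numerical controls for :func:`simulate`.

    ``dt_out`` is the output grid spacing (day) when no explicit output
    times are given; ``max_step`` bounds the fast path's adaptive step.
    """

    rel_tol: float = 1e-6
    abs_tol: float = 1e-8
    dt_out: float = 0.1
    method: str = "LSODA"
    fast: bool = False
    max_step: float = 0.5

    def __post_init__(self) -> None:
        if self.rel_tol <= 0 or self.abs_tol <= 0:
            raise ValueError("tolerances must be > 0")


@dataclass(frozen=True)
class Trajectory:
    """Solved (t, V, K, I1, I2) paths at the requested output times."""

    times: np.ndarray
    v: np.ndarray
    k: np.ndarray
    i1: np.ndarray
    i2: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time_day": self.times, "V_mm3": self.v,
                             "K_mm3": self.k, "I1_mg_ml": self.i1,
                             "I2_mg_ml": self.i2})

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def _pack_params(growth: GrowthParams, chemo: ChemoResponse) -> np.ndarray:
    variant = 0.0 if chemo.variant is ChemoVariant.CONTINUOUS else 1.0
    x1 = chemo.alpha1 if variant == 0.0 else chemo.alpha2
    x2 = chemo.beta1 if variant == 0.0 else chemo.hill
    return np.array([growth.lambda1, growth.lambda2, growth.c, growth.d,
                     growth.alpha, growth.beta, growth.p, growth.v_star,
                     growth.kf, variant, x1, x2])


def _pack_pk(schedule: Schedule, pk_by_drug: dict, drug: Drug):
    events = schedule.for_drug(drug)
    t0 = np.array([e.t_start for e in events])
    rate = np.array([e.dose_mg / e.t_inf for e in events])
    tinf = np.array([e.t_inf for e in events])
    if events and drug in pk_by_drug:
        a, b, A, B = pk_constants(pk_by_drug[drug])
    else:
        t0 = np.empty(0)
        rate = np.empty(0)
        tinf = np.empty(0)
        a, b, A, B = 1.0, 0.5, 0.0, 0.0
    return t0, rate, tinf, a, b, A, B


def _merge_nodes(t_eval: np.ndarray, kinks: np.ndarray):
    """Sorted union of output times and forcing kinks in the solved
    span, with a mask selecting the output times."""
    t0, t1 = t_eval[0], t_eval[-1]
    kinks = kinks[(kinks > t0) & (kinks < t1)]
    nodes = np.union1d(t_eval, kinks)
    mask = np.isin(nodes, t_eval)
    return nodes, mask


def simulate(growth: GrowthParams, chemo: ChemoResponse, schedule: Schedule,
             pk_by_drug: dict, v0: float, k0: float,
             config: SimConfig | None = None,
             t_eval: np.ndarray | None = None) -> Trajectory:
    """Integrate the forced system with state (v0, k0) at the first
    output time (t = 0 on the default grid).

    Output times default to a uniform grid of ``config.dt_out`` over the
    schedule horizon.  Raises :class:`SimulationError` on solver failure
    or when V or K falls to the prevascular volume.
    """
    config = config or SimConfig()
    if v0 <= growth.v_star or k0 <= growth.v_star:
        raise DomainError("initial state must exceed the prevascular volume")
    if t_eval is None:
        n = int(round(schedule.horizon / config.dt_out))
        t_eval = np.linspace(0.0, schedule.horizon, n + 1)
    t_eval = np.asarray(t_eval, dtype=float)
    if t_eval[0] < 0 or np.any(np.diff(t_eval) <= 0):
        raise ValueError("output times must be non-negative and increasing")

    bvz = _pack_pk(schedule, pk_by_drug, Drug.BVZ)
    fol = _pack_pk(schedule, pk_by_drug, Drug.FOLFOX)
    par = _pack_params(growth, chemo)
    nodes, mask = _merge_nodes(t_eval, schedule.kink_times())

    if config.fast:
        v, k, ok = _fast.integrate(nodes, mask, v0, k0, par,
                                   config.rel_tol, config.abs_tol,
                                   config.max_step, *bvz, *fol)
        if not ok:
            raise SimulationError("fast integration failed (domain exit or "
                                  "non-finite state)")
    else:
        v, k = _simulate_scipy(nodes, mask, v0, k0, par, bvz, fol, config)
    i1 = concentration(t_eval, schedule, pk_by_drug, Drug.BVZ) \
        if bvz[0].size else np.zeros_like(t_eval)
    i2 = concentration(t_eval, schedule, pk_by_drug, Drug.FOLFOX) \
        if fol[0].size else np.zeros_like(t_eval)
    return Trajectory(t_eval.copy(), v, k, np.asarray(i1), np.asarray(i2))


def _simulate_scipy(nodes, mask, v0, k0, par, bvz, fol, config):
    bt0, brate, btinf, ba, bb, bA, bB = bvz
    ft0, frate, ftinf, fa, fb, fA, fB = fol

    def rhs(t, y):
        return _fast._rhs(t, y[0], y[1], par, bt0, brate, btinf,
                          ba, bb, bA, bB, ft0, frate, ftinf,
                          fa, fb, fA, fB)

    v_star = par[7]

    out_v = []
    out_k = []
    y = np.array([v0, k0])
    if mask[0]:
        out_v.append(v0)
        out_k.append(k0)
    for seg in range(nodes.size - 1):
        t0, t1 = nodes[seg], nodes[seg + 1]
        sol = solve_ivp(rhs, (t0, t1), y, method=config.method,
                        rtol=config.rel_tol, atol=config.abs_tol,
                        t_eval=[t1])
        if not sol.success:
            raise SimulationError(f"solver failed on [{t0}, {t1}]: "
                                  f"{sol.message}")
        y = sol.y[:, -1]
        if not np.all(np.isfinite(y)) or y[0] <= v_star or y[1] <= v_star:
            raise SimulationError("state left the model domain")
        if mask[seg + 1]:
            out_v.append(y[0])
            out_k.append(y[1])
    return np.asarray(out_v), np.asarray(out_k)


def sample_at(traj: Trajectory, times) -> Trajectory:
    """Monotone-cubic interpolation of a trajectory at new times
    (exact at the stored mesh points)."""
    times = np.atleast_1d(np.asarray(times, dtype=float))
    if times.min() < traj.times[0] - 1e-12 or times.max() > traj.times[-1] + 1e-12:
        raise ValueError("requested times outside the solved range")
    cols = []
    for arr in (traj.v, traj.k, traj.i1, traj.i2):
        cols.append(PchipInterpolator(traj.times, arr)(times))
    return Trajectory(times, *cols)
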