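"""Closed-form plasma concentrations for zero-order infusion into a
two-compartment model with first-order elimination, plus dosing
schedules (superposition over repeated administrations).

For one administration starting at t_D with infusion duration T and
dose D, the central-compartment concentration is

    during infusion (t - t_D <= T):
        I(t) = (D/T) [ (A/a)(1 - e^{-a(t-t_D)}) + (B/b)(1 - e^{-b(t-t_D)}) ]
    after (t - t_D > T):
        I(t) = (D/T) [ (A/a)(1 - e^{-aT}) e^{-a(t-t_D-T)}
                     + (B/b)(1 - e^{-bT}) e^{-b(t-t_D-T)} ]

with hybrid rate constants
    b = 0.5 (k12 + k21 + ke - sqrt((k12+k21+ke)^2 - 4 k21 ke)),
    a = k21 ke / b,
    A = (1/Vc)(a - k21)/(a - b),   B = (1/Vc)(b - k21)/(b - a).
a and b are the eigenvalue magnitudes of the compartmental transfer
matrix; a + b = k12 + k21 + ke and a b = k21 ke.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from enum import Enum

import numpy as np
import pandas as pd

from .params import DOSE_BVZ_MG, DOSE_FOLFOX_MG, PKParams, T_INF_DAY


class Drug(str, Enum):
    BVZ = "bvz"
    FOLFOX = "folfox"


DEFAULT_DOSE = {Drug.BVZ: DOSE_BVZ_MG, Drug.FOLFOX: DOSE_FOLFOX_MG}


class DegeneratePKError(ValueError):
    """Hybrid rate constants coincide; the biexponential closed form is
    undefined.  A measure-zero set under continuous priors — proposals
    hitting it are rejected rather than patched with the repeated-root
    limit."""


def pk_constants(pk: PKParams) -> tuple[float, float, float, float]:
    """Hybrid constants (a, b, A, B) for the biexponential closed form."""
    sigma = pk.k12 + pk.k21 + pk.ke
    disc = sigma * sigma - 4.0 * pk.k21 * pk.ke
    # Algebraically disc = (k12+k21-ke)^2 + ... >= 0; clip rounding noise.
    b = 0.5 * (sigma - math.sqrt(max(disc, 0.0)))
    a = pk.k21 * pk.ke / b
    if abs(a - b) / max(a, b) < 1e-8:
        raise DegeneratePKError(f"a ~= b ({a} vs {b})")
    A = (a - pk.k21) / ((a - b) * pk.vc)
    B = (b - pk.k21) / ((b - a) * pk.vc)
    return a, b, A, B


@dataclass(frozen=True)
class DoseEvent:
    """One intravenous administration: drug, start day, dose (mg) and
    infusion duration (day)."""

    drug: Drug
    t_start: float
    dose: float | None = None  # None -> per-drug default dose
    t_inf: float = T_INF_DAY

    def __post_init__(self) -> None:
        object.__setattr__(self, "drug", Drug(self.drug))
        if self.t_start < 0:
            raise ValueError("t_start must be >= 0")
        if self.t_inf <= 0:
            raise ValueError("t_inf must be > 0")
        if self.dose is not None and self.dose < 0:
            raise ValueError("dose must be >= 0")

    @property
    def dose_mg(self) -> float:
        return DEFAULT_DOSE[self.drug] if self.dose is None else self.dose


@dataclass(frozen=True)
class Schedule:
    """Ordered dosing plan over a horizon (days)."""

    events: tuple[DoseEvent, ...]
    horizon: float = 45.0

    def __post_init__(self) -> None:
        ev = tuple(sorted(self.events, key=lambda e: e.t_start))
        object.__setattr__(self, "events", ev)
        for e in ev:
            if e.t_start >= self.horizon:
                raise ValueError("all events must start before the horizon")
        for drug in Drug:
            ts = [e.t_start for e in ev if e.drug is drug]
            for t0, t1 in zip(ts, ts[1:]):
                if t1 - t0 <= max(e.t_inf for e in ev):
                    raise ValueError(f"{drug.value} doses overlap an infusion")

    def for_drug(self, drug: Drug) -> tuple[DoseEvent, ...]:
        return tuple(e for e in self.events if e.drug is Drug(drug))

    def kink_times(self) -> np.ndarray:
        """Times where the forcing is continuous but not smooth: every
        infusion start and end."""
        ts = sorted({e.t_start for e in self.events}
                    | {e.t_start + e.t_inf for e in self.events})
        return np.asarray(ts)

    def scaled(self, bvz_dose: float | None = None,
               folfox_dose: float | None = None) -> "Schedule":
        """Copy with per-drug doses replaced (dose-grid experiments)."""
        evs = []
        for e in self.events:
            if e.drug is Drug.BVZ and bvz_dose is not None:
                e = replace(e, dose=bvz_dose)
            elif e.drug is Drug.FOLFOX and folfox_dose is not None:
                e = replace(e, dose=folfox_dose)
            evs.append(e)
        return Schedule(tuple(evs), self.horizon)


def concentration_single(t, event: DoseEvent, pk: PKParams):
    """Plasma concentration (mg/ml) from one administration; vectorised
    over t.  Zero before the infusion starts; continuous everywhere."""
    a, b, A, B = pk_constants(pk)
    t = np.asarray(t, dtype=float)
    tau = t - event.t_start
    D_over_T = event.dose_mg / event.t_inf
    during = D_over_T * ((A / a) * (1.0 - np.exp(-a * np.minimum(tau, event.t_inf)))
                         + (B / b) * (1.0 - np.exp(-b * np.minimum(tau, event.t_inf))))
    post_decay = ((A / a) * (1.0 - math.exp(-a * event.t_inf))
                  * np.exp(-a * (tau - event.t_inf))
                  + (B / b) * (1.0 - math.exp(-b * event.t_inf))
                  * np.exp(-b * (tau - event.t_inf)))
    out = np.where(tau <= event.t_inf, during, D_over_T * post_decay)
    out = np.where(tau < 0, 0.0, out)
    return out if out.ndim else float(out)


def concentration(t, schedule: Schedule, pk_by_drug: dict, drug) -> np.ndarray:
    """Total plasma concentration of ``drug``: superposition of all of
    its administrations (linear PK)."""
    drug = Drug(drug)
    t = np.asarray(t, dtype=float)
    total = np.zeros_like(t)
    events = schedule.for_drug(drug)
    if not events:
        return total
    pk = pk_by_drug[drug]
    for event in events:
        total = total + concentration_single(t, event, pk)
    return total


# ---------------------------------------------------------------------------
# Regimen constructors.  TS1: bvz first, chemotherapy 24 h later, weekly
# cycles.  TS2: chemotherapy first, bvz 24 h later.
# ---------------------------------------------------------------------------

def _weekly(drug: Drug, start: float, n_cycles: int, period: float,
            dose: float | None) -> list[DoseEvent]:
    return [DoseEvent(drug, start + i * period, dose) for i in range(n_cycles)]


def vehicle_schedule(horizon: float = 45.0) -> Schedule:
    return Schedule((), horizon)


def monotherapy_schedule(drug, start: float = 0.0, n_cycles: int = 4,
                         period: float = 7.0, dose: float | None = None,
                         horizon: float = 45.0) -> Schedule:
    return Schedule(tuple(_weekly(Drug(drug), start, n_cycles, period, dose)),
                    horizon)


def ts1_schedule(start: float = 0.0, n_cycles: int = 4, period: float = 7.0,
                 lag: float = 1.0, bvz_dose: float | None = None,
                 folfox_dose: float | None = None,
                 horizon: float = 45.0) -> Schedule:
    """bvz then FOLFOX ``lag`` days later, weekly cycles."""
    ev = (_weekly(Drug.BVZ, start, n_cycles, period, bvz_dose)
          + _weekly(Drug.FOLFOX, start + lag, n_cycles, period, folfox_dose))
    return Schedule(tuple(ev), horizon)


def ts2_schedule(start: float = 0.0, n_cycles: int = 4, period: float = 7.0,
                 lag: float = 1.0, bvz_dose: float | None = None,
                 folfox_dose: float | None = None,
                 horizon: float = 45.0) -> Schedule:
    """FOLFOX then bvz ``lag`` days later, weekly cycles."""
    ev = (_weekly(Drug.FOLFOX, start, n_cycles, period, folfox_dose)
          + _weekly(Drug.BVZ, start + lag, n_cycles, period, bvz_dose))
    return Schedule(tuple(ev), horizon)


def with_break(schedule: Schedule, break_start: float,
               break_len: float) -> Schedule:
    """Defer every administration from ``break_start`` onward by
    ``break_len`` days (a treatment break followed by resumption)."""
    evs = tuple(e if e.t_start < break_start
                else replace(e, t_start=e.t_start + break_len)
                for e in schedule.events)
    return Schedule(evs, schedule.horizon + break_len)


def save_schedule(path, schedule: Schedule) -> None:
    rows = [dict(drug=e.drug.value, t_start_day=e.t_start,
                 dose_mg=e.dose_mg, t_inf_day=e.t_inf)
            for e in schedule.events]
    pd.DataFrame(rows, columns=["drug", "t_start_day", "dose_mg",
                                "t_inf_day"]).to_csv(
        path, sep="\t", index=False, float_format="%.17g")


def load_schedule(path, horizon: float = 45.0) -> Schedule:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    evs = tuple(DoseEvent(Drug(r.drug), float(r.t_start_day),
                          float(r.dose_mg), float(r.t_inf_day))
                for r in df.itertuples())
    return Schedule(evs, horizon)
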