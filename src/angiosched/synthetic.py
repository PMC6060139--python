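"""Synthetic xenograft study generator with known ground truth.

Emulates a caliper-measured subcutaneous xenograft experiment: cohorts
of animals per treatment arm, inter-animal heterogeneity in the growth
constant lambda1 (the parameter observed to vary most across real
experiments), treatment commencing once the arm's mean volume crosses
an enrolment threshold (200 mm^3 by convention), weekly dosing, sparse
(about twice-weekly) noisy measurements, and reporting of per-arm mean
and standard error.  The generated files are drop-in inputs for the
inference module, and the ground-truth record makes every pipeline
stage testable without any external data.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict

import numpy as np

from .datasets import ArmDataset
from .params import ChemoResponse, GrowthParams
from .pk import (Drug, Schedule, monotherapy_schedule, ts1_schedule,
                 ts2_schedule, vehicle_schedule)
from .simulate import SimConfig, simulate


class DesignInfeasibleError(RuntimeError):
    """The enrolment threshold is never reached before the horizon."""


@dataclass(frozen=True)
class NoiseModel:
    """Measurement-error model for caliper readings.

    ``proportional-gaussian``: v_obs = v (1 + scale * z), the usual
    caliper behaviour (error grows with the tumour);
    ``additive-gaussian``: v_obs = v + scale * z with scale in mm^3.
    Negative draws are truncated at zero and counted.
    """

    kind: str = "proportional-gaussian"
    scale: float = 0.10

    def __post_init__(self) -> None:
        if self.kind not in ("proportional-gaussian", "additive-gaussian"):
            raise ValueError(f"unknown noise kind {self.kind!r}")
        if self.scale < 0:
            raise ValueError("scale must be >= 0")

    def apply(self, v: np.ndarray, rng: np.random.Generator):
        z = rng.standard_normal(v.shape)
        if self.kind == "proportional-gaussian":
            noisy = v * (1.0 + self.scale * z)
        else:
            noisy = v + self.scale * z
        truncated = int(np.sum(noisy < 0))
        return np.maximum(noisy, 0.0), truncated


@dataclass(frozen=True)
class StudyDesign:
    """Layout of the emulated xenograft study."""

    arms: tuple = ("vehicle", "bvz", "folfox")
    measurement_times: np.ndarray = field(
        default_factory=lambda: np.arange(0.0, 45.1, 3.5))
    treatment_threshold: float = 200.0  # mm^3, enrolment volume
    n_animals: int = 12
    horizon: float = 45.0
    v0: float = 25.0        # implant volume at first measurement, mm^3
    n_cycles: int = 4
    period: float = 7.0
    lag: float = 1.0        # days between the two drugs in combination arms
    lambda1_sigma: float = 0.10  # lognormal sd of per-animal growth rates

    def __post_init__(self) -> None:
        object.__setattr__(self, "measurement_times",
                           np.asarray(self.measurement_times, dtype=float))
        object.__setattr__(self, "arms", tuple(self.arms))
        if self.treatment_threshold <= 0:
            raise ValueError("treatment threshold must be > 0")
        if self.horizon < self.measurement_times[-1]:
            raise ValueError("horizon must cover the measurement times")


def _arm_schedule(arm: str, start: float, design: StudyDesign,
                  horizon: float) -> Schedule:
    if arm == "vehicle":
        return vehicle_schedule(horizon)
    if arm in ("bvz", "folfox"):
        return monotherapy_schedule(arm, start, design.n_cycles,
                                    design.period, horizon=horizon)
    if arm == "ts1":
        return ts1_schedule(start, design.n_cycles, design.period,
                            design.lag, horizon=horizon)
    if arm == "ts2":
        return ts2_schedule(start, design.n_cycles, design.period,
                            design.lag, horizon=horizon)
    raise ValueError(f"unknown arm {arm!r}")


def generate_study(true_growth: GrowthParams, true_chemo: ChemoResponse,
                   pk_by_drug: dict, design: StudyDesign,
                   noise: NoiseModel, seed: int = 0,
                   sim_config: SimConfig | None = None):
    """Simulate the full study.

    Returns
    -------
    (datasets, truth)
        ``datasets``: one :class:`ArmDataset` per arm (mean + SEM over
        animals).  ``truth``: dict with the generating parameters, the
        per-arm schedules and treatment-start days, per-arm animal
        lambda1 values, the seed, and truncation counts.
    """
    rng = np.random.default_rng(seed)
    sim_config = sim_config or SimConfig(fast=True)
    horizon = design.horizon
    fine = np.arange(0.0, horizon + 0.25, 0.25)
    datasets = []
    truth = {"seed": seed, "noise": asdict(noise), "design": {
        "arms": list(design.arms), "n_animals": design.n_animals,
        "treatment_threshold": design.treatment_threshold,
        "v0": design.v0, "horizon": horizon,
        "lambda1_sigma": design.lambda1_sigma},
        "arms": {}, "n_truncated": 0}

    for arm in design.arms:
        lam1 = true_growth.lambda1 * np.exp(
            design.lambda1_sigma * rng.standard_normal(design.n_animals))
        growths = [GrowthParams(
            lambda1=float(l1), lambda2=true_growth.lambda2, c=true_growth.c,
            d=true_growth.d, alpha=true_growth.alpha, beta=true_growth.beta,
            p=true_growth.p, v_star=true_growth.v_star, kf=true_growth.kf)
            for l1 in lam1]

        # Untreated growth of the cohort to locate the enrolment day.
        if arm == "vehicle":
            t_rx = None
            schedule = vehicle_schedule(horizon)
        else:
            free = np.stack([
                simulate(g, true_chemo, vehicle_schedule(horizon),
                         pk_by_drug, design.v0, 5.0 * design.v0,
                         sim_config, t_eval=fine).v
                for g in growths])
            mean_free = free.mean(axis=0)
            crossed = np.nonzero(mean_free >= design.treatment_threshold)[0]
            if crossed.size == 0:
                raise DesignInfeasibleError(
                    f"arm {arm!r}: mean volume never reaches "
                    f"{design.treatment_threshold} mm^3 before day {horizon}")
            t_rx = float(fine[crossed[0]])
            schedule = _arm_schedule(arm, t_rx, design, horizon)

        per_animal = np.stack([
            simulate(g, true_chemo, schedule, pk_by_drug,
                     design.v0, 5.0 * design.v0, sim_config,
                     t_eval=design.measurement_times).v
            for g in growths])
        noisy, truncated = noise.apply(per_animal, rng)
        truth["n_truncated"] += truncated
        mean = noisy.mean(axis=0)
        sem = noisy.std(axis=0, ddof=1) / math.sqrt(design.n_animals) \
            if design.n_animals > 1 else np.zeros_like(mean)
        datasets.append(ArmDataset(arm, design.measurement_times.copy(),
                                   mean, sem, design.n_animals))
        truth["arms"][arm] = {
            "treatment_start_day": t_rx,
            "lambda1_per_animal": [float(x) for x in lam1],
            "schedule": [dict(drug=e.drug.value, t_start_day=e.t_start,
                              dose_mg=e.dose_mg, t_inf_day=e.t_inf)
                         for e in schedule.events]}

    truth["params"] = {
        "lambda1": true_growth.lambda1, "lambda2": true_growth.lambda2,
        "c": true_growth.c, "d": true_growth.d, "alpha": true_growth.alpha,
        "Kf": true_growth.kf, "v_star": true_growth.v_star,
        "model": true_chemo.variant.value,
        "Bk12": pk_by_drug[Drug.BVZ].k12, "Bk21": pk_by_drug[Drug.BVZ].k21,
        "Bke": pk_by_drug[Drug.BVZ].ke,
        "Fk12": pk_by_drug[Drug.FOLFOX].k12,
        "Fk21": pk_by_drug[Drug.FOLFOX].k21,
        "Fke": pk_by_drug[Drug.FOLFOX].ke,
    }
    if true_chemo.variant.value == "continuous":
        truth["params"]["alpha1"] = true_chemo.alpha1
        truth["params"]["beta1"] = true_chemo.beta1
    else:
        truth["params"]["alpha2"] = true_chemo.alpha2
        truth["params"]["p1"] = true_chemo.hill
    return datasets, truth


def schedules_from_truth(truth: dict, horizon: float | None = None) -> dict:
    """Rebuild the per-arm :class:`Schedule` map from a ground-truth
    record (or any saved study metadata of the same shape)."""
    from .pk import DoseEvent
    horizon = horizon or truth["design"]["horizon"]
    out = {}
    for arm, rec in truth["arms"].items():
        evs = tuple(DoseEvent(Drug(e["drug"]), e["t_start_day"],
                              e["dose_mg"], e["t_inf_day"])
                    for e in rec["schedule"])
        out[arm] = Schedule(evs, horizon)
    return out


def save_study(outdir, datasets, truth) -> None:
    from pathlib import Path
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for ds in datasets:
        ds.to_csv(outdir / f"{ds.arm}_volumes.tsv")
    with open(outdir / "ground_truth.json", "w") as fh:
        json.dump(truth, fh, indent=2)
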