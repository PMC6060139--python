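"""Reference in-silico studies: the synthetic xenograft experiments the
analysis scripts, test suite and acceptance script all share.

Two studies are defined:

* the *recovery* study — a vehicle/bvz/FOLFOX three-arm experiment
  generated from a threshold-model ground truth chosen inside the prior
  support so that both treatments are clearly active without
  eradicating the tumour; used for parameter recovery and posterior
  diagnostics; and
* the *selection* studies — one dataset per chemotherapy-response law,
  with ground truths designed so the two laws are actually
  distinguishable from monotherapy arms alone (a Hill switch that
  shuts off mid-arm for the threshold truth; volume-independent kill
  for the continuous truth).
"""

from __future__ import annotations

from .inference import ABCConfig, PriorSpec, abc_smc
from .params import ChemoResponse, GrowthParams, PKParams
from .pk import Drug
from .synthetic import NoiseModel, StudyDesign, generate_study, \
    schedules_from_truth

# Shared untreated-growth and PK ground truth (all inside the prior
# ranges): Gompertz rate 0.15/day, untreated plateau ~1.4e3 mm^3,
# moderate bvz suppression (alpha comparable to typical I1 levels).
_BASE_GROWTH = dict(lambda1=0.15, lambda2=0.002, c=1.5, d=0.12, alpha=0.05)

PK_TRUE = {Drug.BVZ: PKParams(k12=0.3, k21=0.2, ke=0.7),
           Drug.FOLFOX: PKParams(k12=0.1, k21=0.3, ke=0.8)}


def recovery_truth() -> tuple[GrowthParams, ChemoResponse]:
    """Threshold-model ground truth of the recovery study."""
    growth = GrowthParams(kf=0.08, **_BASE_GROWTH)
    chemo = ChemoResponse("threshold", alpha2=300.0, hill=15.0)
    return growth, chemo


def selection_truth(variant: str) -> tuple[GrowthParams, ChemoResponse]:
    """Ground truths of the model-selection studies."""
    if variant == "threshold":
        return (GrowthParams(kf=0.3, **_BASE_GROWTH),
                ChemoResponse("threshold", alpha2=450.0, hill=15.0))
    if variant == "continuous":
        return (GrowthParams(kf=0.03, **_BASE_GROWTH),
                ChemoResponse("continuous", alpha1=0.0, beta1=1.0))
    raise ValueError(f"unknown variant {variant!r}")


def make_recovery_study(seed: int = 11):
    """Generate the three-arm recovery dataset.

    Returns (datasets, truth_record, schedules)."""
    growth, chemo = recovery_truth()
    ds, truth = generate_study(growth, chemo, PK_TRUE, StudyDesign(),
                               NoiseModel(), seed=seed)
    return ds, truth, schedules_from_truth(truth)


def make_selection_study(variant: str, seed: int = 21):
    growth, chemo = selection_truth(variant)
    ds, truth = generate_study(growth, chemo, PK_TRUE, StudyDesign(),
                               NoiseModel(), seed=seed)
    return ds, truth, schedules_from_truth(truth)


# ABC budgets of the two reference experiments.  The recovery fit uses
# the prior generation plus six tolerance updates at the 0.07 quantile;
# the selection fits need a longer, gentler schedule so the weaker
# model family survives the middle generations where the two laws still
# mimic each other.
RECOVERY_ABC = dict(n_particles=2000, n_generations=7,
                    epsilon_quantile=0.07, model="threshold")
SELECTION_ABC = dict(n_particles=1500, n_generations=14,
                     epsilon_quantile=0.15, model="both")


def run_recovery(data_seed: int = 11, abc_seed: int = 1,
                 progress: bool = False, **overrides):
    """Run the recovery fit; returns (populations, meta, datasets,
    truth_record)."""
    ds, truth, schedules = make_recovery_study(data_seed)
    cfg = ABCConfig(seed=abc_seed, **{**RECOVERY_ABC, **overrides})
    pops, meta = abc_smc(PriorSpec(), ds, schedules, cfg, progress=progress)
    return pops, meta, ds, truth


def run_selection(variant: str, data_seed: int = 21, abc_seed: int = 2,
                  progress: bool = False, **overrides):
    """Run one model-selection fit; returns (populations, meta,
    datasets, truth_record)."""
    ds, truth, schedules = make_selection_study(variant, data_seed)
    cfg = ABCConfig(seed=abc_seed, **{**SELECTION_ABC, **overrides})
    pops, meta = abc_smc(PriorSpec(), ds, schedules, cfg, progress=progress)
    return pops, meta, ds, truth
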