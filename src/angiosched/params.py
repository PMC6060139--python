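"""Parameter containers for the vascular tumour growth model.

The model couples tumour volume V (mm^3) to a time-varying carrying
capacity K (mm^3) representing the vascular support of the tumour
(Hahnfeldt-family dynamics), forced by plasma concentrations of an
anti-angiogenic antibody (bevacizumab, "bvz") and a lumped
chemotherapy species ("FOLFOX").  All equations are implemented in raw
numeric units (days, mm^3, mg, ml) without unit conversion.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from enum import Enum


# Fixed structural constants (not inferred).
BETA: float = 1.0          # extent of the abnormal vascular phenotype, mm^{3p}
P_EXP: float = 0.0         # abnormal-phenotype exponent (dimensionless)
VC_ML: float = 7.975       # central-compartment volume, ml
DOSE_BVZ_MG: float = 10.0  # per-administration bvz dose, mg
DOSE_FOLFOX_MG: float = 56.0  # per-administration lumped FOLFOX dose, mg
T_INF_DAY: float = 1.0 / 48.0  # infusion duration, day (30 min)
MOUSE_WEIGHT_KG: float = 0.025  # carried as metadata only; never enters the RHS


class ChemoVariant(str, Enum):
    """Rival functional forms for chemotherapy-mediated tumour kill."""

    CONTINUOUS = "continuous"  # power-law product (V-V*)^a1 (K-V*)^b1
    THRESHOLD = "threshold"    # (V-V*) x Hill switch in (K-V*)


@dataclass(frozen=True)
class GrowthParams:
    """Growth, vasculature and treatment-response constants.

    Parameters
    ----------
    lambda1 : float
        Gompertzian growth constant, day^-1.
    lambda2 : float
        Vasculature degradation rate (endothelial half-life), day^-1.
    c : float
        Vasculature recruitment rate by the tumour, mg/(day mm^{3p} kg).
        Strictly positive: c = 0 would allow an untreated tumour with a
        self-regressing carrying capacity.
    d : float
        Endogenous inhibition of tumour vasculature, day^-1 mm^-2.
    alpha : float
        Stimulator (pro-angiogenic factor) clearance rate, mg/(mm^{3p} kg).
    beta : float
        Extent of the abnormal vascular phenotype, mm^{3p} (fixed 1).
    p : float
        Abnormal-phenotype exponent (fixed 0).
    v_star : float
        Prevascular volume, mm^3 — tumour volume sustainable without
        angiogenesis.  Default 0 recovers the classical system exactly.
    kf : float
        Tumour-cell degradation rate due to chemotherapy, day^-1 mm^-2.
    """

    lambda1: float
    lambda2: float
    c: float
    d: float
    alpha: float
    beta: float = BETA
    p: float = P_EXP
    v_star: float = 0.0
    kf: float = 0.0

    def __post_init__(self) -> None:
        for name in ("lambda1", "lambda2", "d", "alpha", "kf", "v_star"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0, got {getattr(self, name)}")
        if self.c <= 0:
            raise ValueError(f"c must be > 0, got {self.c}")


@dataclass(frozen=True)
class ChemoResponse:
    """Functional form f(V-V*, K-V*) of chemotherapy-mediated kill.

    ``continuous``: f = (V-V*)^alpha1 (V/K power-law product), a
    second-order-reaction form; exponents alpha1, beta1 allow nonlinear
    dependence on tumour volume and vasculature.

    ``threshold``: f = (V-V*) * (K-V*)^h / (alpha2^h + (K-V*)^h), kill
    linear in tumour volume and Hill-saturating in vasculature; in the
    large-``hill`` limit the dependence on K becomes switch-like.  The
    Hill exponent is printed both p1 and p2 in the source material; it
    is housed once here as ``hill``.
    """

    variant: ChemoVariant
    alpha1: float = 1.0
    beta1: float = 1.0
    alpha2: float = 1.0
    hill: float = 1.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "variant", ChemoVariant(self.variant))
        if self.variant is ChemoVariant.THRESHOLD:
            if self.hill < 0:
                raise ValueError("hill must be >= 0")
            if self.alpha2 <= 0:
                raise ValueError("alpha2 must be > 0")
        else:
            import math
            if not (math.isfinite(self.alpha1) and math.isfinite(self.beta1)):
                raise ValueError("alpha1/beta1 must be finite")


@dataclass(frozen=True)
class State:
    """Instantaneous model state: tumour volume and carrying capacity, mm^3."""

    v: float
    k: float


@dataclass(frozen=True)
class PKParams:
    """Two-compartment PK rate constants for one drug.

    First-order elimination from a central compartment of volume ``vc``
    (blood and highly perfused tissue); the peripheral compartment is
    poorly perfused tissue.  Drug enters by zero-order infusion.
    """

    k12: float  # central -> peripheral transfer, day^-1
    k21: float  # peripheral -> central transfer, day^-1
    ke: float   # elimination from central compartment, day^-1
    vc: float = VC_ML  # central-compartment volume, ml

    def __post_init__(self) -> None:
        for name in ("k12", "k21", "ke", "vc"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")


def params_to_dict(growth: GrowthParams, chemo: ChemoResponse,
                   pk_bvz: PKParams, pk_folfox: PKParams) -> dict:
    """Flatten a full parameter set to the flat key-value convention
    (lambda1, lambda2, c, d, alpha, beta, p, Kf, Bk12..., alpha1/beta1 or
    alpha2/p1)."""
    out = {
        "lambda1": growth.lambda1, "lambda2": growth.lambda2,
        "c": growth.c, "d": growth.d, "alpha": growth.alpha,
        "beta": growth.beta, "p": growth.p, "v_star": growth.v_star,
        "Kf": growth.kf,
        "Bk12": pk_bvz.k12, "Bk21": pk_bvz.k21, "Bke": pk_bvz.ke,
        "Fk12": pk_folfox.k12, "Fk21": pk_folfox.k21, "Fke": pk_folfox.ke,
        "Vc": pk_bvz.vc,
        "model": chemo.variant.value,
    }
    if chemo.variant is ChemoVariant.CONTINUOUS:
        out["alpha1"] = chemo.alpha1
        out["beta1"] = chemo.beta1
    else:
        out["alpha2"] = chemo.alpha2
        out["p1"] = chemo.hill
    return out


def params_from_dict(d: dict) -> tuple[GrowthParams, ChemoResponse, PKParams, PKParams]:
    """Inverse of :func:`params_to_dict`."""
    growth = GrowthParams(
        lambda1=d["lambda1"], lambda2=d["lambda2"], c=d["c"], d=d["d"],
        alpha=d["alpha"], beta=d.get("beta", BETA), p=d.get("p", P_EXP),
        v_star=d.get("v_star", 0.0), kf=d.get("Kf", 0.0))
    variant = ChemoVariant(d.get("model", "continuous"))
    if variant is ChemoVariant.CONTINUOUS:
        chemo = ChemoResponse(variant, alpha1=d.get("alpha1", 1.0),
                              beta1=d.get("beta1", 1.0))
    else:
        chemo = ChemoResponse(variant, alpha2=d["alpha2"], hill=d["p1"])
    vc = d.get("Vc", VC_ML)
    pk_b = PKParams(d["Bk12"], d["Bk21"], d["Bke"], vc)
    pk_f = PKParams(d["Fk12"], d["Fk21"], d["Fke"], vc)
    return growth, chemo, pk_b, pk_f


def save_params(path, growth, chemo, pk_bvz, pk_folfox) -> None:
    with open(path, "w") as fh:
        json.dump(params_to_dict(growth, chemo, pk_bvz, pk_folfox), fh, indent=2)


def load_params(path):
    with open(path) as fh:
        return params_from_dict(json.load(fh))


# Published example parameter sets (figure-caption values), used by the
# analysis drivers and tests as fixed, realistic operating points.
FIG2_CONTINUOUS: dict = dict(
    lambda1=0.067, lambda2=4.15e-5, c=0.04, alpha=9.81e-4, d=0.47,
    Bk12=0.47, Bk21=0.089, Bke=0.79, Fk12=0.0014, Fk21=0.39, Fke=0.91,
    Kf=0.057, alpha1=1.0, beta1=1.0, model="continuous")

FIG3_THRESHOLD: dict = dict(
    lambda1=0.17, lambda2=3.39e-3, c=0.04, alpha=1.46e-3, d=0.19,
    Bk12=0.56, Bk21=0.012, Bke=0.95, Fk12=0.22, Fk21=0.038, Fke=0.86,
    Kf=1.12, alpha2=768.1, p1=17.95, model="threshold")

FIG4_BEST_FIT: dict = dict(
    lambda1=0.17, lambda2=1.51e-3, c=0.063, alpha=3.86e-3, d=0.29,
    Bk12=0.068, Bk21=0.18, Bke=0.78, Fk12=0.04, Fk21=0.88, Fke=0.83,
    Kf=0.94, alpha2=188.37, p1=19.56, model="threshold")

FIG5_BEST_FIT: dict = dict(
    lambda1=0.085, lambda2=2.51e-3, c=0.60, alpha=5.59e-3, d=0.80,
    Bk12=0.45, Bk21=0.008, Bke=0.78, Fk12=0.05, Fk21=0.22, Fke=0.50,
    Kf=1.65, alpha2=720.8, p1=12.24, model="threshold")
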