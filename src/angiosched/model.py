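"""Right-hand side of the tumour / carrying-capacity ODE system.

Dynamics (prevascular volume V* subtracted from every term):

    dV/dt = -lambda1 (V-V*) ln((V-V*)/(K-V*)) - Kf I2(t) f(V-V*, K-V*)
    dK/dt = -lambda2 (K-V*)
            + c beta (V-V*)^p (V-V*) / (alpha (beta + (V-V*)^p) + I1(t))
            - d (K-V*) (V-V*)^(2/3)

with I1 the plasma bvz concentration (suppressing vasculature
recruitment) and I2 the plasma chemotherapy concentration driving
tumour kill through the response law f.
"""

from __future__ import annotations

import math

from .params import ChemoResponse, ChemoVariant, GrowthParams, State

# Floor applied to the excess volumes inside the chemotherapy response
# only: negative exponents (the continuous law admits alpha1, beta1 < 0)
# diverge as V -> V*, and this keeps likelihood-free exploration of that
# region finite without touching well-behaved states.
EFFECT_FLOOR_MM3 = 1e-6


class DomainError(ValueError):
    """State left the model's domain (V <= V* or K <= V*)."""


def chemo_effect(state: State, growth: GrowthParams, chemo: ChemoResponse) -> float:
    """Chemotherapy response f(V-V*, K-V*), the vasculature-dependent
    delivery factor multiplying Kf * I2(t) in dV/dt.

    Raises
    ------
    DomainError
        If V <= V* or K <= V*.
    FloatingPointError
        If the response evaluates non-finite (e.g. strongly negative
        exponents at the clamp floor).
    """
    dv = state.v - growth.v_star
    dk = state.k - growth.v_star
    if dv <= 0 or dk <= 0:
        raise DomainError(f"state outside domain: V-V*={dv}, K-V*={dk}")
    dv = max(dv, EFFECT_FLOOR_MM3)
    dk = max(dk, EFFECT_FLOOR_MM3)
    if chemo.variant is ChemoVariant.CONTINUOUS:
        f = dv ** chemo.alpha1 * dk ** chemo.beta1
    else:
        h = chemo.hill
        # Hill ratio in log space to survive h ~ 20 at large K.
        r = h * (math.log(dk) - math.log(chemo.alpha2))
        if r > 0:
            sat = 1.0 / (1.0 + math.exp(-r))
        else:
            sat = math.exp(r) / (1.0 + math.exp(r))
        f = dv * sat
    if not math.isfinite(f):
        raise FloatingPointError("non-finite chemotherapy effect")
    return f


def rhs(t: float, state: State, growth: GrowthParams, chemo: ChemoResponse,
        i1: float, i2: float) -> tuple[float, float]:
    """(dV/dt, dK/dt) at time t given plasma concentrations i1 (bvz)
    and i2 (chemotherapy), both mg/ml."""
    dv = state.v - growth.v_star
    dk = state.k - growth.v_star
    if dv <= 0 or dk <= 0:
        raise DomainError(f"state outside domain: V-V*={dv}, K-V*={dk}")
    growth_term = -growth.lambda1 * dv * math.log(dv / dk)
    kill = 0.0
    if growth.kf > 0 and i2 > 0:
        kill = growth.kf * i2 * chemo_effect(state, growth, chemo)
    dvdt = growth_term - kill
    dvp = dv ** growth.p
    stim = growth.c * growth.beta * dvp * dv / (
        growth.alpha * (growth.beta + dvp) + i1)
    dkdt = -growth.lambda2 * dk + stim - growth.d * dk * dv ** (2.0 / 3.0)
    if not (math.isfinite(dvdt) and math.isfinite(dkdt)):
        raise FloatingPointError("non-finite derivative")
    return dvdt, dkdt


def untreated_asymptote(growth: GrowthParams) -> float:
    """Closed-form untreated steady state of the classical (V* = 0,
    p = 0, beta = 1) system: V_inf^(2/3) = (c/(2 alpha) - lambda2)/d.

    Returns the steady-state volume in mm^3; raises ValueError when the
    bracket is non-positive (tumour not sustainable)."""
    q = (growth.c / (2.0 * growth.alpha) - growth.lambda2) / growth.d
    if q <= 0:
        raise ValueError("no positive untreated steady state for these rates")
    return q ** 1.5
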