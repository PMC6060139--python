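"""Compiled adaptive integrator for likelihood-free inference.

ABC-SMC needs ~1e5 forward simulations per fit, so the inference path
uses a numba-compiled embedded Dormand-Prince 5(4) integrator with
standard proportional step control, split piecewise at infusion kink
times (the forcing is continuous but not smooth there).  The reference
path (scipy LSODA/BDF in :mod:`.simulate`) is the accuracy yardstick;
the two are cross-validated in the test suite.

Parameter vector layout (``par``):
    0 lambda1, 1 lambda2, 2 c, 3 d, 4 alpha, 5 beta, 6 p, 7 v_star,
    8 kf, 9 variant (0 = continuous, 1 = threshold), 10 x1, 11 x2
where (x1, x2) = (alpha1, beta1) for the continuous chemotherapy law
and (alpha2, hill) for the threshold law.

Per-drug PK forcing arrays: event start times, dose rates (dose/t_inf),
infusion durations, and scalars a, b, A, B of the biexponential closed
form.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

EFFECT_FLOOR = 1e-6


@njit(fastmath=False)
def conc_total(t, ev_t0, ev_rate, ev_tinf, a, b, A, B):
    """Superposed closed-form plasma concentration of one drug at t."""
    tot = 0.0
    for i in range(ev_t0.shape[0]):
        tau = t - ev_t0[i]
        if tau < 0.0:
            continue
        T = ev_tinf[i]
        if tau <= T:
            tot += ev_rate[i] * ((A / a) * (1.0 - math.exp(-a * tau))
                                 + (B / b) * (1.0 - math.exp(-b * tau)))
        else:
            tot += ev_rate[i] * ((A / a) * (1.0 - math.exp(-a * T))
                                 * math.exp(-a * (tau - T))
                                 + (B / b) * (1.0 - math.exp(-b * T))
                                 * math.exp(-b * (tau - T)))
    return tot


@njit(fastmath=False)
def _rhs(t, v, k, par,
         bt0, brate, btinf, ba, bb, bA, bB,
         ft0, frate, ftinf, fa, fb, fA, fB):
    """(dV/dt, dK/dt); NaNs when the state leaves the model domain."""
    v_star = par[7]
    dv = v - v_star
    dk = k - v_star
    if dv <= 0.0 or dk <= 0.0:
        return np.nan, np.nan
    growth = -par[0] * dv * math.log(dv / dk)
    kill = 0.0
    kf = par[8]
    if kf > 0.0 and ft0.shape[0] > 0:
        i2 = conc_total(t, ft0, frate, ftinf, fa, fb, fA, fB)
        if i2 > 0.0:
            dvc = max(dv, EFFECT_FLOOR)
            dkc = max(dk, EFFECT_FLOOR)
            if par[9] < 0.5:  # continuous power-law product
                f = math.exp(par[10] * math.log(dvc) + par[11] * math.log(dkc))
            else:             # threshold: linear in V, Hill switch in K
                r = par[11] * (math.log(dkc) - math.log(par[10]))
                if r > 0.0:
                    sat = 1.0 / (1.0 + math.exp(-r))
                else:
                    er = math.exp(r)
                    sat = er / (1.0 + er)
                f = dvc * sat
            kill = kf * i2 * f
    i1 = 0.0
    if bt0.shape[0] > 0:
        i1 = conc_total(t, bt0, brate, btinf, ba, bb, bA, bB)
    beta = par[5]
    p = par[6]
    dvp = math.exp(p * math.log(max(dv, EFFECT_FLOOR))) if p != 0.0 else 1.0
    stim = par[2] * beta * dvp * dv / (par[4] * (beta + dvp) + i1)
    dkdt = -par[1] * dk + stim - par[3] * dk * dv ** (2.0 / 3.0)
    return growth - kill, dkdt


# Dormand-Prince 5(4) coefficients.
_A21 = 1.0 / 5.0
_A31, _A32 = 3.0 / 40.0, 9.0 / 40.0
_A41, _A42, _A43 = 44.0 / 45.0, -56.0 / 15.0, 32.0 / 9.0
_A51, _A52, _A53, _A54 = (19372.0 / 6561.0, -25360.0 / 2187.0,
                          64448.0 / 6561.0, -212.0 / 729.0)
_A61, _A62, _A63, _A64, _A65 = (9017.0 / 3168.0, -355.0 / 33.0,
                                46732.0 / 5247.0, 49.0 / 176.0,
                                -5103.0 / 18656.0)
_B1, _B3, _B4, _B5, _B6 = (35.0 / 384.0, 500.0 / 1113.0, 125.0 / 192.0,
                           -2187.0 / 6784.0, 11.0 / 84.0)
_E1, _E3, _E4, _E5, _E6, _E7 = (35.0 / 384.0 - 5179.0 / 57600.0,
                                500.0 / 1113.0 - 7571.0 / 16695.0,
                                125.0 / 192.0 - 393.0 / 640.0,
                                -2187.0 / 6784.0 + 92097.0 / 339200.0,
                                11.0 / 84.0 - 187.0 / 2100.0,
                                -1.0 / 40.0)
_C2, _C3, _C4, _C5 = 1.0 / 5.0, 3.0 / 10.0, 4.0 / 5.0, 8.0 / 9.0


@njit(fastmath=False)
def _dp45_segment(t0, t1, v, k, par, rtol, atol, hmax, h0,
                  bt0, brate, btinf, ba, bb, bA, bB,
                  ft0, frate, ftinf, fa, fb, fA, fB):
    """Integrate one smooth segment [t0, t1].

    Returns (v, k, h_next, ok); ``h_next`` seeds the next segment."""
    t = t0
    h = min(h0, hmax, t1 - t0)
    while t < t1 - 1e-12:
        if h < 1e-10:
            return v, k, h, False
        if t + h > t1:
            h = t1 - t
        k1v, k1k = _rhs(t, v, k, par, bt0, brate, btinf, ba, bb, bA, bB,
                        ft0, frate, ftinf, fa, fb, fA, fB)
        k2v, k2k = _rhs(t + _C2 * h, v + h * _A21 * k1v, k + h * _A21 * k1k,
                        par, bt0, brate, btinf, ba, bb, bA, bB,
                        ft0, frate, ftinf, fa, fb, fA, fB)
        k3v, k3k = _rhs(t + _C3 * h, v + h * (_A31 * k1v + _A32 * k2v),
                        k + h * (_A31 * k1k + _A32 * k2k),
                        par, bt0, brate, btinf, ba, bb, bA, bB,
                        ft0, frate, ftinf, fa, fb, fA, fB)
        k4v, k4k = _rhs(t + _C4 * h,
                        v + h * (_A41 * k1v + _A42 * k2v + _A43 * k3v),
                        k + h * (_A41 * k1k + _A42 * k2k + _A43 * k3k),
                        par, bt0, brate, btinf, ba, bb, bA, bB,
                        ft0, frate, ftinf, fa, fb, fA, fB)
        k5v, k5k = _rhs(t + _C5 * h,
                        v + h * (_A51 * k1v + _A52 * k2v + _A53 * k3v
                                 + _A54 * k4v),
                        k + h * (_A51 * k1k + _A52 * k2k + _A53 * k3k
                                 + _A54 * k4k),
                        par, bt0, brate, btinf, ba, bb, bA, bB,
                        ft0, frate, ftinf, fa, fb, fA, fB)
        k6v, k6k = _rhs(t + h,
                        v + h * (_A61 * k1v + _A62 * k2v + _A63 * k3v
                                 + _A64 * k4v + _A65 * k5v),
                        k + h * (_A61 * k1k + _A62 * k2k + _A63 * k3k
                                 + _A64 * k4k + _A65 * k5k),
                        par, bt0, brate, btinf, ba, bb, bA, bB,
                        ft0, frate, ftinf, fa, fb, fA, fB)
        v5 = v + h * (_B1 * k1v + _B3 * k3v + _B4 * k4v + _B5 * k5v
                      + _B6 * k6v)
        k5_ = k + h * (_B1 * k1k + _B3 * k3k + _B4 * k4k + _B5 * k5k
                       + _B6 * k6k)
        k7v, k7k = _rhs(t + h, v5, k5_, par, bt0, brate, btinf,
                        ba, bb, bA, bB, ft0, frate, ftinf, fa, fb, fA, fB)
        bad = not (math.isfinite(v5) and math.isfinite(k5_)
                   and math.isfinite(k7v) and math.isfinite(k7k))
        if bad:
            h *= 0.2
            continue
        ev = h * (_E1 * k1v + _E3 * k3v + _E4 * k4v + _E5 * k5v
                  + _E6 * k6v + _E7 * k7v)
        ek = h * (_E1 * k1k + _E3 * k3k + _E4 * k4k + _E5 * k5k
                  + _E6 * k6k + _E7 * k7k)
        sv = atol + rtol * abs(v5)
        sk = atol + rtol * abs(k5_)
        err = math.sqrt(0.5 * ((ev / sv) ** 2 + (ek / sk) ** 2))
        if err <= 1.0:
            t += h
            v = v5
            k = k5_
            if v <= par[7] or k <= par[7]:
                return v, k, h, False
            fac = 5.0 if err == 0.0 else min(5.0, 0.9 * err ** -0.2)
            h = min(h * fac, hmax)
        else:
            h = max(h * max(0.2, 0.9 * err ** -0.2), 1e-11)
    return v, k, h, True


@njit(fastmath=False)
def integrate(t_nodes, out_mask, v0, k0, par, rtol, atol, hmax,
              bt0, brate, btinf, ba, bb, bA, bB,
              ft0, frate, ftinf, fa, fb, fA, fB):
    """Adaptive integration over consecutive ``t_nodes`` (kinks plus
    output times merged); records state where ``out_mask`` is set.

    Returns (v_out, k_out, ok): ok is False when the state leaves the
    domain (V or K <= V*) or the step size collapses.
    """
    n_out = 0
    for i in range(out_mask.shape[0]):
        if out_mask[i]:
            n_out += 1
    v_out = np.empty(n_out)
    k_out = np.empty(n_out)
    v = v0
    k = k0
    j = 0
    if out_mask[0]:
        v_out[0] = v
        k_out[0] = k
        j = 1
    h = hmax
    for seg in range(t_nodes.shape[0] - 1):
        v, k, h, ok = _dp45_segment(
            t_nodes[seg], t_nodes[seg + 1], v, k, par, rtol, atol, hmax, h,
            bt0, brate, btinf, ba, bb, bA, bB,
            ft0, frate, ftinf, fa, fb, fA, fB)
        if not ok:
            return v_out, k_out, False
        if out_mask[seg + 1]:
            v_out[j] = v
            k_out[j] = k
            j += 1
    return v_out, k_out, True


@njit(fastmath=False)
def sse_study(eps, node_cat, node_off, mask_cat, vobs_cat, v0s, k0s,
              par, rtol, atol, hmax,
              bt0_cat, brate_cat, btinf_cat, boff, ba, bb, bA, bB,
              ft0_cat, frate_cat, ftinf_cat, foff, fa, fb, fA, fB):
    """Pooled squared-error distance over all study arms in one pass.

    Arm arrays are concatenated with offset vectors (``node_off``,
    ``boff``, ``foff``).  Integration aborts and returns +inf as soon
    as the accumulated squared error exceeds ``eps`` (or an arm's
    integration fails), which is what makes likelihood-free rejection
    affordable.
    """
    n_arms = v0s.shape[0]
    sse = 0.0
    iobs = 0  # runs over masked nodes of all arms in order
    for ai in range(n_arms):
        lo, hi = node_off[ai], node_off[ai + 1]
        nodes = node_cat[lo:hi]
        mask = mask_cat[lo:hi]
        bt0 = bt0_cat[boff[ai]:boff[ai + 1]]
        brate = brate_cat[boff[ai]:boff[ai + 1]]
        btinf = btinf_cat[boff[ai]:boff[ai + 1]]
        ft0 = ft0_cat[foff[ai]:foff[ai + 1]]
        frate = frate_cat[foff[ai]:foff[ai + 1]]
        ftinf = ftinf_cat[foff[ai]:foff[ai + 1]]
        v = v0s[ai]
        k = k0s[ai]
        if mask[0]:
            diff = v - vobs_cat[iobs]
            sse += diff * diff
            iobs += 1
            if sse > eps:
                return np.inf
        h = hmax
        for seg in range(nodes.shape[0] - 1):
            v, k, h, ok = _dp45_segment(
                nodes[seg], nodes[seg + 1], v, k, par, rtol, atol, hmax, h,
                bt0, brate, btinf, ba, bb, bA, bB,
                ft0, frate, ftinf, fa, fb, fA, fB)
            if not ok:
                return np.inf
            if mask[seg + 1]:
                diff = v - vobs_cat[iobs]
                sse += diff * diff
                iobs += 1
                if sse > eps:
                    return np.inf
    return sse


def warm_up() -> None:
    """Trigger JIT compilation once (used by test sessions and drivers)."""
    par = np.array([0.1, 1e-3, 0.05, 0.2, 1e-3, 1.0, 0.0, 0.0, 0.1, 1.0,
                    100.0, 10.0])
    e = np.array([0.0])
    r = np.array([480.0])
    ti = np.array([1.0 / 48.0])
    nodes = np.array([0.0, 1.0 / 48.0, 1.0])
    mask = np.array([True, False, True])
    integrate(nodes, mask, 1.0, 10.0, par, 1e-6, 1e-8, 0.5,
              e, r, ti, 0.5, 0.1, 0.1, -0.02,
              e, r, ti, 0.5, 0.1, 0.1, -0.02)
    off = np.array([0, 3])
    eoff = np.array([0, 1])
    sse_study(np.inf, nodes, off, mask, np.array([1.0, 2.0]),
              np.array([1.0]), np.array([10.0]), par, 1e-5, 1e-3, 1.0,
              e, r, ti, eoff, 0.5, 0.1, 0.1, -0.02,
              e, r, ti, eoff, 0.5, 0.1, 0.1, -0.02)
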