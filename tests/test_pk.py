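"""Pharmacokinetics: hybrid constants, closed-form concentrations,
superposition and schedule constructors."""

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy.integrate import quad, solve_ivp

import angiosched as ang
from angiosched.pk import (DegeneratePKError, DoseEvent, Drug, Schedule,
                           concentration, concentration_single, pk_constants,
                           ts1_schedule, ts2_schedule, vehicle_schedule,
                           with_break)
from angiosched.params import PKParams, T_INF_DAY

BVZ_FIG2 = PKParams(k12=0.47, k21=0.089, ke=0.79)


def compartment_ode_oracle(ts, event: DoseEvent, pk: PKParams):
    """Independent oracle: integrate the two-compartment mass-balance
    ODEs (amounts; central concentration = A_c / Vc) with the infusion
    as a square-pulse input."""
    rate = event.dose_mg / event.t_inf

    def f(t, y):
        ac, ap = y
        inp = rate if event.t_start <= t <= event.t_start + event.t_inf \
            else 0.0
        return (inp - (pk.k12 + pk.ke) * ac + pk.k21 * ap,
                pk.k12 * ac - pk.k21 * ap)

    out = np.empty_like(ts, dtype=float)
    y = [0.0, 0.0]
    t_prev = 0.0
    # integrate piecewise so the pulse edges are exact segment ends
    edges = sorted({event.t_start, event.t_start + event.t_inf})
    for i, t in enumerate(ts):
        seg = [t_prev] + [e for e in edges if t_prev < e < t] + [t]
        for a, b in zip(seg, seg[1:]):
            sol = solve_ivp(f, (a, b), y, method="LSODA", rtol=1e-11,
                            atol=1e-14)
            y = sol.y[:, -1]
        out[i] = y[0] / pk.vc
        t_prev = t
    return out


class TestHybridConstants:
    def test_decoupled_limit(self):
        """k12 -> 0 decouples the compartments: {a, b} = {k21, ke}."""
        pk = PKParams(k12=1e-12, k21=0.3, ke=0.8)
        a, b, _, _ = pk_constants(pk)
        assert sorted([a, b]) == pytest.approx(sorted([0.3, 0.8]), rel=1e-9)

    def test_eigenvalue_oracle(self):
        """a, b equal the decay eigenvalues of the transfer matrix."""
        pk = BVZ_FIG2
        a, b, _, _ = pk_constants(pk)
        M = np.array([[-(pk.k12 + pk.ke), pk.k21], [pk.k12, -pk.k21]])
        eig = sorted(-np.linalg.eigvals(M).real)
        assert sorted([b, a]) == pytest.approx(eig, rel=1e-10)

    @given(st.floats(0.01, 1.0), st.floats(0.01, 1.0), st.floats(0.01, 1.0))
    def test_algebraic_identities(self, k12, k21, ke):
        """a + b = k12 + k21 + ke and a b = k21 ke always hold."""
        try:
            a, b, _, _ = pk_constants(PKParams(k12=k12, k21=k21, ke=ke))
        except DegeneratePKError:
            return
        assert a + b == pytest.approx(k12 + k21 + ke, rel=1e-10)
        assert a * b == pytest.approx(k21 * ke, rel=1e-10)

    def test_degenerate_raises(self):
        with pytest.raises(DegeneratePKError):
            pk_constants(PKParams(k12=1e-18, k21=0.5, ke=0.5))


class TestConcentrationSingle:
    def test_zero_at_start_and_before(self):
        ev = DoseEvent(Drug.BVZ, 3.0)
        assert concentration_single(3.0, ev, BVZ_FIG2) == 0.0
        assert concentration_single(1.0, ev, BVZ_FIG2) == 0.0

    def test_continuity_at_infusion_end(self):
        """The during- and post-infusion branches agree at t_D + T."""
        ev = DoseEvent(Drug.BVZ, 0.0)
        T = ev.t_inf
        c_end = concentration_single(T, ev, BVZ_FIG2)
        c_after = concentration_single(T + 1e-12, ev, BVZ_FIG2)
        assert c_after == pytest.approx(c_end, rel=1e-9)

    def test_ode_oracle(self):
        """Closed form vs stiff integration of the compartment system,
        published bvz rates, D = 10 mg, T = 30 min."""
        ev = DoseEvent(Drug.BVZ, 0.0, dose=10.0)
        ts = np.array([0.005, T_INF_DAY, 0.05, 0.2, 0.5, 1.0, 2.0, 5.0,
                       10.0, 20.0])
        closed = concentration_single(ts, ev, BVZ_FIG2)
        oracle = compartment_ode_oracle(ts, ev, BVZ_FIG2)
        assert np.allclose(closed, oracle, rtol=1e-6,
                           atol=1e-6 * closed.max())

    def test_single_dose_auc(self):
        """Total exposure equals D / (Vc ke) analytically."""
        ev = DoseEvent(Drug.FOLFOX, 0.0, dose=56.0)
        pk = PKParams(k12=0.1, k21=0.3, ke=0.8)
        # decay rates >= 0.19/day: the [0, 400] window captures the
        # tail to far below the quadrature tolerance
        auc, _ = quad(lambda t: concentration_single(t, ev, pk), 0.0, 400.0,
                      points=[ev.t_inf, 1.0, 10.0, 50.0], limit=300)
        assert auc == pytest.approx(ev.dose_mg / (pk.vc * pk.ke), rel=1e-3)

    def test_non_negative_and_decaying(self):
        ev = DoseEvent(Drug.BVZ, 0.0)
        ts = np.linspace(0, 365, 4000)
        c = concentration_single(ts, ev, BVZ_FIG2)
        assert np.all(c >= 0)
        assert c[-1] < 1e-6 * c.max()


class TestSuperposition:
    def test_empty_schedule(self):
        ts = np.linspace(0, 10, 50)
        c = concentration(ts, vehicle_schedule(45), {}, Drug.BVZ)
        assert np.all(c == 0)

    def test_linearity(self):
        """Two doses = sum of the time-shifted single-dose curves."""
        sched = Schedule((DoseEvent(Drug.BVZ, 0.0), DoseEvent(Drug.BVZ, 7.0)))
        pk = {Drug.BVZ: BVZ_FIG2}
        total = concentration(20.0, sched, pk, Drug.BVZ)
        parts = (concentration_single(20.0, DoseEvent(Drug.BVZ, 0.0),
                                      BVZ_FIG2)
                 + concentration_single(13.0 + 7.0, DoseEvent(Drug.BVZ, 7.0),
                                        BVZ_FIG2))
        assert total == pytest.approx(parts, rel=1e-12)

    def test_weekly_schedule_ode_oracle(self):
        """Weekly x4 bvz superposition vs one continuous compartment-ODE
        integration carrying state across doses."""
        events = [DoseEvent(Drug.BVZ, 7.0 * i, dose=10.0) for i in range(4)]
        sched = Schedule(tuple(events), horizon=45.0)
        pk = BVZ_FIG2
        rate = 10.0 / T_INF_DAY

        def f(t, y):
            inp = sum(rate for e in events
                      if e.t_start <= t <= e.t_start + e.t_inf)
            return (inp - (pk.k12 + pk.ke) * y[0] + pk.k21 * y[1],
                    pk.k12 * y[0] - pk.k21 * y[1])

        edges = sorted({e.t_start for e in events}
                       | {e.t_start + e.t_inf for e in events})
        ts = np.array([0.5, 3.0, 7.5, 10.0, 14.5, 21.5, 30.0, 44.0])
        y = [0.0, 0.0]
        t_prev = 0.0
        oracle = []
        for t in ts:
            seg = [t_prev] + [e for e in edges if t_prev < e < t] + [t]
            for a, b in zip(seg, seg[1:]):
                sol = solve_ivp(f, (a, b), y, method="LSODA", rtol=1e-11,
                                atol=1e-14)
                y = sol.y[:, -1]
            oracle.append(y[0] / pk.vc)
            t_prev = t
        closed = concentration(ts, sched, {Drug.BVZ: pk}, Drug.BVZ)
        assert np.allclose(closed, np.array(oracle), rtol=1e-6,
                           atol=1e-8)


class TestSchedules:
    def test_ts1_ts2_ordering(self):
        ts1 = ts1_schedule()
        ts2 = ts2_schedule()
        first_bvz = min(e.t_start for e in ts1.events if e.drug is Drug.BVZ)
        first_fol = min(e.t_start for e in ts1.events
                        if e.drug is Drug.FOLFOX)
        assert first_fol - first_bvz == pytest.approx(1.0)
        first_bvz2 = min(e.t_start for e in ts2.events if e.drug is Drug.BVZ)
        first_fol2 = min(e.t_start for e in ts2.events
                         if e.drug is Drug.FOLFOX)
        assert first_bvz2 - first_fol2 == pytest.approx(1.0)

    def test_with_break_identities(self):
        sched = ts1_schedule()
        assert with_break(sched, 10.0, 0.0).events == sched.events
        moved = with_break(sched, 100.0, 21.0)
        assert moved.events == sched.events

    def test_with_break_defers(self):
        sched = ts1_schedule()
        moved = with_break(sched, 14.0, 21.0)
        for e0, e1 in zip(sched.events, moved.events):
            if e0.t_start < 14.0:
                assert e1.t_start == e0.t_start
            else:
                assert e1.t_start == e0.t_start + 21.0

    def test_schedule_roundtrip(self, tmp_path):
        sched = ts2_schedule(start=5.0, n_cycles=3)
        path = tmp_path / "sched.tsv"
        ang.save_schedule(path, sched)
        back = ang.load_schedule(path, horizon=sched.horizon)
        orig = [(e.drug, e.t_start, e.dose_mg, e.t_inf) for e in sched.events]
        got = [(e.drug, e.t_start, e.dose_mg, e.t_inf) for e in back.events]
        assert got == orig

    def test_overlapping_doses_rejected(self):
        with pytest.raises(ValueError):
            Schedule((DoseEvent(Drug.BVZ, 0.0),
                      DoseEvent(Drug.BVZ, 0.001)))
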