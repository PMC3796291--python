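"""Turnover pharmacodynamics and the double-delta transform."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import solve_ivp

from mrpkpd import (
    DeltaResponseParameters,
    UacrIrmParameters,
    ValidationError,
    double_delta,
    simulate_delta_response,
    simulate_uacr,
    vehicle_reference,
)

from conftest import euler_turnover


class TestUacrModel:
    def test_steady_state_without_drug(self):
        p = UacrIrmParameters(kin=2.0, kout=0.1, imax=0.5, ic50=10.0, uacr0=20.0)
        u = simulate_uacr(p, lambda t: np.zeros_like(t), np.linspace(0, 30, 7))
        assert u == pytest.approx(np.full(7, 20.0), rel=1e-9)

    def test_untreated_disease_rises_to_asymptote(self):
        # uacr0 below Kin/Kout: monotone rise saturating at Kin/Kout = 20
        p = UacrIrmParameters(kin=2.0, kout=0.1, imax=0.5, ic50=10.0, uacr0=5.0)
        t = np.linspace(0, 120, 25)
        u = simulate_uacr(p, lambda tt: np.zeros_like(tt), t)
        assert np.all(np.diff(u) > 0)
        assert u[-1] == pytest.approx(20.0, rel=1e-4)
        assert np.all(u < 20.0 + 1e-9)

    def test_saturating_inhibition_closed_form_decay(self):
        # Imax=1 and C >> IC50 shuts production off: U(t) = uacr0*exp(-Kout*t)
        p = UacrIrmParameters(kin=2.0, kout=0.1, imax=1.0, ic50=1.0, uacr0=10.0)
        u = simulate_uacr(p, lambda t: np.full_like(t, 1e9), [0.0, 10.0])
        assert u[-1] == pytest.approx(10.0 * np.exp(-1.0), rel=1e-4)

    def test_imax_zero_is_concentration_independent(self):
        p = UacrIrmParameters(kin=3.0, kout=0.2, imax=0.0, ic50=5.0, uacr0=7.0)
        t = np.linspace(0, 20, 9)
        u_none = simulate_uacr(p, lambda tt: np.zeros_like(tt), t)
        u_huge = simulate_uacr(p, lambda tt: np.full_like(tt, 1e6), t)
        assert u_none == pytest.approx(u_huge, rel=1e-12)

    def test_rejects_negative_concentration(self):
        p = UacrIrmParameters(kin=2.0, kout=0.1, imax=0.5, ic50=10.0, uacr0=5.0)
        with pytest.raises(ValidationError):
            simulate_uacr(p, lambda t: np.full_like(t, -1.0), [0.0, 1.0])

    def test_monotone_in_concentration(self):
        p = UacrIrmParameters(kin=2.0, kout=0.1, imax=0.9, ic50=10.0, uacr0=5.0)
        t = np.linspace(0, 30, 11)
        lo = simulate_uacr(p, lambda tt: np.full_like(tt, 1.0), t)
        hi = simulate_uacr(p, lambda tt: np.full_like(tt, 50.0), t)
        assert np.all(hi[1:] < lo[1:])


class TestDeltaModel:
    def test_zero_concentration_gives_zero_response(self):
        p = DeltaResponseParameters(kin_max=1.0, kout=0.5, ec50=3.0)
        d = simulate_delta_response(p, lambda t: np.zeros_like(t), np.linspace(0, 10, 5))
        assert np.all(d == 0.0)

    def test_half_maximal_steady_state(self):
        # C = EC50 -> steady state Kin_max * 0.5 / Kout = 1.0
        p = DeltaResponseParameters(kin_max=1.0, kout=0.5, ec50=3.0)
        d = simulate_delta_response(p, lambda t: np.full_like(t, 3.0), [0.0, 60.0])
        assert d[-1] == pytest.approx(1.0, rel=1e-6)

    def test_first_order_approach_to_steady_state(self):
        p = DeltaResponseParameters(kin_max=2.0, kout=0.25, ec50=1.0)
        dss = 2.0 * (5.0 / 6.0) / 0.25
        d = simulate_delta_response(p, lambda t: np.full_like(t, 5.0), [0.0, 4.0])
        assert d[-1] == pytest.approx(dss * (1 - np.exp(-1.0)), rel=1e-5)

    def test_monotone_in_concentration_and_nonnegative(self):
        p = DeltaResponseParameters(kin_max=1.0, kout=0.3, ec50=2.0)
        t = np.linspace(0, 12, 13)
        lo = simulate_delta_response(p, lambda tt: np.full_like(tt, 1.0), t)
        hi = simulate_delta_response(p, lambda tt: np.full_like(tt, 10.0), t)
        assert np.all(hi[1:] > lo[1:]) and np.all(lo >= 0)


class TestAgainstIndependentIntegrators:
    """The exponential-integrator engine vs scipy LSODA and explicit Euler."""

    def _pulse_conc(self, t):
        t = np.asarray(t, dtype=float)
        return 40.0 * (np.exp(-0.1 * t) - np.exp(-0.8 * t))

    def test_uacr_vs_solve_ivp(self):
        p = UacrIrmParameters(kin=7.9, kout=0.08, imax=0.95, ic50=10.4, uacr0=30.0)
        t_grid = np.array([0.0, 5.0, 14.0, 25.0])

        def rhs(t, y):
            c = self._pulse_conc(t)
            return p.kin * (1 - p.imax * c / (c + p.ic50)) - p.kout * y

        ref = solve_ivp(rhs, (0, 25), [p.uacr0], t_eval=t_grid,
                        rtol=1e-8, atol=1e-10, method="LSODA").y[0]
        mine = simulate_uacr(p, self._pulse_conc, t_grid)
        assert mine == pytest.approx(ref, rel=1e-3)

    def test_delta_vs_solve_ivp(self):
        p = DeltaResponseParameters(kin_max=0.9, kout=0.3, ec50=3.1)

        def rhs(t, y):
            c = self._pulse_conc(t)
            return p.kin_max * c / (c + p.ec50) - p.kout * y

        t_grid = np.array([0.0, 1.0, 3.0, 5.5, 7.0])
        ref = solve_ivp(rhs, (0, 7), [0.0], t_eval=t_grid,
                        rtol=1e-8, atol=1e-12, method="LSODA").y[0]
        mine = simulate_delta_response(p, self._pulse_conc, t_grid)
        assert mine == pytest.approx(ref, rel=1e-3, abs=1e-10)

    def test_uacr_vs_explicit_euler(self):
        p = UacrIrmParameters(kin=3.0, kout=0.15, imax=0.8, ic50=5.0, uacr0=12.0)
        ref = euler_turnover(self._pulse_conc, 20.0, p.kin, p.kout, p.uacr0,
                             imax=p.imax, ic50=p.ic50, h=0.0005)
        mine = simulate_uacr(p, self._pulse_conc, [0.0, 20.0])[-1]
        assert mine == pytest.approx(ref, rel=1e-3)


class TestDoubleDelta:
    def test_subject_equal_to_vehicle_gives_zeros(self):
        series = [(0.0, 4.1), (14.0, 4.4), (27.0, 4.9)]
        dd = double_delta(series, series)
        assert dd.values == pytest.approx(np.zeros(3), abs=1e-12)
        assert dd.values[0] == 0.0

    def test_arithmetic_example(self):
        subj = [(0.0, 4.0), (14.0, 4.5)]
        veh = [(0.0, 4.2), (14.0, 4.4)]
        dd = double_delta(subj, veh)
        assert dd.values[1] == pytest.approx(0.3)

    def test_constant_vehicle_reduces_to_change_from_baseline(self):
        subj = [(0.0, 3.0), (7.0, 3.8), (14.0, 2.5)]
        veh = [(0.0, 5.0), (14.0, 5.0)]
        dd = double_delta(subj, veh)
        assert dd.values == pytest.approx([0.0, 0.8, -0.5])

    def test_requires_time_zero_in_both_series(self):
        with pytest.raises(ValidationError):
            double_delta([(1.0, 2.0), (2.0, 2.5)], [(0.0, 1.0), (2.0, 1.0)])
        with pytest.raises(ValidationError):
            double_delta([(0.0, 2.0), (2.0, 2.5)], [(1.0, 1.0), (2.0, 1.0)])

    def test_vehicle_must_cover_subject_times(self):
        with pytest.raises(ValidationError):
            double_delta([(0.0, 1.0), (10.0, 2.0)], [(0.0, 1.0), (5.0, 1.5)])

    @settings(deadline=None, max_examples=25)
    @given(st.floats(-50.0, 50.0))
    def test_invariant_to_common_additive_shift(self, shift):
        subj = np.array([(0.0, 3.0), (7.0, 3.8), (14.0, 2.5)])
        veh = np.array([(0.0, 5.0), (7.0, 5.2), (14.0, 4.9)])
        base = double_delta(subj, veh).values
        shifted = double_delta(
            np.column_stack([subj[:, 0], subj[:, 1] + shift]),
            np.column_stack([veh[:, 0], veh[:, 1] + shift]),
        ).values
        assert shifted == pytest.approx(base, abs=1e-9)


class TestVehicleReference:
    def test_mean_across_pooled_studies(self):
        df = pd.DataFrame(
            {
                "ID": [1, 1, 2, 2, 3, 3],
                "TIME": [0.0, 7.0] * 3,
                "DV": [3.0, 4.0, 5.0, 6.0, 4.0, 5.0],
            }
        )
        ref = vehicle_reference(df)
        assert ref[:, 0].tolist() == [0.0, 7.0]
        assert ref[:, 1] == pytest.approx([4.0, 5.0])

    def test_single_animal_is_identity(self):
        df = pd.DataFrame({"ID": [9, 9], "TIME": [0.0, 3.0], "DV": [2.0, 2.5]})
        ref = vehicle_reference(df)
        assert ref[:, 1] == pytest.approx([2.0, 2.5])

    def test_empty_set_rejected(self):
        with pytest.raises(ValidationError):
            vehicle_reference(pd.DataFrame({"TIME": [], "DV": []}))
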