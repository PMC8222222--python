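import numpy as np
import pytest

from gatekit import gating
from gatekit.curves import boltzmann, boltzmann_single
from gatekit.errors import ArgumentError, EstimationError
from gatekit.gating import IVCurve, fit_boltzmann, qc_reversal, reversal_potential
from gatekit.synth import (
    GateParams,
    TwoGateModel,
    build_standard_protocol,
    simulate_sweepset,
)
from gatekit.traces import RecordingMeta, SweepSet

from conftest import FAST_PORE, LOCKED_COMMON, LOCKED_PORE, SLOW_COMMON_SAT


class TestReversalPotential:
    def test_ohmic_interpolation_exact(self):
        V = np.arange(-100.0, 101.0, 20.0)
        assert reversal_potential(IVCurve(V, 0.5 * (V - 10.0))) == pytest.approx(10.0)

    def test_symmetric_solutions_near_zero(self):
        m = TwoGateModel(N_T=200, Er_mV=0.0)
        p = build_standard_protocol("activation", step_ms=20.0, tail_ms=1.0)
        s = simulate_sweepset(m, p, mode="mean")
        er = reversal_potential(gating.instantaneous_iv(s))
        assert abs(er) <= 0.5

    def test_ground_truth_recovery_within_bin(self):
        m = TwoGateModel(N_T=200, Er_mV=57.4)
        p = build_standard_protocol("activation", step_ms=20.0, tail_ms=1.0)
        s = simulate_sweepset(m, p, mode="mean")
        er = reversal_potential(gating.instantaneous_iv(s))
        assert abs(er - 57.4) <= 20.0

    def test_no_sign_change_raises(self):
        V = np.arange(0.0, 100.0, 20.0)
        with pytest.raises(EstimationError):
            reversal_potential(IVCurve(V, V + 50.0))

    def test_multiple_crossings_warn_and_pick_nearest(self):
        V = np.array([-40.0, -20.0, 0.0, 20.0, 40.0])
        I = np.array([-1.0, 1.0, -1.0, 1.0, 2.0])
        with pytest.warns(UserWarning):
            er = reversal_potential(IVCurve(V, I), nernst_guess_mV=12.0)
        assert er == pytest.approx(10.0)


class TestConductance:
    def test_fully_open_channel_constant_G(self):
        m = TwoGateModel(N_T=100, pore=LOCKED_PORE, common=LOCKED_COMMON)
        p = build_standard_protocol("activation", step_ms=30.0, tail_ms=1.0)
        s = simulate_sweepset(m, p, mode="mean")
        _, G = gating.conductance_curve(s, Er_mV=0.0, source="steady")
        assert np.ptp(G) / G.mean() < 0.01

    def test_steady_G_tracks_gate_product(self):
        m = TwoGateModel(N_T=500)
        p = build_standard_protocol(
            "activation", steps_mV=tuple(np.arange(-200.0, 201.0, 20.0)),
            step_ms=3000.0, tail_ms=1.0, sample_rate_kHz=2.0)
        s = simulate_sweepset(m, p, mode="mean")
        V, G = gating.conductance_curve(s, Er_mV=0.0, source="steady")
        expect = m.pore.p_inf(V) * m.common.p_inf(V)
        ratio = G / G[0]
        np.testing.assert_allclose(ratio, expect / expect[0], rtol=0.02)

    def test_tail_source_matches_steady_popen(self):
        # slow gates: tail current reports the open probability reached at
        # the end of the step
        m = TwoGateModel(N_T=500, pore=LOCKED_PORE,
                         common=GateParams(-80.0, -0.9, 400.0, 1e9))
        p = build_standard_protocol(
            "activation", steps_mV=tuple(np.arange(-200.0, 201.0, 20.0)),
            step_ms=3000.0, tail_ms=10.0, sample_rate_kHz=2.0)
        s = simulate_sweepset(m, p, mode="mean")
        V_t, G_t = gating.conductance_curve(s, Er_mV=0.0, source="tail")
        P_tail, _, _ = gating.apparent_popen(V_t, G_t)
        expect = m.common.p_inf(V_t)
        np.testing.assert_allclose(P_tail, expect, atol=0.03)

    def test_all_points_near_er_rejected(self):
        m = TwoGateModel(N_T=10)
        p = build_standard_protocol("activation", steps_mV=(-4.0, -2.0, 0.0),
                                    step_ms=20.0, tail_ms=1.0)
        s = simulate_sweepset(m, p, mode="mean")
        with pytest.raises(EstimationError):
            gating.conductance_curve(s, Er_mV=0.0, source="steady")


class TestApparentPopen:
    V = np.arange(-200.0, 81.0, 20.0)

    def test_saturating_curve_reaches_one(self):
        V = np.arange(-400.0, 81.0, 20.0)
        G = 4.6 * boltzmann(V, -0.84, -89.3)
        P_A, Gmax, _ = gating.apparent_popen(V, G)
        assert Gmax == pytest.approx(4.6, rel=1e-4)
        assert P_A.max() == pytest.approx(1.0, abs=1e-3)

    def test_truncated_curve_extrapolates_amplitude(self):
        # no saturation reached: raw-max normalization underestimates P_A
        V = np.arange(-120.0, 81.0, 20.0)
        true = boltzmann(V, -0.84, -89.3)
        G = 4.6 * true
        P_A, Gmax, _ = gating.apparent_popen(V, G)
        np.testing.assert_allclose(P_A, true, atol=1e-6)
        # raw-max normalization would claim full opening at the most
        # negative sampled V; the amplitude extrapolation does not
        assert Gmax == pytest.approx(4.6, rel=1e-6)
        assert P_A.max() < (G / G.max()).max() - 0.1

    def test_too_few_points(self):
        with pytest.raises(ArgumentError):
            gating.apparent_popen(self.V[:5], np.ones(5))


class TestBoltzmannFit:
    V = np.arange(-200.0, 81.0, 20.0)

    def test_noiseless_single_recovery(self):
        y = boltzmann_single(self.V, 1.0, -0.84, -89.3, 0.0)
        fit = fit_boltzmann(self.V, y, model="single")
        assert fit.V05_O_mV == pytest.approx(-89.3, abs=0.1)
        assert fit.z_O == pytest.approx(-0.84, abs=0.01)

    def test_midpoint_is_half(self):
        for z in (-1.17, -0.6, 1.0):
            assert boltzmann_single(-89.3, 1.0, z, -89.3, 0.0) == 0.5

    def test_auto_selects_double_for_reopening_curve(self):
        rng = np.random.default_rng(0)
        V = np.arange(-200.0, 201.0, 20.0)
        y = (0.8 * boltzmann(V, -0.79, -21.2)
             + 0.21 * boltzmann(V, 1.20, 130.8) + 0.2
             + rng.normal(0, 1e-3, V.size))
        fit = fit_boltzmann(V, y, model="auto")
        assert fit.model == "double"
        assert fit.z_O < 0 < fit.z_rO

    def test_auto_keeps_single_for_monotone_curve(self):
        rng = np.random.default_rng(1)
        y = boltzmann_single(self.V, 1.0, -0.84, -89.3, 0.0) \
            + rng.normal(0, 5e-3, self.V.size)
        assert fit_boltzmann(self.V, y, model="auto").model == "single"

    def test_sign_convention(self):
        # hyperpolarization-activated branch fits with negative z
        y = boltzmann_single(self.V, 1.0, -0.84, -89.3, 0.0)
        assert fit_boltzmann(self.V, y, model="single").z_O < 0

    def test_min_point_counts(self):
        with pytest.raises(ArgumentError):
            fit_boltzmann(self.V[:5], np.ones(5), model="single")
        with pytest.raises(ArgumentError):
            fit_boltzmann(self.V[:8], np.ones(8), model="double")


class TestDecomposition:
    def test_constitutively_open_pore_gives_unit_PP(self):
        # common gate nearly voltage-independent and slow, so the interpulse
        # ratio is a clean identity check
        m = TwoGateModel(N_T=1000, pore=LOCKED_PORE,
                         common=GateParams(0.0, -0.05, 450.0, 1e9))
        p = build_standard_protocol(
            "interpulse", steps_mV=tuple(np.arange(-200.0, 201.0, 20.0)),
            step_ms=2500.0)
        s = simulate_sweepset(m, p, mode="mean")
        er = gating.reversal_potential(gating.instantaneous_iv(s))
        V, G = gating.conductance_curve(s, er, source="steady")
        P_A, _, _ = gating.apparent_popen(V, G)
        P_A_full = np.interp(s.step_voltages(), V, P_A)
        curves = gating.decompose_gates(s, P_A_full, Er_mV=er)
        d = curves.defined
        np.testing.assert_allclose(curves.P_P[d], 1.0, atol=0.02)
        np.testing.assert_allclose(curves.P_C[d], P_A_full[d], atol=0.05)

    def test_ground_truth_recovery(self, decomposition_sat):
        fx = decomposition_sat
        curves, model = fx["curves"], fx["model"]
        assert model.pore.tau_ms(-200.0) <= 4.0
        d = curves.defined
        pp_true = model.pore.p_inf(curves.V_mV)
        pc_true = model.common.p_inf(curves.V_mV)
        assert np.nanmax(np.abs(curves.P_P[d] - pp_true[d])) <= 0.05
        assert np.nanmax(np.abs(curves.P_C[d] - pc_true[d])) <= 0.05

    def test_consistency_PA_equals_product(self, decomposition_sat):
        curves = decomposition_sat["curves"]
        d = curves.defined
        resid = curves.P_A[d] - curves.P_P[d] * curves.P_C[d]
        assert np.nanmax(np.abs(resid)) <= 0.02

    def test_wt_pattern_V05s(self, decomposition_wt):
        # fitted half-activation voltages match the generating gates
        # (pore near -57 mV, common near -111 mV)
        fx = decomposition_wt
        curves, model = fx["curves"], fx["model"]
        d = curves.defined
        fit_pp = fit_boltzmann(curves.V_mV[d], curves.P_P[d], model="single")
        fit_pc = fit_boltzmann(curves.V_mV[d], curves.P_C[d], model="single")
        assert fit_pp.V05_O_mV == pytest.approx(model.pore.V05_mV, abs=3.0)
        assert fit_pc.V05_O_mV == pytest.approx(model.common.V05_mV, abs=5.0)

    def test_missing_interpulse_rejected(self):
        m = TwoGateModel(N_T=10)
        p = build_standard_protocol("activation", step_ms=20.0, tail_ms=1.0)
        s = simulate_sweepset(m, p, mode="mean")
        with pytest.raises(ArgumentError):
            gating.decompose_gates(s, np.zeros(s.n_steps))

    def test_below_noise_floor_flagged_not_fabricated(self, decomposition_sat):
        curves = decomposition_sat["curves"]
        assert (~curves.defined).any()
        assert np.all(np.isnan(curves.P_P[~curves.defined]))


class TestQC:
    def _symmetric_set(self, Er):
        m = TwoGateModel(N_T=200, Er_mV=Er)
        p = build_standard_protocol("activation", step_ms=20.0, tail_ms=1.0)
        return simulate_sweepset(m, p, mode="mean")

    def test_symmetric_accept(self):
        res = qc_reversal(self._symmetric_set(0.5))
        assert res.accept and res.nernst_mV == 0.0

    def test_symmetric_reject(self):
        assert not qc_reversal(self._symmetric_set(25.0)).accept

    def test_gradient_fixture_tolerance_dependence(self):
        m = TwoGateModel(N_T=200, Er_mV=57.4)
        p = build_standard_protocol("activation", step_ms=20.0, tail_ms=1.0)
        meta = RecordingMeta(Cl_in_mM=140.0, Cl_out_mM=10.0)
        s = simulate_sweepset(m, p, mode="mean", meta=meta)
        assert qc_reversal(s, tol_mV=10.0).accept
        assert not qc_reversal(s, tol_mV=5.0).accept


class TestStochasticBoltzmannRecovery:
    def test_v05_and_z_within_tolerance(self, pore_only_stochastic):
        model, s = pore_only_stochastic
        er = gating.reversal_potential(gating.instantaneous_iv(s))
        V, G = gating.conductance_curve(s, er, source="steady")
        P_A, _, _ = gating.apparent_popen(V, G, T_K=s.meta.T_K)
        fit = fit_boltzmann(V, P_A, model="single", T_K=s.meta.T_K)
        assert fit.V05_O_mV == pytest.approx(model.pore.V05_mV, abs=3.0)
        assert fit.z_O == pytest.approx(model.pore.z, rel=0.10)
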