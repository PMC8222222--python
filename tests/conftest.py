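"""Shared fixtures: simulated recordings used across module and acceptance tests.

All heavy simulations are session-scoped so each is run once per session.
"""

import numpy as np
import pytest

from gatekit import gating
from gatekit.synth import (
    GateParams,
    TwoGateModel,
    build_standard_protocol,
    simulate_sweepset,
)

# pore gate fast enough that the 15 ms interpulse opens it fully
FAST_PORE = GateParams(V05_mV=-56.6, z=-1.17, tau0_ms=2.0, nu_mV=250.0)
# common gate slow everywhere: the decomposition premise (common gate frozen
# during the interpulse) holds; V05 chosen so the product curve saturates
# within the sampled voltage range
SLOW_COMMON_SAT = GateParams(V05_mV=-80.0, z=-0.9, tau0_ms=450.0, nu_mV=1e9)
# WT-like common-gate equilibrium, still slow (for the V05 pattern checks)
SLOW_COMMON_WT = GateParams(V05_mV=-110.9, z=-0.75, tau0_ms=450.0, nu_mV=1e9)
# protopore gate locked open over the experimental voltage range
LOCKED_PORE = GateParams(V05_mV=4000.0, z=-1.0, tau0_ms=4.0, nu_mV=250.0)
LOCKED_COMMON = GateParams(V05_mV=4000.0, z=-1.0, tau0_ms=45.0, nu_mV=250.0)


def decompose_mean_mode(common: GateParams):
    """Mean-mode interpulse recording plus its full gate decomposition."""
    model = TwoGateModel(N_T=1000, i_ref_pA=0.23, Er_mV=0.0, seed=0,
                         pore=FAST_PORE, common=common)
    protocol = build_standard_protocol(
        "interpulse", steps_mV=tuple(np.arange(-200.0, 201.0, 20.0)),
        step_ms=2500.0)
    s = simulate_sweepset(model, protocol, mode="mean")
    Er = gating.reversal_potential(gating.instantaneous_iv(s))
    V, G = gating.conductance_curve(s, Er, source="steady")
    P_A, Gmax, _ = gating.apparent_popen(V, G, T_K=s.meta.T_K)
    P_A_full = np.interp(s.step_voltages(), V, P_A)
    curves = gating.decompose_gates(s, P_A_full, Er_mV=Er)
    return dict(model=model, sweepset=s, Er=Er, Gmax=Gmax, curves=curves)


@pytest.fixture(scope="session")
def decomposition_sat():
    """Decomposition fixture with a saturating G-V curve (tight tolerances)."""
    return decompose_mean_mode(SLOW_COMMON_SAT)


@pytest.fixture(scope="session")
def decomposition_wt():
    """Decomposition fixture with WT-like common-gate equilibrium."""
    return decompose_mean_mode(SLOW_COMMON_WT)


@pytest.fixture(scope="session")
def stationary_ensemble():
    """Stochastic steady-state ensemble at -100 mV (both gates fluctuating)."""
    model = TwoGateModel(N_T=300, i_ref_pA=0.23, Er_mV=0.0, seed=1)
    protocol = build_standard_protocol("noise", holding_mV=-100.0,
                                       steps_mV=(-100.0,))
    s = simulate_sweepset(model, protocol, n_repeats=300, mode="stochastic")
    return model, s


@pytest.fixture(scope="session")
def deactivation_ensemble():
    """Common-gate deactivation repeats for the noise-analysis pipeline.

    Pore gate locked open so the variance-mean relation with P_P = 1 is
    exact at every time point.
    """
    model = TwoGateModel(
        N_T=800, i_ref_pA=0.23, Er_mV=0.0, seed=2, sigma_instr_pA=0.5,
        pore=LOCKED_PORE,
        common=GateParams(V05_mV=-110.9, z=-0.75, tau0_ms=20.0, nu_mV=250.0))
    protocol = build_standard_protocol("noise", holding_mV=-200.0,
                                       steps_mV=(100.0,), step_ms=400.0)
    s = simulate_sweepset(model, protocol, n_repeats=600, mode="stochastic")
    return model, s


@pytest.fixture(scope="session")
def pore_only_stochastic():
    """50-repeat stochastic activation set of a pore-only channel.

    The common gate is locked open, so the apparent open probability is a
    single Boltzmann with the pore-gate parameters.
    """
    model = TwoGateModel(N_T=500, i_ref_pA=0.23, Er_mV=0.0, seed=11,
                         sigma_instr_pA=1.0, pore=FAST_PORE,
                         common=LOCKED_COMMON)
    protocol = build_standard_protocol("activation", step_ms=150.0,
                                       tail_ms=30.0)
    s = simulate_sweepset(model, protocol, n_repeats=50, mode="stochastic")
    return model, s
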