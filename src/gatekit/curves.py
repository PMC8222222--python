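"""Boltzmann open-probability curves.

The single-term curve is

    B(V; z, V05) = 1 / (1 + exp(-z F/(R T) (V - V05)))

with ``z`` the apparent gating charge (negative for a gate that opens on
hyperpolarization) and ``V05`` the half-activation voltage.  Fitted curves
extend this with free amplitudes and an offset so that probabilities stay in
[0, 1] even when two terms are summed.
"""

from __future__ import annotations

import numpy as np
from scipy.special import expit

from gatekit.constants import T_K_DEFAULT, thermal_voltage_mV


def boltzmann(V_mV, z: float, V05_mV: float, T_K: float = T_K_DEFAULT):
    """Single-term Boltzmann open probability at membrane potential ``V_mV``.

    Evaluates 1/(1+exp(-zF/RT (V - V05))) with a numerically stable sigmoid;
    by construction the value at ``V == V05`` is exactly 0.5 for any z.
    """
    x = np.asarray(V_mV, dtype=float)
    return expit(z * (x - V05_mV) / thermal_voltage_mV(T_K))


def boltzmann_single(V_mV, A: float, z: float, V05_mV: float, P_min: float,
                     T_K: float = T_K_DEFAULT):
    """Amplitude/offset-extended single Boltzmann: A*B(V) + P_min."""
    return A * boltzmann(V_mV, z, V05_mV, T_K) + P_min


def boltzmann_double(V_mV, A_O: float, z_O: float, V05_O_mV: float,
                     A_rO: float, z_rO: float, V05_rO_mV: float,
                     P_min: float, T_K: float = T_K_DEFAULT):
    """Sum of an opening and a re-opening Boltzmann term plus an offset.

    Convention: the opening branch carries z_O < 0 (activates on
    hyperpolarization), the re-opening branch z_rO > 0 (activates on
    depolarization).
    """
    return (A_O * boltzmann(V_mV, z_O, V05_O_mV, T_K)
            + A_rO * boltzmann(V_mV, z_rO, V05_rO_mV, T_K)
            + P_min)
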