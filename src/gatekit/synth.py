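"""Stochastic two-gate channel simulator and electrochemical utilities.

The generative model is a homodimeric "double-barrelled" channel: each of
``N_T`` dimers carries two independent fast protopore gates and one slow
common gate acting on both pores.  Every gate is a two-state Markov process
whose open probability relaxes as

    p(t) = p_inf(V) + (p_0 - p_inf(V)) exp(-t / tau(V))

with p_inf the gate's Boltzmann equilibrium and tau(V) = tau0 * exp(V / nu)
clipped to [0.5, 500] ms.  A pore conducts ohmically,
i(V) = i_ref * (V - Er) / 100 (pA), only while both its protopore gate and
the dimer's common gate are open.

At steady state the ensemble variance of the total current obeys the
double-barrel identity

    sigma^2 = (1 + P_P) * i * I_bar - I_bar^2 / N_T
            = N_T * i^2 * 2 p pc (1 + p - 2 p pc)

which is the closed form the noise-analysis module fits against.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import comb

import numpy as np

from gatekit.constants import T_K_DEFAULT, R_J_PER_MOL_K, F_C_PER_MOL
from gatekit.curves import boltzmann
from gatekit.errors import ArgumentError
from gatekit.traces import Interpulse, RecordingMeta, SweepSet, VoltageProtocol

TAU_CLIP_MS = (0.5, 500.0)


@dataclass(frozen=True)
class GateParams:
    """Boltzmann equilibrium plus exponential voltage dependence of tau."""

    V05_mV: float
    z: float
    tau0_ms: float
    nu_mV: float

    def __post_init__(self):
        if self.z == 0:
            raise ArgumentError("gate charge z must be nonzero")
        if self.tau0_ms <= 0 or self.nu_mV == 0:
            raise ArgumentError("tau0_ms must be > 0 and nu_mV nonzero")

    def p_inf(self, V_mV, T_K: float = T_K_DEFAULT):
        return boltzmann(V_mV, self.z, self.V05_mV, T_K)

    def tau_ms(self, V_mV):
        return float(np.clip(self.tau0_ms * np.exp(np.asarray(V_mV, float) / self.nu_mV),
                             *TAU_CLIP_MS))


# Defaults land tau_f in 1.5-10 ms and tau_s in 20-100 ms over -200..+200 mV
# and give WT-like half-activation voltages for the two gates.
DEFAULT_PORE = GateParams(V05_mV=-56.6, z=-1.17, tau0_ms=4.0, nu_mV=250.0)
DEFAULT_COMMON = GateParams(V05_mV=-110.9, z=-0.75, tau0_ms=45.0, nu_mV=250.0)


@dataclass(frozen=True)
class TwoGateModel:
    """Generative parameters of the dimeric double-barrel channel."""

    N_T: int = 500
    i_ref_pA: float = 0.23
    Er_mV: float = 0.0
    pore: GateParams = field(default_factory=lambda: DEFAULT_PORE)
    common: GateParams = field(default_factory=lambda: DEFAULT_COMMON)
    sigma_instr_pA: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.N_T < 0:
            raise ArgumentError("N_T must be >= 0")
        if self.sigma_instr_pA < 0:
            raise ArgumentError("sigma_instr_pA must be >= 0")

    def i_pore_pA(self, V_mV):
        """Single-protopore ohmic current at potential V (pA)."""
        return self.i_ref_pA * (np.asarray(V_mV, float) - self.Er_mV) / 100.0

    def mean_steady_current(self, V_mV, T_K: float = T_K_DEFAULT):
        """Closed-form steady-state mean current N_T*2*i(V)*p_p*p_c."""
        return (self.N_T * 2.0 * self.i_pore_pA(V_mV)
                * self.pore.p_inf(V_mV, T_K) * self.common.p_inf(V_mV, T_K))

    def steady_state_variance(self, V_mV, T_K: float = T_K_DEFAULT):
        """Analytic steady-state current variance of the dimer model.

        N_T * i^2 * 2 p pc (1 + p - 2 p pc); equals
        (1+p)*i*I_bar - I_bar^2/N_T with I_bar the steady mean.  Instrument
        noise variance is *not* included.
        """
        i = self.i_pore_pA(V_mV)
        p = self.pore.p_inf(V_mV, T_K)
        pc = self.common.p_inf(V_mV, T_K)
        return self.N_T * i ** 2 * 2.0 * p * pc * (1.0 + p - 2.0 * p * pc)


# ---------------------------------------------------------------------------
# protocols

def build_standard_protocol(variant: str, **overrides) -> VoltageProtocol:
    """Standard protocols: "activation", "interpulse" or "noise".

    activation  : steps -160..+200 mV in 20 mV increments, tail at +80 mV.
    interpulse  : same steps with a 15 ms / -200 mV pulse intercalated after
                  the steady-state portion of each test step.
    noise       : single 200 ms step at +100 mV from a -200 mV holding,
                  meant to be run with repeats.

    Keyword overrides are passed through to :class:`VoltageProtocol`.
    """
    if variant == "activation":
        base = dict(holding_mV=0.0,
                    steps_mV=tuple(np.arange(-160.0, 200.0 + 1, 20.0)),
                    step_ms=400.0, tail_mV=80.0, tail_ms=50.0,
                    sample_rate_kHz=10.0)
    elif variant == "interpulse":
        base = dict(holding_mV=0.0,
                    steps_mV=tuple(np.arange(-160.0, 200.0 + 1, 20.0)),
                    step_ms=400.0, tail_mV=80.0, tail_ms=50.0,
                    sample_rate_kHz=10.0,
                    interpulse=Interpulse(voltage_mV=-200.0, duration_ms=15.0),
                    post_interpulse_ms=25.0)
    elif variant == "noise":
        base = dict(holding_mV=-200.0, steps_mV=(100.0,), step_ms=200.0,
                    tail_mV=-200.0, tail_ms=0.0, sample_rate_kHz=10.0)
    else:
        raise ArgumentError(f"unknown protocol variant {variant!r}")
    base.update(overrides)
    return VoltageProtocol(**base)


# ---------------------------------------------------------------------------
# simulation

def _relax_segmentwise(gate: GateParams, protocol: VoltageProtocol,
                       step_mV: float, T_K: float) -> np.ndarray:
    """Deterministic p(t) over the whole sweep, exact within each segment."""
    K = protocol.n_samples
    p = np.empty(K)
    p_cur = float(gate.p_inf(protocol.holding_mV, T_K))
    dt = protocol.dt_ms
    for _, v, start, n in protocol.segment_table(step_mV):
        p_inf = float(gate.p_inf(v, T_K))
        tau = gate.tau_ms(v)
        decay = np.exp(-np.arange(n) * dt / tau)
        p[start:start + n] = p_inf + (p_cur - p_inf) * decay
        p_cur = p_inf + (p_cur - p_inf) * np.exp(-n * dt / tau)
    return p


def _gate_flip_probs(p_inf: float, tau_ms: float, dt_ms: float):
    """Exact discrete-time transition probabilities over one sample interval."""
    E = np.exp(-dt_ms / tau_ms)
    p_co = p_inf * (1.0 - E)            # closed -> open
    p_oo = p_inf + (1.0 - p_inf) * E    # open -> open
    return p_co, p_oo


def _dimer_transition_matrix(pore: GateParams, common: GateParams,
                             V_mV: float, dt_ms: float, T_K: float) -> np.ndarray:
    """6x6 one-sample transition matrix over dimer states (c, k).

    State index s = 3*c + k with c the common gate (0 closed / 1 open) and
    k the number of open protopore gates (0..2).  Gates flip independently.
    """
    q_co, q_oo = _gate_flip_probs(float(pore.p_inf(V_mV, T_K)),
                                  pore.tau_ms(V_mV), dt_ms)
    r_co, r_oo = _gate_flip_probs(float(common.p_inf(V_mV, T_K)),
                                  common.tau_ms(V_mV), dt_ms)
    C = np.array([[1.0 - r_co, r_co], [1.0 - r_oo, r_oo]])
    P2 = np.zeros((3, 3))
    for k in range(3):
        for a in range(k + 1):          # of k open pores, a stay open
            pa = comb(k, a) * q_oo ** a * (1 - q_oo) ** (k - a)
            for b in range(2 - k + 1):  # of 2-k closed pores, b open
                pb = comb(2 - k, b) * q_co ** b * (1 - q_co) ** (2 - k - b)
                P2[k, a + b] += pa * pb
    T = np.zeros((6, 6))
    for c in range(2):
        for k in range(3):
            T[3 * c + k] = np.concatenate([C[c, 0] * P2[k], C[c, 1] * P2[k]])
    return T


def _equilibrium_distribution(m: TwoGateModel, V_mV: float, T_K: float) -> np.ndarray:
    pp = float(m.pore.p_inf(V_mV, T_K))
    pc = float(m.common.p_inf(V_mV, T_K))
    pore_dist = np.array([(1 - pp) ** 2, 2 * pp * (1 - pp), pp ** 2])
    return np.concatenate([(1 - pc) * pore_dist, pc * pore_dist])


_OPEN_PORES = np.array([0.0, 0.0, 0.0, 0.0, 1.0, 2.0])  # per dimer state


def _stochastic_sweeps(m: TwoGateModel, protocol: VoltageProtocol,
                       step_mV: float, n_repeats: int, rng: np.random.Generator,
                       T_K: float) -> np.ndarray:
    """Exact Markov sampling of all repeats at one test potential, (R, K)."""
    table = protocol.segment_table(step_mV)
    K = protocol.n_samples
    dt = protocol.dt_ms
    seg_of = np.empty(K, dtype=int)
    for si, (_, _, start, n) in enumerate(table):
        seg_of[start:start + n] = si
    T_mats = [_dimer_transition_matrix(m.pore, m.common, v, dt, T_K)
              for _, v, _, _ in table]
    i_seg = np.array([m.i_pore_pA(v) for _, v, _, _ in table])

    counts = rng.multinomial(m.N_T, _equilibrium_distribution(
        m, protocol.holding_mV, T_K), size=n_repeats)
    out = np.empty((n_repeats, K))
    for idx in range(K):
        seg = seg_of[idx]
        out[:, idx] = i_seg[seg] * (counts @ _OPEN_PORES)
        if idx < K - 1:
            T = T_mats[seg]
            new = np.zeros_like(counts)
            for s in range(6):
                n_s = counts[:, s]
                if n_s.any():
                    new += rng.multinomial(n_s, T[s])
            counts = new
    if m.sigma_instr_pA > 0:
        out += rng.normal(0.0, m.sigma_instr_pA, size=out.shape)
    return out


def simulate_sweepset(m: TwoGateModel, p: VoltageProtocol,
                      n_repeats: int = 1, mode: str = "stochastic",
                      meta: RecordingMeta | None = None) -> SweepSet:
    """Simulate whole-cell currents under a step protocol.

    ``mode="mean"`` returns the noiseless expectation
    N_T * 2 * i(V) * p_pore(t) * p_common(t); ``mode="stochastic"`` performs
    exact per-channel Markov sampling (plus Gaussian instrument noise) and,
    for ``n_repeats >= 2``, stores the repeats with the ensemble mean in
    ``sweeps``.  Identical (model, protocol, seed) give identical traces.
    """
    if n_repeats < 0:
        raise ArgumentError("n_repeats must be >= 0")
    if mode not in ("stochastic", "mean"):
        raise ArgumentError(f"unknown mode {mode!r}")
    if meta is None:
        meta = RecordingMeta()
    T_K = meta.T_K
    t_ms = p.time_ms()
    steps = p.steps_mV

    if mode == "mean":
        sweeps = np.empty((len(steps), p.n_samples))
        for r, v_step in enumerate(steps):
            pp = _relax_segmentwise(m.pore, p, v_step, T_K)
            pc = _relax_segmentwise(m.common, p, v_step, T_K)
            i_t = m.i_pore_pA(p.sample_voltages(v_step))
            sweeps[r] = m.N_T * 2.0 * i_t * pp * pc
        return SweepSet(t_ms=t_ms, sweeps=sweeps, protocol=p, meta=meta)

    rng = np.random.default_rng(m.seed)
    R = max(n_repeats, 1)
    reps = np.empty((R, len(steps), p.n_samples))
    for r, v_step in enumerate(steps):
        reps[:, r, :] = _stochastic_sweeps(m, p, v_step, R, rng, T_K)
    if R >= 2:
        return SweepSet(t_ms=t_ms, sweeps=reps.mean(axis=0), protocol=p,
                        meta=meta, repeats=reps)
    return SweepSet(t_ms=t_ms, sweeps=reps[0], protocol=p, meta=meta)


# ---------------------------------------------------------------------------
# electrochemistry

def nernst_potential(Cl_in_mM: float, Cl_out_mM: float,
                     T_K: float = T_K_DEFAULT) -> float:
    """Chloride Nernst potential, anion convention, in mV.

    Returns (RT/F) ln(Cl_in/Cl_out): equal concentrations give 0 and
    Cl_in > Cl_out gives a positive reversal potential.
    """
    if Cl_in_mM <= 0 or Cl_out_mM <= 0:
        raise ArgumentError("concentrations must be positive")
    return 1000.0 * R_J_PER_MOL_K * T_K / F_C_PER_MOL * np.log(Cl_in_mM / Cl_out_mM)


def acetate_charged_fraction(pH: float, pKa: float = 4.75) -> float:
    """Deprotonated (anionic) fraction of a weak acid, 1/(1+10^(pKa-pH)).

    At pH 4.2 with pKa 4.75 this evaluates to 0.22 (2 d.p.).  Note this is
    the fraction of the *minority charged* species at that pH; published
    work sometimes labels the same number an "uncharged fraction", which is
    inconsistent with the Henderson–Hasselbalch relation.
    """
    return 1.0 / (1.0 + 10.0 ** (pKa - pH))
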