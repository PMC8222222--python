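"""Reversal potential, conductance, open probability and gate decomposition.

Workflow for one recording:

1. ``instantaneous_iv`` / ``reversal_potential`` — Er from the zero crossing
   of the instantaneous I-V relation.
2. ``conductance_curve`` — G = I/(V - Er) from steady-state or tail currents.
3. ``apparent_popen`` — P_A = G/G_max with G_max from the amplitude of a
   single-Boltzmann fit (not the raw maximum).
4. ``decompose_gates`` — the interpulse protocol yields P_P = I_ss/I_post
   and P_C = P_A/P_P per test potential.
5. ``fit_boltzmann`` — single or double Boltzmann voltage dependence with
   free amplitudes and offset; "auto" selects the model by small-sample AIC.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.optimize import curve_fit

from gatekit.constants import T_K_DEFAULT
from gatekit.curves import boltzmann_double, boltzmann_single
from gatekit.errors import ArgumentError, EstimationError, FitError
from gatekit.synth import nernst_potential
from gatekit.traces import SweepSet

#: conductance points within this distance of Er are excluded (division blow-up)
NEAR_ER_EXCLUSION_MV = 5.0
#: fraction of the pre-interpulse step treated as the steady-state window
STEADY_WINDOW_FRACTION = 0.10
#: blanking after the interpulse ends before I_post is sampled (ms)
POST_INTERPULSE_BLANK_MS = 0.3
#: tail current = mean over this window after the tail step begins (ms)
TAIL_WINDOW_MS = (1.0, 3.0)
#: probabilities are clipped to [0, 1 + this] and flagged beyond it
P_CLIP_EPS = 0.05


@dataclass
class IVCurve:
    """Current-voltage pairs with the interpolated zero crossing."""

    V_mV: np.ndarray
    I_pA: np.ndarray
    label: str = "instantaneous"

    def __post_init__(self):
        self.V_mV = np.asarray(self.V_mV, dtype=float)
        self.I_pA = np.asarray(self.I_pA, dtype=float)
        if self.V_mV.ndim != 1 or self.V_mV.shape != self.I_pA.shape:
            raise ArgumentError("V and I must be matching 1-D arrays")
        if np.any(np.diff(self.V_mV) <= 0):
            raise ArgumentError("V_mV must be strictly increasing")


def instantaneous_iv(s: SweepSet, t_sample_ms: float = 0.0) -> IVCurve:
    """I-V relation sampled ``t_sample_ms`` after the step onset."""
    idx = int(round(t_sample_ms * s.protocol.sample_rate_kHz))
    idx = min(idx, s.sweeps.shape[1] - 1)
    return IVCurve(V_mV=s.step_voltages(), I_pA=s.sweeps[:, idx])


def reversal_potential(iv: IVCurve, nernst_guess_mV: Optional[float] = None) -> float:
    """Er from linear interpolation between the bracketing (V, I) pair.

    With several sign changes the crossing nearest ``nernst_guess_mV`` is
    returned with a warning; without a sign change an
    :class:`~gatekit.errors.EstimationError` is raised (no extrapolation).
    """
    V, I = iv.V_mV, iv.I_pA
    crossings = []
    for k in range(len(V) - 1):
        if I[k] == 0.0:
            crossings.append(V[k])
        elif I[k] * I[k + 1] < 0:
            frac = -I[k] / (I[k + 1] - I[k])
            crossings.append(V[k] + frac * (V[k + 1] - V[k]))
    if I[-1] == 0.0:
        crossings.append(V[-1])
    if not crossings:
        raise EstimationError("current does not change sign across the "
                              "voltage range; cannot interpolate Er")
    if len(crossings) > 1:
        warnings.warn(f"{len(crossings)} zero crossings found; returning the "
                      "one nearest the Nernst prediction", stacklevel=2)
        ref = 0.0 if nernst_guess_mV is None else nernst_guess_mV
        return float(min(crossings, key=lambda v: abs(v - ref)))
    return float(crossings[0])


def _steady_window(s: SweepSet, row: int) -> float:
    _, _, start, n = s.protocol.segment_table(s.protocol.steps_mV[row])[0]
    n_win = max(1, int(round(n * STEADY_WINDOW_FRACTION)))
    return float(s.sweeps[row, start + n - n_win:start + n].mean())


def conductance_curve(s: SweepSet, Er_mV: float, source: str = "steady"):
    """(V, G) pairs with G in nS (pA/mV).

    ``source="steady"`` uses the mean current over the last 10% of the test
    step, G = I/(V - Er); ``source="tail"`` uses the tail-current magnitude
    at the fixed tail potential (G proportional to I_tail).  Points within
    5 mV of Er are excluded.
    """
    if source not in ("steady", "tail"):
        raise ArgumentError(f"unknown conductance source {source!r}")
    V = s.step_voltages()
    if source == "steady":
        I = np.array([_steady_window(s, r) for r in range(s.n_steps)])
        keep = np.abs(V - Er_mV) > NEAR_ER_EXCLUSION_MV
        if not keep.any():
            raise EstimationError("all points within the near-Er exclusion zone")
        G = I[keep] / (V[keep] - Er_mV)
        return V[keep], G
    # tail source: fixed driving force, G tracks the tail current magnitude
    table = s.protocol.segment_table(V[0])
    names = [seg[0] for seg in table]
    if "tail" not in names:
        raise ArgumentError("protocol has no tail step")
    _, v_tail, start, n = table[names.index("tail")]
    if abs(v_tail - Er_mV) <= NEAR_ER_EXCLUSION_MV:
        raise EstimationError("tail potential lies in the near-Er exclusion zone")
    rate = s.protocol.sample_rate_kHz
    a = start + int(round(TAIL_WINDOW_MS[0] * rate))
    b = start + int(round(TAIL_WINDOW_MS[1] * rate)) + 1
    b = min(b, start + n)
    I_tail = s.sweeps[:, a:b].mean(axis=1)
    return V, I_tail / (v_tail - Er_mV)


@dataclass(frozen=True)
class BoltzmannFit:
    """Fitted Boltzmann voltage dependence (single or double term)."""

    model: str
    A_O: float
    z_O: float
    V05_O_mV: float
    P_min: float
    A_rO: Optional[float] = None
    z_rO: Optional[float] = None
    V05_rO_mV: Optional[float] = None
    se: dict = field(default_factory=dict)
    rss: float = np.nan
    aicc: float = np.nan
    T_K: float = T_K_DEFAULT

    def predict(self, V_mV):
        if self.model == "single":
            return boltzmann_single(V_mV, self.A_O, self.z_O, self.V05_O_mV,
                                    self.P_min, self.T_K)
        return boltzmann_double(V_mV, self.A_O, self.z_O, self.V05_O_mV,
                                self.A_rO, self.z_rO, self.V05_rO_mV,
                                self.P_min, self.T_K)


def _aicc(rss: float, n: int, k: int) -> float:
    rss = max(rss, 1e-300)
    aic = n * np.log(rss / n) + 2 * k
    if n - k - 1 > 0:
        aic += 2 * k * (k + 1) / (n - k - 1)
    return aic


def _fit_single_boltzmann(V, y, sigma, T_K):
    def f(v, A, z, V05, Pmin):
        return boltzmann_single(v, A, z, V05, Pmin, T_K)

    span = V.max() - V.min()
    bounds = ([0.0, -10.0, V.min() - 2 * span, -0.5],
              [2.0, 10.0, V.max() + 2 * span, 1.2])
    amp0 = max(float(y.max() - y.min()), 1e-3)
    best = None
    for z0, q in itertools.product((-1.0, -0.3, 1.0), (0.25, 0.5, 0.75)):
        p0 = [amp0, z0, float(np.quantile(V, q)), float(max(y.min(), -0.4))]
        try:
            popt, pcov = curve_fit(f, V, y, p0=p0, sigma=sigma, bounds=bounds,
                                   maxfev=20000)
        except Exception:
            continue
        rss = float(np.sum((f(V, *popt) - y) ** 2))
        if best is None or rss < best[0]:
            best = (rss, popt, pcov)
    if best is None:
        raise FitError("single-Boltzmann fit failed from every start "
                       f"(grid: z in (-1,-0.3,1), V05 quantiles 25/50/75, "
                       f"n={len(V)})")
    rss, popt, pcov = best
    ses = np.sqrt(np.clip(np.diag(pcov), 0, np.inf))
    return BoltzmannFit(
        model="single", A_O=popt[0], z_O=popt[1], V05_O_mV=popt[2],
        P_min=popt[3],
        se=dict(zip(("A_O", "z_O", "V05_O_mV", "P_min"), ses)),
        rss=rss, aicc=_aicc(rss, len(V), 4), T_K=T_K)


def _fit_double_boltzmann(V, y, sigma, T_K):
    def f(v, A_O, z_O, V05_O, A_rO, z_rO, V05_rO, Pmin):
        return boltzmann_double(v, A_O, z_O, V05_O, A_rO, z_rO, V05_rO,
                                Pmin, T_K)

    span = V.max() - V.min()
    # opening branch z < 0, re-opening branch z > 0 by convention
    bounds = ([0.0, -10.0, V.min() - 2 * span, 0.0, 1e-3, V.min() - 2 * span, -0.5],
              [2.0, -1e-3, V.max() + 2 * span, 2.0, 10.0, V.max() + 2 * span, 1.2])
    amp0 = max(float(y.max() - y.min()), 1e-3)
    best = None
    for zo0, zr0 in itertools.product((-0.5, -1.5), (0.5, 1.5)):
        p0 = [amp0, zo0, float(np.quantile(V, 0.3)),
              0.5 * amp0, zr0, float(np.quantile(V, 0.9)),
              float(max(y.min(), -0.4))]
        try:
            popt, pcov = curve_fit(f, V, y, p0=p0, sigma=sigma, bounds=bounds,
                                   maxfev=40000)
        except Exception:
            continue
        rss = float(np.sum((f(V, *popt) - y) ** 2))
        if best is None or rss < best[0]:
            best = (rss, popt, pcov)
    if best is None:
        raise FitError("double-Boltzmann fit failed from every start")
    rss, popt, pcov = best
    names = ("A_O", "z_O", "V05_O_mV", "A_rO", "z_rO", "V05_rO_mV", "P_min")
    ses = np.sqrt(np.clip(np.diag(pcov), 0, np.inf))
    return BoltzmannFit(
        model="double", A_O=popt[0], z_O=popt[1], V05_O_mV=popt[2],
        A_rO=popt[3], z_rO=popt[4], V05_rO_mV=popt[5], P_min=popt[6],
        se=dict(zip(names, ses)), rss=rss, aicc=_aicc(rss, len(V), 7),
        T_K=T_K)


#: "auto" keeps the double model only when it beats single by this much AICc
AICC_DOUBLE_MARGIN = 4.0


def fit_boltzmann(V_mV, values, model: str = "auto",
                  se: Optional[np.ndarray] = None,
                  T_K: float = T_K_DEFAULT) -> BoltzmannFit:
    """Fit a voltage-dependence curve with a Boltzmann model.

    The fitted form generalizes the textbook expression with free amplitudes
    and an offset, A_O*B(V; z_O, V05_O) [+ A_rO*B(V; z_rO, V05_rO)] + P_min,
    so that the curve can stay within [0, 1].  ``model`` is "single",
    "double" or "auto" (small-sample AIC selection, double accepted only
    when it wins by more than 4).  ``se`` supplies per-point weights.
    """
    V = np.asarray(V_mV, dtype=float)
    y = np.asarray(values, dtype=float)
    finite = np.isfinite(V) & np.isfinite(y)
    V, y = V[finite], y[finite]
    sigma = None
    if se is not None:
        sigma = np.asarray(se, dtype=float)[finite]
        sigma = np.where(sigma > 0, sigma, np.nanmax(sigma) or 1.0)
    if model not in ("single", "double", "auto"):
        raise ArgumentError(f"unknown Boltzmann model {model!r}")
    if model in ("single", "auto") and len(V) < 6:
        raise ArgumentError(f"need >= 6 points, got {len(V)}")
    if model == "double" and len(V) < 9:
        raise ArgumentError(f"need >= 9 points for a double fit, got {len(V)}")

    if model == "single":
        return _fit_single_boltzmann(V, y, sigma, T_K)
    if model == "double":
        return _fit_double_boltzmann(V, y, sigma, T_K)
    single = _fit_single_boltzmann(V, y, sigma, T_K)
    if len(V) < 9:
        return single
    try:
        double = _fit_double_boltzmann(V, y, sigma, T_K)
    except FitError:
        return single
    if double.aicc < single.aicc - AICC_DOUBLE_MARGIN:
        return double
    return single


def apparent_popen(V_mV, G_nS, T_K: float = T_K_DEFAULT):
    """P_A = G/G_max with G_max from a single-Boltzmann amplitude.

    G_max is the saturation level A + P_min of the fitted curve rather than
    the raw maximum, so truncated G-V curves extrapolate correctly.  Falls
    back to max-G normalization with a warning if the fit fails.
    """
    V = np.asarray(V_mV, dtype=float)
    G = np.asarray(G_nS, dtype=float)
    if len(V) < 6:
        raise ArgumentError(f"need >= 6 voltage points, got {len(V)}")
    scale = float(np.max(np.abs(G)))
    if scale == 0:
        raise EstimationError("zero maximum conductance")
    try:
        # fit on the normalized curve: amplitude bounds assume probability scale
        fit = _fit_single_boltzmann(V, G / scale, None, T_K)
        Gmax = (fit.A_O + fit.P_min) * scale
    except FitError:
        warnings.warn("single-Boltzmann G-V fit failed; normalizing by the "
                      "raw conductance maximum", stacklevel=2)
        fit, Gmax = None, float(np.max(np.abs(G)))
    if Gmax == 0:
        raise EstimationError("zero maximum conductance")
    return G / Gmax, Gmax, fit


@dataclass
class GatingCurves:
    """Per-voltage apparent, pore and common open probabilities."""

    V_mV: np.ndarray
    P_A: np.ndarray
    P_P: np.ndarray
    P_C: np.ndarray
    Gmax_nS: float = np.nan
    source: str = "steady"
    defined: np.ndarray = None  # mask where P_P (hence P_C) is reported
    out_of_range: np.ndarray = None

    def __post_init__(self):
        if self.defined is None:
            self.defined = np.isfinite(self.P_P)
        if self.out_of_range is None:
            self.out_of_range = np.zeros_like(self.P_A, dtype=bool)


def decompose_gates(s: SweepSet, P_A, Er_mV: Optional[float] = None,
                    noise_floor_pA: Optional[float] = None,
                    source: str = "steady") -> GatingCurves:
    """Interpulse decomposition of P_A into pore and common components.

    P_P(V) = I_ss(V) / I_post(V), with I_ss the mean over the steady-state
    window before the interpulse and I_post the first sample at least 0.3 ms
    after the interpulse returns to the test potential (the brief strong
    hyperpolarization opens the fast gate fully, so I_post reports the
    common gate alone).  P_C = P_A / P_P.  Where |I_post| falls below the
    noise floor, P_P and P_C are flagged undefined rather than fabricated.

    Known bias: P_P overestimates the true pore open probability by at most
    a factor 1/(1 - exp(-15/tau_f(interpulse V))); negligible for
    tau_f <= 4 ms.
    """
    if s.protocol.interpulse is None:
        raise ArgumentError("protocol has no interpulse step")
    P_A = np.asarray(P_A, dtype=float)
    V = s.step_voltages()
    if P_A.shape != V.shape:
        raise ArgumentError("P_A must be sampled at the sweep-set voltages")

    rate = s.protocol.sample_rate_kHz
    I_ss = np.empty(s.n_steps)
    I_post = np.empty(s.n_steps)
    for r, v in enumerate(V):
        table = s.protocol.segment_table(v)
        names = [seg[0] for seg in table]
        _, _, st, n = table[names.index("step")]
        n_win = max(1, int(round(n * STEADY_WINDOW_FRACTION)))
        I_ss[r] = s.sweeps[r, st + n - n_win:st + n].mean()
        _, _, st_post, n_post = table[names.index("post")]
        k = st_post + int(np.ceil(POST_INTERPULSE_BLANK_MS * rate))
        k = min(k, st_post + n_post - 1)
        I_post[r] = s.sweeps[r, k]

    if noise_floor_pA is None:
        noise_floor_pA = 1e-3 * float(np.max(np.abs(s.sweeps)))
    defined = np.abs(I_post) > noise_floor_pA
    P_P = np.full(s.n_steps, np.nan)
    P_P[defined] = I_ss[defined] / I_post[defined]
    P_C = np.full(s.n_steps, np.nan)
    ok = defined & (np.abs(P_P) > 0)
    P_C[ok] = P_A[ok] / P_P[ok]

    out = np.zeros(s.n_steps, dtype=bool)
    for arr in (P_P, P_C):
        with np.errstate(invalid="ignore"):
            out |= (arr < -P_CLIP_EPS) | (arr > 1.0 + P_CLIP_EPS)
        np.clip(arr, 0.0, 1.0 + P_CLIP_EPS, out=arr,
                where=np.isfinite(arr))
    return GatingCurves(V_mV=V, P_A=P_A, P_P=P_P, P_C=P_C, source=source,
                        defined=defined, out_of_range=out)


@dataclass(frozen=True)
class QCResult:
    accept: bool
    Er_mV: float
    nernst_mV: float
    tol_mV: float


def qc_reversal(s: SweepSet, tol_mV: float = 10.0) -> QCResult:
    """Accept the recording iff measured Er is within ``tol_mV`` of Nernst."""
    nernst = nernst_potential(s.meta.Cl_in_mM, s.meta.Cl_out_mM, s.meta.T_K)
    Er = reversal_potential(instantaneous_iv(s), nernst_guess_mV=nernst)
    return QCResult(accept=bool(abs(Er - nernst) <= tol_mV), Er_mV=Er,
                    nernst_mV=nernst, tol_mV=tol_mV)
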