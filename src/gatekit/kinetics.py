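"""Biexponential relaxation fitting.

Current relaxations are fitted with

    I(t) = A1 (1 - exp(-t/tau_f)) + A2 (1 - exp(-t/tau_s)) + A0

over a user window (t measured from the window start).  Fractional weights
are W_P = A1/(A0+A1+A2), W_C = A2/(A0+A1+A2), W_const = A0/(A0+A1+A2); their
sum is 1 by construction.  Time constants are labelled so tau_f <= tau_s.

Implementation: variable projection — for fixed (tau_f, tau_s) the
amplitudes solve a linear least-squares problem, so the nonlinear search
runs over the two log-time-constants only, with a multistart grid spanning
the physiological range (tau_f 1-10 ms, tau_s 20-100 ms).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from gatekit.errors import ArgumentError, FitError
from gatekit.traces import SweepSet

MULTISTART_TAUF_MS = (1.0, 3.0, 10.0)
MULTISTART_TAUS_MS = (20.0, 50.0, 100.0)
#: if the two fitted time constants agree within this relative tolerance the
#: trace is refitted as a single exponential.
TAU_DEGENERACY_RTOL = 0.05


@dataclass(frozen=True)
class KineticsFit:
    A0: float
    A1: float
    A2: float
    tau_f_ms: float
    tau_s_ms: float
    rss: float
    converged: bool

    @property
    def _total(self) -> float:
        return self.A0 + self.A1 + self.A2

    @property
    def W_P(self) -> float:
        return self.A1 / self._total if self._total != 0 else float("nan")

    @property
    def W_C(self) -> float:
        return self.A2 / self._total if self._total != 0 else float("nan")

    @property
    def W_const(self) -> float:
        return self.A0 / self._total if self._total != 0 else float("nan")

    def predict(self, t_ms: np.ndarray) -> np.ndarray:
        t = np.asarray(t_ms, dtype=float)
        return (self.A1 * (1.0 - np.exp(-t / self.tau_f_ms))
                + self.A2 * (1.0 - np.exp(-t / self.tau_s_ms))
                + self.A0)


def _design(t: np.ndarray, taus) -> np.ndarray:
    cols = [1.0 - np.exp(-t / tau) for tau in taus] + [np.ones_like(t)]
    return np.column_stack(cols)


def _projected_residuals(log_taus: np.ndarray, t: np.ndarray, y: np.ndarray):
    X = _design(t, np.exp(log_taus))
    amps, *_ = np.linalg.lstsq(X, y, rcond=None)
    return X @ amps - y, amps


def fit_biexponential(t_ms: np.ndarray, i_pA: np.ndarray,
                      window: Optional[Tuple[float, float]] = None) -> KineticsFit:
    """Least-squares biexponential fit of one trace over ``window``.

    ``window`` is (t_start_ms, t_end_ms) in the trace's own time base; at
    least 50 samples must fall inside it.  A multistart over log-spaced time
    constants is run and the lowest-RSS solution returned, with tau labels
    ordered so tau_f <= tau_s.  Near-degenerate time constants (within 5%)
    trigger a single-exponential refit with A2 = 0.
    """
    t_ms = np.asarray(t_ms, dtype=float)
    i_pA = np.asarray(i_pA, dtype=float)
    if t_ms.shape != i_pA.shape or t_ms.ndim != 1:
        raise ArgumentError("t_ms and i_pA must be matching 1-D arrays")
    if window is None:
        window = (t_ms[0], t_ms[-1])
    lo, hi = window
    if lo < t_ms[0] - 1e-9 or hi > t_ms[-1] + 1e-9 or hi <= lo:
        raise ArgumentError(f"window {window} outside trace span "
                            f"({t_ms[0]}, {t_ms[-1]})")
    mask = (t_ms >= lo) & (t_ms <= hi)
    if mask.sum() < 50:
        raise ArgumentError(f"only {int(mask.sum())} samples in window; need >= 50")
    t = t_ms[mask] - t_ms[mask][0]
    y = i_pA[mask]

    best = None
    for tf0, ts0 in itertools.product(MULTISTART_TAUF_MS, MULTISTART_TAUS_MS):
        try:
            sol = least_squares(
                lambda lt: _projected_residuals(lt, t, y)[0],
                x0=np.log([tf0, ts0]),
                bounds=(np.log(1e-3), np.log(1e5)),
                xtol=1e-12, ftol=1e-12, gtol=1e-12)
        except Exception:
            continue
        rss = float(2.0 * sol.cost)
        if best is None or rss < best[0]:
            best = (rss, sol)
    if best is None:
        raise FitError("biexponential fit failed from every start")
    rss, sol = best
    taus = np.exp(sol.x)
    _, amps = _projected_residuals(sol.x, t, y)
    (tau_f, a1), (tau_s, a2) = sorted([(taus[0], amps[0]), (taus[1], amps[1])])
    a0 = amps[2]

    if abs(tau_s - tau_f) / tau_s < TAU_DEGENERACY_RTOL:
        return _fit_single(t, y)
    return KineticsFit(A0=float(a0), A1=float(a1), A2=float(a2),
                       tau_f_ms=float(tau_f), tau_s_ms=float(tau_s),
                       rss=rss, converged=bool(sol.success))


def _fit_single(t: np.ndarray, y: np.ndarray) -> KineticsFit:
    best = None
    for tau0 in MULTISTART_TAUF_MS + MULTISTART_TAUS_MS:
        sol = least_squares(
            lambda lt: _projected_residuals(lt, t, y)[0],
            x0=np.log([tau0]), bounds=(np.log(1e-3), np.log(1e5)),
            xtol=1e-12, ftol=1e-12, gtol=1e-12)
        rss = float(2.0 * sol.cost)
        if best is None or rss < best[0]:
            best = (rss, sol)
    rss, sol = best
    tau = float(np.exp(sol.x[0]))
    _, amps = _projected_residuals(sol.x, t, y)
    return KineticsFit(A0=float(amps[1]), A1=float(amps[0]), A2=0.0,
                       tau_f_ms=tau, tau_s_ms=tau, rss=rss,
                       converged=bool(sol.success))


#: default blanking after step onset before the fit window opens (ms);
#: real recordings carry a capacitive transient there.
DEFAULT_BLANK_MS = 0.5


def fit_sweepset_kinetics(s: SweepSet, blank_ms: float = DEFAULT_BLANK_MS) -> pd.DataFrame:
    """Fit every test-step relaxation of a sweep set.

    The window runs from ``blank_ms`` after step onset to the end of the
    (pre-interpulse) test step.  Returns one row per test potential with
    columns V_mV, A0, A1, A2, tau_f_ms, tau_s_ms, W_P, W_C, W_const, rss,
    converged.
    """
    rows = []
    for r, v in enumerate(s.protocol.steps_mV):
        name, _, start, n = s.protocol.segment_table(v)[0]
        t0 = s.t_ms[start]
        fit = fit_biexponential(s.t_ms, s.sweeps[r],
                                window=(t0 + blank_ms, t0 + (n - 1) * s.protocol.dt_ms))
        rows.append(dict(V_mV=v, A0=fit.A0, A1=fit.A1, A2=fit.A2,
                         tau_f_ms=fit.tau_f_ms, tau_s_ms=fit.tau_s_ms,
                         W_P=fit.W_P, W_C=fit.W_C, W_const=fit.W_const,
                         rss=fit.rss, converged=fit.converged))
    return pd.DataFrame(rows)
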