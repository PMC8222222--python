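"""Non-stationary noise analysis.

The time-resolved ensemble variance is estimated from consecutive-sweep
differences (robust to slow rundown):

    sigma^2(t) = 1/(2(M-1)) * sum_{j=1}^{M-1} [I_{j+1}(t) - I_j(t)]^2

and the variance-mean relation of a double-barrelled channel,

    sigma^2 = (1 + P_P) * i * I_bar - I_bar^2 / N,

is fitted for the single-protopore current ``i`` and channel count ``N``
with P_P held at a user-supplied constant (0 or 1 in the classic cases).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Union

import numpy as np

from gatekit.errors import ArgumentError, FitError

DEFAULT_N_BINS = 50
#: fraction of lowest-|mean| points used for the instrument-noise baseline
BASELINE_DECILE = 0.10


def nonstationary_variance(repeats: np.ndarray):
    """Pairwise-difference variance and ensemble mean of repeated sweeps.

    ``repeats`` is (M, n_time) with M >= 2 identical-protocol sweeps.
    Returns ``(I_bar_t, sigma2_t)``.  On i.i.d. noise the pairwise estimator
    is unbiased for the true ensemble variance.
    """
    X = np.asarray(repeats, dtype=float)
    if X.ndim != 2:
        raise ArgumentError("repeats must be a (M, n_time) matrix")
    M = X.shape[0]
    if M < 2:
        raise ArgumentError(f"need >= 2 sweeps, got {M}")
    diffs = np.diff(X, axis=0)
    sigma2 = (diffs ** 2).sum(axis=0) / (2.0 * (M - 1))
    return X.mean(axis=0), sigma2


@dataclass(frozen=True)
class NoiseResult:
    """Variance-mean fit of Eq. sigma^2 = (1+P_P) i I_bar - I_bar^2/N."""

    M: int
    i_pA: float
    N: float
    P_P_assumed: float
    baseline_pA2: float
    n_bins: int
    cov: np.ndarray          # covariance of the raw (a, b) coefficients
    I_bar_bins: np.ndarray
    sigma2_bins: np.ndarray

    @property
    def vertex_mean_pA(self) -> float:
        """Mean current at the parabola maximum, (1+P_P) i N / 2."""
        return (1.0 + self.P_P_assumed) * self.i_pA * self.N / 2.0

    def predict(self, I_bar):
        I = np.asarray(I_bar, dtype=float)
        return (1.0 + self.P_P_assumed) * self.i_pA * I - I ** 2 / self.N


def fit_variance_mean(I_bar: np.ndarray, sigma2: np.ndarray,
                      P_P_assumed: float, n_bins: int = DEFAULT_N_BINS,
                      baseline: Union[str, float, None] = "auto",
                      M: int = 0) -> NoiseResult:
    """Fit the double-barrel variance-mean parabola.

    Points are binned by mean current (``n_bins`` equal-width bins) before a
    linear least-squares fit of sigma^2 = a*I_bar - b*I_bar^2 with
    a = (1+P_P) i and b = 1/N.  ``baseline`` is the instrument-noise
    variance subtracted first: "auto" estimates it from the lowest-|I_bar|
    decile of points, a float is used verbatim, None disables subtraction.

    Constraints: N > 0 and sign(i) = sign of the mean current; violations
    raise :class:`~gatekit.errors.FitError`.
    """
    I = np.asarray(I_bar, dtype=float).ravel()
    s2 = np.asarray(sigma2, dtype=float).ravel()
    if I.shape != s2.shape:
        raise ArgumentError("I_bar and sigma2 must have matching shapes")
    if I.size < 10:
        raise ArgumentError(f"need >= 10 points, got {I.size}")
    if not 0.0 <= P_P_assumed <= 1.0:
        raise ArgumentError("P_P_assumed must lie in [0, 1]")
    spread = I.max() - I.min()
    if spread < 0.10 * np.max(np.abs(I)):
        raise FitError("degenerate mean-current range (< 10% spread)")

    if baseline == "auto":
        order = np.argsort(np.abs(I))
        n_base = max(1, int(round(BASELINE_DECILE * I.size)))
        baseline_val = float(s2[order[:n_base]].mean())
    elif baseline is None:
        baseline_val = 0.0
    else:
        baseline_val = float(baseline)
    s2 = s2 - baseline_val

    edges = np.linspace(I.min(), I.max(), n_bins + 1)
    which = np.clip(np.digitize(I, edges) - 1, 0, n_bins - 1)
    I_b, s2_b = [], []
    for b in range(n_bins):
        m = which == b
        if m.any():
            I_b.append(I[m].mean())
            s2_b.append(s2[m].mean())
    I_b = np.array(I_b)
    s2_b = np.array(s2_b)

    X = np.column_stack([I_b, -I_b ** 2])
    coef, res, _, _ = np.linalg.lstsq(X, s2_b, rcond=None)
    a, b = coef
    dof = max(len(I_b) - 2, 1)
    rss = float(res[0]) if res.size else float(np.sum((X @ coef - s2_b) ** 2))
    cov = rss / dof * np.linalg.inv(X.T @ X)

    if b <= 0:
        raise FitError(f"fitted channel count is not positive (1/N = {b:.3g})")
    i_hat = a / (1.0 + P_P_assumed)
    sign_I = np.sign(np.mean(I_b))
    if sign_I != 0 and np.sign(i_hat) != sign_I:
        raise FitError("fitted single-channel current sign contradicts the "
                       "mean current")
    return NoiseResult(M=M, i_pA=float(i_hat), N=float(1.0 / b),
                       P_P_assumed=float(P_P_assumed),
                       baseline_pA2=baseline_val, n_bins=n_bins, cov=cov,
                       I_bar_bins=I_b, sigma2_bins=s2_b)


def analyse_repeats(repeats: np.ndarray, P_P_assumed: float,
                    n_bins: int = DEFAULT_N_BINS,
                    baseline: Union[str, float, None] = "auto",
                    t_mask: Optional[np.ndarray] = None) -> NoiseResult:
    """End-to-end pipeline: pairwise variance then variance-mean fit."""
    I_bar, s2 = nonstationary_variance(repeats)
    if t_mask is not None:
        I_bar, s2 = I_bar[t_mask], s2[t_mask]
    return fit_variance_mean(I_bar, s2, P_P_assumed, n_bins=n_bins,
                             baseline=baseline, M=repeats.shape[0])
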