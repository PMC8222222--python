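"""Anomalous mole fraction (AMF) profiling.

V05 (and Er) are tabulated against the mole fraction of a substituting
anion.  AMF behaviour is quantified by the maximum signed deviation of
V05(x) from the chord joining the endpoint values: interior points lying
above the chord give a "concave" profile, below give "convex", and
deviations within tolerance give "linear".  The tolerance defaults to twice
the largest V05 standard error in the series, floored at 3 mV.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from gatekit.errors import ArgumentError

CHORD_TOL_FLOOR_MV = 3.0
CHORD_TOL_SE_FACTOR = 2.0


@dataclass
class MoleFractionSeries:
    """V05 and Er versus anion mole fraction, with standard errors."""

    x: np.ndarray
    V05_mV: np.ndarray
    se_V05: Optional[np.ndarray] = None
    Er_mV: Optional[np.ndarray] = None
    se_Er: Optional[np.ndarray] = None
    anion: str = "SCN"
    pH_i: float = 7.3

    def __post_init__(self):
        self.x = np.asarray(self.x, dtype=float)
        self.V05_mV = np.asarray(self.V05_mV, dtype=float)
        if self.x.ndim != 1 or self.x.shape != self.V05_mV.shape:
            raise ArgumentError("x and V05_mV must be matching 1-D arrays")
        if np.any(self.x < 0) or np.any(self.x > 1):
            raise ArgumentError("mole fractions must lie in [0, 1]")
        if np.any(np.diff(self.x) <= 0):
            raise ArgumentError("x must be sorted ascending and unique")
        for name in ("se_V05", "Er_mV", "se_Er"):
            v = getattr(self, name)
            if v is not None:
                v = np.asarray(v, dtype=float)
                if v.shape != self.x.shape:
                    raise ArgumentError(f"{name} must match x in shape")
                setattr(self, name, v)


@dataclass(frozen=True)
class AMFResult:
    chord_dev_mV: float        # maximum signed deviation from the chord
    is_amf: bool
    is_nonmonotonic: bool
    direction: str             # "concave" | "convex" | "linear"
    tol_mV: float
    deviations_mV: np.ndarray  # per interior point


def amf_profile(series: MoleFractionSeries,
                tol_mV: Optional[float] = None) -> AMFResult:
    """Chord-deviation AMF statistic for one mole-fraction series.

    Requires at least 3 points including both endpoints x=0 and x=1 (the
    chord is undefined otherwise).  Er monotonicity never enters the AMF
    call; it is a separate readout.
    """
    x, v = series.x, series.V05_mV
    if x.size < 3:
        raise ArgumentError("need >= 3 mole-fraction points")
    if not (np.isclose(x[0], 0.0) and np.isclose(x[-1], 1.0)):
        raise ArgumentError("series must include both endpoints x=0 and x=1")
    if tol_mV is None:
        tol_mV = CHORD_TOL_FLOOR_MV
        if series.se_V05 is not None:
            tol_mV = max(tol_mV,
                         CHORD_TOL_SE_FACTOR * float(np.max(series.se_V05)))

    chord = v[0] + (v[-1] - v[0]) * (x - x[0]) / (x[-1] - x[0])
    dev = (v - chord)[1:-1]
    k = int(np.argmax(np.abs(dev)))
    chord_dev = float(dev[k])
    is_amf = abs(chord_dev) > tol_mV
    if not is_amf:
        direction = "linear"
    elif chord_dev > 0:
        direction = "concave"   # values above the chord
    else:
        direction = "convex"
    signs = np.sign(np.diff(v))
    nonmono = bool(np.any(signs[:-1] * signs[1:] < 0))
    return AMFResult(chord_dev_mV=chord_dev if is_amf else chord_dev,
                     is_amf=is_amf, is_nonmonotonic=nonmono,
                     direction=direction, tol_mV=float(tol_mV),
                     deviations_mV=dev)
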