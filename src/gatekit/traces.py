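"""Sweep/protocol data model, on-disk bundle format, junction correction.

A *sweep bundle* is a directory holding ``meta.json`` (recording metadata and
the voltage protocol) plus one or more CSV trace tables:

* ``sweeps.csv`` — header ``t_ms,V_-160,V_-140,...``; one row per sample;
  one current column per test potential, in picoamperes.
* ``sweeps_rep<k>.csv`` — optional identical-protocol repetitions (for noise
  analysis), stacked in file-name order.

Time is milliseconds, current picoamperes, voltage millivolts throughout.
"""

from __future__ import annotations

import json
import math
import re
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from gatekit.errors import ArgumentError, FormatError, ShapeError

_REP_RE = re.compile(r"^sweeps_rep(\d+)\.csv$")


@dataclass(frozen=True)
class Interpulse:
    """Brief pulse intercalated in each test step after steady state.

    The default (-200 mV / 15 ms) drives the fast protopore gate fully open
    so the current immediately after the pulse reports the common gate alone.
    """

    voltage_mV: float
    duration_ms: float
    onset: str = "after_steady_state"


@dataclass(frozen=True)
class VoltageProtocol:
    """Step protocol: holding -> test step (+ optional interpulse) -> tail.

    When an interpulse is present each sweep runs: test potential for
    ``step_ms`` (reaching steady state), the interpulse, then the test
    potential again for ``post_interpulse_ms`` before the tail step.
    """

    holding_mV: float
    steps_mV: tuple
    step_ms: float
    tail_mV: float
    tail_ms: float
    sample_rate_kHz: float = 10.0
    interpulse: Optional[Interpulse] = None
    post_interpulse_ms: float = 25.0

    def __post_init__(self):
        steps = tuple(float(v) for v in self.steps_mV)
        object.__setattr__(self, "steps_mV", steps)
        if len(steps) == 0:
            raise ArgumentError("protocol needs at least one test potential")
        if len(steps) > 1:
            incs = np.diff(steps)
            if not (np.all(incs > 0) or np.all(incs < 0)):
                raise ArgumentError("steps_mV must be strictly monotone")
            if not np.allclose(incs, incs[0], rtol=0, atol=1e-9):
                raise ArgumentError("steps_mV must use a uniform increment")
        if self.step_ms <= 0 or self.sample_rate_kHz <= 0:
            raise ArgumentError("durations and sample rate must be positive")
        if self.tail_ms < 0:
            raise ArgumentError("tail_ms must be >= 0")
        if self.interpulse is not None:
            if self.interpulse.duration_ms <= 0:
                raise ArgumentError("interpulse duration must be positive")
            if self.interpulse.duration_ms >= self.step_ms:
                raise ArgumentError("interpulse duration must be < step_ms")
            if self.post_interpulse_ms <= 0:
                raise ArgumentError("post_interpulse_ms must be positive")

    @property
    def dt_ms(self) -> float:
        return 1.0 / self.sample_rate_kHz

    def segments(self, step_mV: float) -> list:
        """(name, voltage_mV, duration_ms) triples for one sweep epoch."""
        segs = [("step", float(step_mV), self.step_ms)]
        if self.interpulse is not None:
            segs.append(("interpulse", self.interpulse.voltage_mV,
                         self.interpulse.duration_ms))
            segs.append(("post", float(step_mV), self.post_interpulse_ms))
        if self.tail_ms > 0:
            segs.append(("tail", self.tail_mV, self.tail_ms))
        return segs

    def segment_table(self, step_mV: float) -> list:
        """(name, voltage_mV, start_index, n_samples) for each segment.

        The sample at a segment boundary belongs to the *new* segment: it is
        recorded at the new command voltage with the gate state inherited
        from the previous segment (instantaneous current convention).
        """
        out, start = [], 0
        for name, v, dur in self.segments(step_mV):
            n = int(round(dur * self.sample_rate_kHz))
            if n < 1:
                raise ArgumentError(f"segment {name!r} shorter than one sample")
            out.append((name, v, start, n))
            start += n
        return out

    @property
    def n_samples(self) -> int:
        return sum(n for _, _, _, n in self.segment_table(self.steps_mV[0]))

    def time_ms(self) -> np.ndarray:
        return np.arange(self.n_samples) * self.dt_ms

    def sample_voltages(self, step_mV: float) -> np.ndarray:
        v = np.empty(self.n_samples)
        for _, volt, start, n in self.segment_table(step_mV):
            v[start:start + n] = volt
        return v

    def to_dict(self) -> dict:
        d = {
            "holding_mV": self.holding_mV,
            "steps_mV": list(self.steps_mV),
            "step_ms": self.step_ms,
            "tail_mV": self.tail_mV,
            "tail_ms": self.tail_ms,
            "sample_rate_kHz": self.sample_rate_kHz,
            "post_interpulse_ms": self.post_interpulse_ms,
        }
        if self.interpulse is not None:
            d["interpulse"] = {
                "voltage_mV": self.interpulse.voltage_mV,
                "duration_ms": self.interpulse.duration_ms,
                "onset": self.interpulse.onset,
            }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "VoltageProtocol":
        try:
            ip = d.get("interpulse")
            interpulse = Interpulse(**ip) if ip is not None else None
            return cls(
                holding_mV=float(d["holding_mV"]),
                steps_mV=tuple(float(v) for v in d["steps_mV"]),
                step_ms=float(d["step_ms"]),
                tail_mV=float(d["tail_mV"]),
                tail_ms=float(d["tail_ms"]),
                sample_rate_kHz=float(d.get("sample_rate_kHz", 10.0)),
                interpulse=interpulse,
                post_interpulse_ms=float(d.get("post_interpulse_ms", 25.0)),
            )
        except KeyError as exc:  # pragma: no cover - exercised via read_sweepset
            raise FormatError(f"protocol missing field {exc.args[0]!r}") from exc


@dataclass(frozen=True)
class RecordingMeta:
    """Solutions, pH, temperature and junction potential of one recording."""

    Cl_in_mM: float = 140.0
    Cl_out_mM: float = 140.0
    pH_in: float = 7.3
    pH_out: float = 7.3
    temperature_C: float = 22.0
    junction_mV: float = 0.0
    channel_label: str = "WT"
    corrected: bool = False

    def __post_init__(self):
        if self.Cl_in_mM <= 0 or self.Cl_out_mM <= 0:
            raise ArgumentError("chloride concentrations must be positive")
        if not (0 < self.pH_in < 14 and 0 < self.pH_out < 14):
            raise ArgumentError("pH values must lie in (0, 14)")

    @property
    def T_K(self) -> float:
        return self.temperature_C + 273.15

    def to_dict(self) -> dict:
        return {
            "Cl_in_mM": self.Cl_in_mM,
            "Cl_out_mM": self.Cl_out_mM,
            "pH_in": self.pH_in,
            "pH_out": self.pH_out,
            "temperature_C": self.temperature_C,
            "junction_mV": self.junction_mV,
            "channel_label": self.channel_label,
            "corrected": self.corrected,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RecordingMeta":
        known = {f: d[f] for f in (
            "Cl_in_mM", "Cl_out_mM", "pH_in", "pH_out", "temperature_C",
            "junction_mV", "channel_label", "corrected") if f in d}
        for f in ("Cl_in_mM", "Cl_out_mM", "pH_in", "pH_out"):
            if f not in known:
                raise FormatError(f"meta.json missing field {f!r}")
            if not isinstance(known[f], (int, float)) or isinstance(known[f], bool):
                raise FormatError(f"meta.json field {f!r} is not numeric")
        return cls(**known)


@dataclass
class SweepSet:
    """Time-stamped current sweeps for one step protocol.

    ``sweeps`` has shape (n_steps, n_time); when identical-protocol
    repetitions are present ``repeats`` adds a leading axis
    (n_repeats, n_steps, n_time) and ``sweeps`` holds the ensemble mean.
    """

    t_ms: np.ndarray
    sweeps: np.ndarray
    protocol: VoltageProtocol
    meta: RecordingMeta = field(default_factory=RecordingMeta)
    repeats: Optional[np.ndarray] = None

    def __post_init__(self):
        self.t_ms = np.asarray(self.t_ms, dtype=float)
        self.sweeps = np.asarray(self.sweeps, dtype=float)
        if self.t_ms.ndim != 1:
            raise ShapeError("t_ms must be one-dimensional")
        if self.sweeps.ndim != 2:
            raise ShapeError("sweeps must be (n_steps, n_time)")
        if self.sweeps.shape[1] != self.t_ms.size:
            raise ShapeError(
                f"trace length {self.sweeps.shape[1]} != time vector length "
                f"{self.t_ms.size}")
        if self.sweeps.shape[0] != len(self.protocol.steps_mV):
            raise ShapeError(
                f"{self.sweeps.shape[0]} sweep rows for "
                f"{len(self.protocol.steps_mV)} test potentials")
        if self.t_ms.size > 1:
            dts = np.diff(self.t_ms)
            if not np.allclose(dts, self.protocol.dt_ms, rtol=1e-6, atol=1e-9):
                raise ShapeError("time vector is not uniform at 1/sample_rate")
        if self.repeats is not None:
            self.repeats = np.asarray(self.repeats, dtype=float)
            if self.repeats.ndim != 3 or self.repeats.shape[1:] != self.sweeps.shape:
                raise ShapeError("repeats must be (n_repeats, n_steps, n_time)")

    @property
    def n_steps(self) -> int:
        return self.sweeps.shape[0]

    @property
    def n_repeats(self) -> int:
        return 0 if self.repeats is None else self.repeats.shape[0]

    def step_voltages(self) -> np.ndarray:
        return np.asarray(self.protocol.steps_mV)


# ---------------------------------------------------------------------------
# bundle IO

_CSV_FMT = "%.17g"


def _voltage_header(steps_mV: Sequence[float]) -> list:
    return ["t_ms"] + [f"V_{v:+g}" for v in steps_mV]


def _write_csv(path: Path, t_ms: np.ndarray, block: np.ndarray,
               steps_mV: Sequence[float]) -> None:
    table = np.column_stack([t_ms, block.T])
    header = ",".join(_voltage_header(steps_mV))
    np.savetxt(path, table, fmt=_CSV_FMT, delimiter=",", header=header, comments="")


def _read_csv(path: Path, n_steps: int) -> tuple:
    with open(path) as fh:
        header = fh.readline().strip().split(",")
    if header[0] != "t_ms":
        raise FormatError(f"{path.name}: first column must be 't_ms'")
    if len(header) != n_steps + 1:
        raise ShapeError(
            f"{path.name}: {len(header) - 1} trace columns for {n_steps} "
            "test potentials")
    data = np.loadtxt(path, delimiter=",", skiprows=1, ndmin=2)
    if data.shape[1] != n_steps + 1:
        raise ShapeError(f"{path.name}: ragged rows")
    return data[:, 0], data[:, 1:].T


def write_sweepset(s: SweepSet, path) -> Path:
    """Write a sweep bundle readable by :func:`read_sweepset`.

    The numeric round trip is lossless to double precision (``%.17g``).
    Repeats, when present, go to zero-padded ``sweeps_rep<k>.csv`` files so
    that file-name order equals repeat order.
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    meta = s.meta.to_dict()
    meta["protocol"] = s.protocol.to_dict()
    with open(path / "meta.json", "w") as fh:
        json.dump(meta, fh, indent=1)
    _write_csv(path / "sweeps.csv", s.t_ms, s.sweeps, s.protocol.steps_mV)
    if s.repeats is not None:
        width = max(2, int(math.log10(max(s.n_repeats, 1))) + 1)
        for k in range(s.n_repeats):
            _write_csv(path / f"sweeps_rep{k + 1:0{width}d}.csv",
                       s.t_ms, s.repeats[k], s.protocol.steps_mV)
    return path


def read_sweepset(path) -> SweepSet:
    """Read a sweep bundle (``meta.json`` + CSV trace tables)."""
    path = Path(path)
    meta_path = path / "meta.json"
    if not meta_path.exists():
        raise FormatError(f"{path}: missing meta.json")
    with open(meta_path) as fh:
        raw = json.load(fh)
    if "protocol" not in raw:
        raise FormatError("meta.json missing field 'protocol'")
    protocol = VoltageProtocol.from_dict(raw["protocol"])
    meta = RecordingMeta.from_dict(raw)
    n_steps = len(protocol.steps_mV)

    sweeps_path = path / "sweeps.csv"
    if not sweeps_path.exists():
        raise FormatError(f"{path}: missing sweeps.csv")
    t_ms, sweeps = _read_csv(sweeps_path, n_steps)

    rep_files = sorted(
        (p for p in path.iterdir() if _REP_RE.match(p.name)),
        key=lambda p: int(_REP_RE.match(p.name).group(1)))
    repeats = None
    if rep_files:
        blocks = []
        for p in rep_files:
            t_rep, block = _read_csv(p, n_steps)
            if block.shape != sweeps.shape:
                raise ShapeError(f"{p.name}: repeat shape {block.shape} != "
                                 f"sweeps shape {sweeps.shape}")
            blocks.append(block)
        repeats = np.stack(blocks)
    return SweepSet(t_ms=t_ms, sweeps=sweeps, protocol=protocol, meta=meta,
                    repeats=repeats)


# ---------------------------------------------------------------------------
# junction-potential correction

def correct_junction_potential(s: SweepSet, undo: bool = False) -> SweepSet:
    """Apply (or revert) the liquid-junction-potential correction.

    Every command voltage in the protocol is replaced by ``V - junction_mV``
    and the ``corrected`` flag is set; a second application is a no-op with a
    warning.  ``undo=True`` restores the original voltages exactly.
    """
    if not undo and s.meta.corrected:
        warnings.warn("junction potential already corrected; returning input "
                      "unchanged", stacklevel=2)
        return s
    if undo and not s.meta.corrected:
        warnings.warn("junction potential not yet corrected; nothing to undo",
                      stacklevel=2)
        return s
    dj = -s.meta.junction_mV if not undo else s.meta.junction_mV
    p = s.protocol
    ip = p.interpulse
    if ip is not None:
        ip = replace(ip, voltage_mV=ip.voltage_mV + dj)
    protocol = replace(
        p,
        holding_mV=p.holding_mV + dj,
        steps_mV=tuple(v + dj for v in p.steps_mV),
        tail_mV=p.tail_mV + dj,
        interpulse=ip,
    )
    meta = replace(s.meta, corrected=not undo)
    return SweepSet(t_ms=s.t_ms, sweeps=s.sweeps, protocol=protocol,
                    meta=meta, repeats=s.repeats)
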