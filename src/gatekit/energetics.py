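"""Double-mutant-cycle energetics and group-comparison statistics.

The gating energy change caused by a mutation is

    Delta(zFV05) = -F (z_wt V05_wt - z_mut V05_mut)        [kcal/mol]

with V05 in volts and F = 23.061 kcal mol^-1 V^-1.  A mutant cycle walks the
four corners WT -> A, B -> AB (edge pair 1/2) and WT -> B, A -> AB (edge
pair 3/4); unequal parallel edges indicate that the two mutated residues are
energetically coupled.  Uncertainty comes from a seeded parametric bootstrap
over the corner parameters.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from gatekit.constants import F_KCAL_PER_MOL_V
from gatekit.errors import ArgumentError


@dataclass(frozen=True)
class CornerParams:
    """Fitted Boltzmann parameters (mean +/- SD) of one cycle corner."""

    label: str
    z: float
    V05_mV: float
    sd_z: float = 0.0
    sd_V05: float = 0.0
    n: int = 1

    def __post_init__(self):
        if self.n < 1:
            raise ArgumentError("n must be >= 1")
        if self.sd_z < 0 or self.sd_V05 < 0:
            raise ArgumentError("standard deviations must be >= 0")


def gating_energy_change(wt: CornerParams, mut: CornerParams) -> float:
    """Signed gating energy change of a mutation, in kcal/mol."""
    return -F_KCAL_PER_MOL_V * (wt.z * wt.V05_mV - mut.z * mut.V05_mV) / 1000.0


def _deltas(z: np.ndarray, v_mV: np.ndarray) -> np.ndarray:
    """Edge energies for corner arrays ordered (WT, A, B, AB).

    delta_1: WT->A, delta_2: B->AB, delta_3: WT->B, delta_4: A->AB, so that
    delta_1 + delta_4 = delta_2 + delta_3 exactly (both telescope WT->AB).
    """
    zv = z * v_mV / 1000.0
    d1 = -F_KCAL_PER_MOL_V * (zv[..., 0] - zv[..., 1])
    d2 = -F_KCAL_PER_MOL_V * (zv[..., 2] - zv[..., 3])
    d3 = -F_KCAL_PER_MOL_V * (zv[..., 0] - zv[..., 2])
    d4 = -F_KCAL_PER_MOL_V * (zv[..., 1] - zv[..., 3])
    return np.stack([d1, d2, d3, d4], axis=-1)


@dataclass(frozen=True)
class MutantCycleResult:
    labels: tuple
    delta: np.ndarray          # point estimates, kcal/mol, edges 1..4
    delta_sd: np.ndarray       # bootstrap SDs
    coupling_12: float         # delta_2 - delta_1
    coupling_34: float         # delta_4 - delta_3
    p_12: float
    p_34: float
    n_boot: int
    seed: int


def _boot_pvalue(draws: np.ndarray) -> float:
    """Two-sided bootstrap p-value that the difference is zero."""
    n = draws.size
    lo = (np.sum(draws <= 0) + 1) / (n + 1)
    hi = (np.sum(draws >= 0) + 1) / (n + 1)
    return float(min(1.0, 2.0 * min(lo, hi)))


def mutant_cycle(corners: Sequence[CornerParams], n_boot: int = 1000,
                 seed: int = 0) -> MutantCycleResult:
    """Full double-mutant-cycle analysis on corners (WT, A, B, AB).

    Point estimates come from the corner means; uncertainty from a
    parametric bootstrap resampling each corner's (z, V05) from independent
    normals with the supplied SDs.  p-values compare the parallel edge
    pairs (1 vs 2 and 3 vs 4) two-sidedly from the bootstrap distribution.
    """
    if len(corners) != 4:
        raise ArgumentError("mutant cycle needs exactly 4 corners "
                            "(WT, mutant A, mutant B, double mutant)")
    z0 = np.array([c.z for c in corners])
    v0 = np.array([c.V05_mV for c in corners])
    point = _deltas(z0, v0)

    rng = np.random.default_rng(seed)
    sz = np.array([c.sd_z for c in corners])
    sv = np.array([c.sd_V05 for c in corners])
    z_b = rng.normal(z0, sz, size=(n_boot, 4))
    v_b = rng.normal(v0, sv, size=(n_boot, 4))
    boot = _deltas(z_b, v_b)

    c12 = boot[:, 1] - boot[:, 0]
    c34 = boot[:, 3] - boot[:, 2]
    return MutantCycleResult(
        labels=tuple(c.label for c in corners),
        delta=point,
        delta_sd=boot.std(axis=0, ddof=1),
        coupling_12=float(point[1] - point[0]),
        coupling_34=float(point[3] - point[2]),
        p_12=_boot_pvalue(c12),
        p_34=_boot_pvalue(c34),
        n_boot=n_boot,
        seed=seed,
    )


@dataclass(frozen=True)
class GroupComparison:
    F: float
    p: float
    alpha: float
    pairs: tuple               # (label_a, label_b, meandiff, p_adj, reject)

    def flagged(self) -> tuple:
        return tuple((a, b) for a, b, _, _, rej in self.pairs if rej)


def compare_groups(groups: Dict[str, Sequence[float]],
                   alpha: float = 0.01) -> GroupComparison:
    """One-way ANOVA with Tukey HSD pairwise flags at ``alpha`` (default 0.01)."""
    if len(groups) < 2:
        raise ArgumentError("need >= 2 groups")
    for label, vals in groups.items():
        if len(vals) < 2:
            raise ArgumentError(f"group {label!r} has n < 2")
    labels = list(groups)
    arrays = [np.asarray(groups[k], dtype=float) for k in labels]
    F, p = stats.f_oneway(*arrays)
    values = np.concatenate(arrays)
    tags = np.concatenate([[k] * len(a) for k, a in zip(labels, arrays)])
    tk = pairwise_tukeyhsd(values, tags, alpha=alpha)
    pairs = tuple(
        (str(a), str(b), float(md), float(padj), bool(rej))
        for a, b, md, padj, rej in zip(
            tk.groupsunique[tk._multicomp.pairindices[0]],
            tk.groupsunique[tk._multicomp.pairindices[1]],
            tk.meandiffs, tk.pvalues, tk.reject))
    return GroupComparison(F=float(F), p=float(p), alpha=alpha, pairs=pairs)
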