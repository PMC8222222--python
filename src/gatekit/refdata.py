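"""Published reference gating parameters for rat CLC-2 and mutants.

Boltzmann parameters (half-activation voltage V05 in mV, apparent charge z,
mean +/- SD) of the apparent (P_A), pore (P_P) and common (P_C) open
probabilities under the conditions listed; whole-cell HEK-293 recordings,
opening branch only.  Used as inputs for the mutant-cycle energetics and as
ground truth for fixture models.
"""

from __future__ import annotations

import pandas as pd

from gatekit.energetics import CornerParams

_RECORDS = [
    # label, pH_i, Cl_o_mM, then (V05, sd, z, sd) for PA, PP, PC, Er, sd_Er, n
    dict(label="WT", pH_i=7.3, Cl_o_mM=140,
         V05_PA=-89.3, sd_V05_PA=8.5, z_PA=-0.84, sd_z_PA=0.04,
         V05_PP=-56.6, sd_V05_PP=1.0, z_PP=-1.17, sd_z_PP=0.07,
         V05_PC=-110.9, sd_V05_PC=6.3, z_PC=-0.75, sd_z_PC=0.03,
         Er_mV=None, sd_Er=None, n=5),
    dict(label="WT", pH_i=7.3, Cl_o_mM=10,
         V05_PA=-79.1, sd_V05_PA=5.8, z_PA=-0.78, sd_z_PA=0.02,
         V05_PP=-39.5, sd_V05_PP=2.2, z_PP=-1.19, sd_z_PP=0.07,
         V05_PC=-82.9, sd_V05_PC=6.1, z_PC=-0.54, sd_z_PC=0.04,
         Er_mV=57.4, sd_Er=0.6, n=5),
    dict(label="Y561F", pH_i=7.3, Cl_o_mM=140,
         V05_PA=-34.8, sd_V05_PA=9.4, z_PA=-0.8, sd_z_PA=0.0,
         V05_PP=-13.8, sd_V05_PP=6.4, z_PP=-1.1, sd_z_PP=0.1,
         V05_PC=-51.2, sd_V05_PC=6.4, z_PC=-0.4, sd_z_PC=0.0,
         Er_mV=None, sd_Er=None, n=9),
    dict(label="Y561F", pH_i=7.3, Cl_o_mM=10,
         V05_PA=-68.9, sd_V05_PA=5.4, z_PA=-0.67, sd_z_PA=0.02,
         V05_PP=-6.3, sd_V05_PP=4.4, z_PP=-0.73, sd_z_PP=0.04,
         V05_PC=-71.9, sd_V05_PC=4.5, z_PC=-0.62, sd_z_PC=0.07,
         Er_mV=52.5, sd_Er=1.6, n=6),
    dict(label="Y561A", pH_i=7.3, Cl_o_mM=140,
         V05_PA=-21.2, sd_V05_PA=6.2, z_PA=-0.79, sd_z_PA=0.07,
         V05_PP=5.1, sd_V05_PP=2.8, z_PP=-1.25, sd_z_PP=0.02,
         V05_PC=-65.6, sd_V05_PC=10.6, z_PC=-0.81, sd_z_PC=0.06,
         Er_mV=None, sd_Er=None, n=7),
    dict(label="E213D", pH_i=7.3, Cl_o_mM=140,
         V05_PA=-92.4, sd_V05_PA=1.4, z_PA=-0.60, sd_z_PA=0.02,
         V05_PP=-43.0, sd_V05_PP=2.8, z_PP=-0.74, sd_z_PP=0.03,
         V05_PC=-86.0, sd_V05_PC=6.1, z_PC=-0.51, sd_z_PC=0.01,
         Er_mV=None, sd_Er=None, n=8),
    dict(label="E213D-Y561A", pH_i=7.3, Cl_o_mM=140,
         V05_PA=-35.4, sd_V05_PA=4.1, z_PA=-0.67, sd_z_PA=0.03,
         V05_PP=-5.6, sd_V05_PP=1.5, z_PP=-1.11, sd_z_PP=0.10,
         V05_PC=-63.3, sd_V05_PC=9.4, z_PC=-0.61, sd_z_PC=0.05,
         Er_mV=None, sd_Er=None, n=7),
]


def reference_params() -> pd.DataFrame:
    """Reference Boltzmann-parameter table as a DataFrame."""
    return pd.DataFrame(_RECORDS)


def corner(label: str, component: str = "PP", pH_i: float = 7.3,
           Cl_o_mM: float = 140) -> CornerParams:
    """Build a mutant-cycle corner from the reference table.

    ``component`` selects which gating component's (V05, z) to use:
    "PA", "PP" or "PC".
    """
    df = reference_params()
    row = df[(df.label == label) & (df.pH_i == pH_i) & (df.Cl_o_mM == Cl_o_mM)]
    if row.empty:
        raise KeyError(f"no reference row for {label!r} at pH {pH_i}, "
                       f"[Cl-]o {Cl_o_mM} mM")
    r = row.iloc[0]
    return CornerParams(label=label,
                        z=float(r[f"z_{component}"]),
                        V05_mV=float(r[f"V05_{component}"]),
                        sd_z=float(r[f"sd_z_{component}"]),
                        sd_V05=float(r[f"sd_V05_{component}"]),
                        n=int(r["n"]))


def cycle_corners(component: str = "PP"):
    """The canonical (WT, E213D, Y561A, E213D-Y561A) corner quadruple."""
    return tuple(corner(lbl, component)
                 for lbl in ("WT", "E213D", "Y561A", "E213D-Y561A"))
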