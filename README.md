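# gatekit

Gating analysis for voltage-clamp recordings of a double-barrelled chloride
channel (two fast protopore gates plus one slow common gate per dimer), with
a stochastic two-gate simulator so the whole pipeline is testable without
any experimental data.

## What it does

| Module | Purpose |
|---|---|
| `gatekit.traces` | Sweep/protocol data model, on-disk sweep-bundle format (`meta.json` + CSV traces), liquid-junction-potential correction |
| `gatekit.synth` | Exact Markov simulation of the dimeric two-gate channel; standard activation/interpulse/noise protocols; Nernst and Henderson–Hasselbalch utilities |
| `gatekit.kinetics` | Biexponential relaxation fits: `tau_f`, `tau_s` and the fractional weights `W_P`, `W_C`, `W_const` |
| `gatekit.gating` | Reversal potential, conductance, apparent open probability `P_A = G/G_max`, interpulse decomposition into `P_P`/`P_C`, single/double Boltzmann fits, Er-vs-Nernst QC |
| `gatekit.noise` | Non-stationary noise analysis: pairwise-difference variance and the variance–mean fit `sigma^2 = (1+P_P) i I - I^2/N` |
| `gatekit.energetics` | Double-mutant-cycle coupling energies `Delta(zFV05)` with parametric-bootstrap uncertainty; one-way ANOVA + Tukey HSD |
| `gatekit.molefraction` | Anomalous-mole-fraction profiling of `V05` vs anion mole fraction (chord-deviation statistic) |
| `gatekit.refdata` | Published reference Boltzmann parameters for WT and mutant channels |

Units throughout: millivolts, milliseconds, picoamperes, millimolar;
energies in kcal/mol (F = 23.061 kcal mol⁻¹ V⁻¹).

## CLI

Every stage is exposed as a subcommand of `gatekit`; results are emitted as
CSV/JSON with the producing configuration echoed for provenance.

```sh
# simulate a 50-repeat interpulse bundle from the default WT-like model
gatekit simulate --protocol interpulse --repeats 50 --seed 7 --out bundle/

# kinetics, conductance/open probability, gate decomposition
gatekit kinetics  --in bundle/ --out kinetics.csv
gatekit gating    --in bundle/ --source steady --out gating.csv
gatekit decompose --in bundle/ --out pppc.csv
gatekit boltzmann --in pppc.csv --column P_P --model auto --out boltz.json

# noise analysis of a repeat bundle (P_P held fixed, 0 or 1)
gatekit simulate --protocol noise --repeats 100 --seed 7 --out noisebundle/
gatekit noise --in noisebundle/ --pp 0.0 --out noise.json

# mutant cycle and mole-fraction profile from parameter tables
gatekit cycle --corners corners.csv --nboot 1000 --seed 1 --out cycle.json
gatekit amf --in series.csv --out amf.json
```

A custom model is a JSON file mirroring `TwoGateModel`
(`{"N_T": 500, "i_ref_pA": 0.23, "Er_mV": 0, "pore": {"V05_mV": -56.6,
"z": -1.17, "tau0_ms": 4, "nu_mV": 250}, ...}`), passed with
`gatekit simulate --model model.json`.

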