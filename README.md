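# growthtoggle

A simulator and analysis toolkit for a **growth-rate-controlled genetic
toggle switch**: two mutually repressing genes inserted at distant loci of
the *E. coli* chromosome, one next to the replication origin (*ori*), the
other next to the terminus (*ter*).

## Why gene position makes a toggle growth-aware

Replication of the *E. coli* chromosome takes C ≈ 40 min and must finish
≈ 20 min before division, so fast-growing cells run overlapping
replication rounds and carry more copies of *ori*-proximal genes than of
*ter*-proximal ones.  The cycle-averaged copy ratio of two loci at
distances L₁, L₂ from *ori* (ori–ter distance = 1) is

    R₁/₂ = 2^[(C/T)(L₂ − L₁)]

where T is the doubling time: 4 at T = 20 min, 2 at T = 40 min, →1 for
slow growth.  A toggle switch built from one gene copy at *ori* and two
identical copies at *ter* is therefore dosage-balanced exactly at
T = 40 min; shorter cycles tip it into the *ori*-dominant state, longer
cycles into the *ter*-dominant state.  The package implements:

* **`cell_cycle`** — the replication schedule and instantaneous /
  cycle-averaged copy numbers of any locus, the dosage-ratio law above,
  and the balanced-design calculator `L₂(T, R) = −(T/C)·log₂R`;
* **`model_params`** — the kinetic parametrization (per-second rates,
  bimolecular rates ∝ 1/volume, transcription ∝ 1/DNA content);
* **`deterministic`** — the eight-ODE mean-field model and a quasi-static
  hysteresis sweep in T that classifies mono-/bistability;
* **`stochastic`** — an exact Gillespie lineage simulation with growing
  volume, scheduled locus replication (which strips bound repressors),
  division with binomial partitioning, and a numba core (~5·10⁶ events/s);
* **`analysis`** — R_protein = (P_ori+2D_ori)/(P_ter+2D_ter) estimators,
  state-to-state mean first-passage times from exponential-tail fits,
  response times after growth-rate shifts, and two-fold parameter scans;
* **`cli`** — a `growthtoggle` command with `dosage`, `design`,
  `ode-scan`, `simulate`, `mfpt`, `respond` and `sensitivity`
  subcommands.

See `docs/methods.md` for the model definition, estimators and numerical
choices.

## Worked example

```python
from growthtoggle.cell_cycle import CellCycleParams, dosage_ratio, best_balanced_design
from growthtoggle.deterministic import DeterministicState, relax_to_steady_state, protein_ratio
from growthtoggle.model_params import RateConstants
from growthtoggle.stochastic import SimulationConfig, run_ensemble

# dosage: the ori:ter copy ratio doubles when T halves
print(dosage_ratio(0.0, 1.0, CellCycleParams(T=40.0)))   # 2.0
print(dosage_ratio(0.0, 1.0, CellCycleParams(T=20.0)))   # 4.0

# uncoupled genes (r_g = 0): expression follows dosage
rc0 = RateConstants(r_g_scale=0.0)
empty = DeterministicState(1, 1, 0, 0, 0, 0, 0, 0)
for T in (20.0, 120.0):
    state, _ = relax_to_steady_state(empty, rc0, CellCycleParams(T=T))
    print(T, round(protein_ratio(state), 3))             # 20 2.0 / 120 0.643

# stochastic ensemble at the same settings (200 lineages, 40 h each)
cfg = SimulationConfig(T=120.0, rc=rc0, t_end_h=40.0, burn_in_h=10.0,
                       seed=100, record_dt_s=600.0)
ens = run_ensemble(cfg, 200)
print(round(ens.R_protein_birth, 3))                     # ~0.645 ± 0.006

# where to put the second gene so the toggle balances at a chosen T
print(best_balanced_design(120.0))  # BalancedDesign(ratio=0.8, L2=0.966)
```

The printed ratios are the population-average total protein content
(monomers + 2·dimers) of the *ori* gene over the *ter* gene: 2.0 at
T = 20 min and 0.643 at T = 120 min when repression is off, i.e. a
three-fold swing from dosage alone.  With strong repression
(`r_g_scale=0.0035`) the same sweep spans more than three orders of
magnitude, because the bistable toggle snaps into the state favoured by
the dosage imbalance.

From the shell:

```sh
growthtoggle design --T 20                 # {"T": 20.0, "ratio": 0.25, "L2": 1.0}
growthtoggle dosage --T 40 --L 0
growthtoggle simulate --T 40 --rg 0.002 --t-end-hours 10 --seed 1 --out-dir run1
growthtoggle mfpt --rg 0.002 --T 40 --min-transitions 100 --seed 1
```

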