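# pmfsim

Kinetic/thermodynamic simulation of the chloroplast light reactions with a
variable ATP synthase c-ring, built to study how the rotor's c-subunit
stoichiometry shapes proton-motive-force (pmf) storage, lumen pH,
photosynthetic control, qE quenching, and the singlet-oxygen cost of storing
pmf as an electric field.

The model couples:

* **Thermodynamics** — `pmf = Δψ + z·ΔpH` with `z = ln(10)·R·T/F`; the
  H⁺/ATP ratio is `c_subunits / 3`, and the dark-equilibrium pmf is
  `ΔG_ATP / (H⁺/ATP · F)` (~89 mV for c₁₄, ~155 mV for c₈ at 40 kJ/mol).
* **Kinetics** — a stiff ODE system per mol PSII: light-driven PSII/PSI
  turnover, a plastoquinone pool, pH-throttled PQH₂ oxidation at b₆f
  (ten-fold from pH 7.5 to 5.5), an ohmic ATP synthase around the ring's
  equilibrium pmf, counter-ion re-partitioning of Δψ into ΔpH, PsbS/
  zeaxanthin qE, and S₂/S₃Q_A⁻ charge recombination whose rate rises one
  decade per 0.06 V of Δψ, with a fixed ¹O₂ yield per event.
* **Light protocols** — static, sinusoidal and square-wave regimes that can
  deliver identical integrated photon dose.

Several rate constants and membrane constants (`k_r`, `g_atpase`,
`c_membrane`, `beta_lumen`, `g_ion`, …) are **calibrations**, not measured
values; they are documented on `KineticParams` and fully overridable from
the configuration document.

## CLI

```sh
# dark-equilibrium table (pmf, Δψ/ΔpH partition, lumen pH, b6f rate, qE)
pmfsim equilibrium --out results/

# write the default experiment specs (three static intensities; three
# equal-dose 1-h regimes)
pmfsim fixtures --out fixtures/

# run a full ring x protocol sweep: per-run trajectory CSV + summary JSON
# + a combined comparison table
pmfsim simulate --config fixtures/equal_dose.yaml --out results/
```

Exit codes: `0` success, `1` at least one simulation failed, `2`
configuration error. Configuration is one YAML document with `rings`,
`fraction_psi`, `thermo`, `kinetics`, `protocols` and `output` sections;
unknown keys are rejected with the offending key path.

Python API:

```python
from pmfsim import CRingConfig, ThermoParams, KineticParams, make_static, run

traj = run(CRingConfig(14), ThermoParams(), KineticParams(),
           make_static(1000.0, 600.0))
traj.summary()          # cumulative LEF, cumulative 1O2, min lumen pH, ...
traj.to_frame()         # full time series incl. deltas from dark values
```

## Layout

```
src/pmfsim/thermo.py     closed-form pmf & ATP synthase thermodynamics
src/pmfsim/kinetics.py   ODE right-hand side, rate laws, parameters
src/pmfsim/light.py      static / sinusoidal / square-wave protocols
src/pmfsim/simulate.py   dark equilibration, stiff integration, Trajectory
src/pmfsim/config.py     experiment spec (YAML), strict validation
src/pmfsim/cli.py        equilibrium / simulate / fixtures commands
tests/                   unit, property and acceptance suites
```
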