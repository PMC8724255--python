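# eqspec

Multi-component chemical-equilibrium engine: Newton-Raphson speciation over
mass-action mass balances, van't Hoff temperature dependence of formation
constants, potentiometric-titration simulation, and global Newton-Gauss
fitting of reaction enthalpies/entropies with standard errors and
parameter-correlation diagnostics.

The package ships a complete executable encoding of a supramolecular
pyrophosphate-sensing network (a Zn(II)–dipicolylamine/phenylboronic-acid
receptor, an alizarin-type dye, and pyrophosphate in water): ten separable
sub-mechanism models, the full assembly model, the generating thermodynamic
parameter tables, named parameter-recovery experiment designs, and a
speciation-vs-pH prediction workflow.

## Layout

| module               | contents                                                              |
|----------------------|-----------------------------------------------------------------------|
| `eqspec.model`       | components, species stoichiometry, van't Hoff thermodynamics, model file I/O |
| `eqspec.speciation`  | damped Newton-Raphson mass-balance solver (log-concentration domain)  |
| `eqspec.titration`   | titration protocols, dilution trajectories, simulation, noise, augmentation, dataset I/O |
| `eqspec.fitting`     | Newton-Gauss least squares, σ_P/σ_R statistics, correlation diagnostics |
| `eqspec.sensor`      | built-in sensing models, parameter tables, recovery designs, prediction |
| `eqspec.cli`         | `eqspec` command-line interface                                       |

Built-in data assets (plain text) live in `src/eqspec/data/`:
`sensor_species.csv` (stoichiometry + generating ΔH/ΔS per species) and
`designs.yaml` (titration conditions, free parameters, noise level per
recovery design).

## Quick start

```python
import numpy as np
import eqspec as eq

# speciation of the full sensing model at fixed totals
model = eq.make_submodel("full")
state = eq.solve_free_concentrations(
    model, {"ARS": 0.04, "1": 0.02, "PPi": 0.02, "Zn": 0.02, "H": 0.05}, 308.0)
print(eq.ph_of(state), state.conc_of("H4ARS1ZnPPia"))

# end-to-end parameter recovery: simulate at the generating truth, add
# seeded pH noise (SD 0.002), fit ΔH/ΔS globally across temperatures
res = eq.run_recovery("ars_protonation", seed=1)
print(res.report)

# species profiles over an imposed pH grid
prof = eq.predict_speciation_vs_ph(
    model, {"ARS": 0.04, "1": 0.02, "PPi": 0.02, "Zn": 0.02},
    T=308.0, ph_grid=np.arange(5, 11, 0.02))
print(eq.peak_ph(prof, "H4ARS1ZnPPia"))
```

## CLI

```bash
eqspec simulate proto.yaml --model ars_protonation --out curve.csv --profiles conc.csv
eqspec fit curves.csv --model model.csv --free HARS,H2ARS --report fit.csv
eqspec recover ternary --seed 7 --report report.csv
eqspec predict --model full --totals '{"ARS":0.04,"1":0.02,"PPi":0.02,"Zn":0.02}' \
       -T 308 --ph-range 5:11 --peak-of H4ARS1ZnPPia
```

Protocol files are small YAML documents (`label`, `T`, `v0`, `initial`,
`titrant`, `n`/`vstep` or explicit `aliquots`); model files are CSV tables
with one integer column per component plus `dH`/`dS` (or a fixed `lnb`) and
a `free` flag; datasets are delimited text with per-block headers.

## Notes on the numerics

* Formation constants are held as ln β; ln β(T) = −ΔH/(RT) + ΔS/R with
  R = 8.31 J/(mol·K). Water autoprotolysis is a pseudo-species with proton
  coefficient −1 and fixed thermodynamics (pKw ≈ 14.0 at 298 K by default).
* The speciation solver iterates on log-concentrations; the mass-balance map
  is the gradient of a convex potential, so damped Newton steps converge
  from cold starts, and titration curves warm-start consecutive points.
* Hydroxide enters the proton balance as −[OH⁻]; negative proton totals
  (excess strong base) are legal inputs.
* The fit driver uses Marquardt-damped Gauss-Newton on scaled parameters
  (ΔH in kJ/mol); σ_P comes from the undamped (JᵀJ)⁻¹ at the optimum and
  structurally degenerate parameter sets are reported as ±1 correlations.
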