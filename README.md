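# stemdem

Bonded-sphere discrete-element modelling and calibration of shrub-branch
fracture mechanics.

Woody shrub branches (the motivating material is *Caragana korshinskii* Kom.,
harvested for fodder) are hard and tough, and designing crushing machinery
for them requires a mechanical model of how a stem deforms and fractures
under compression, bending, shear and tension. `stemdem` implements the
standard bonded-particle route to that model, plus the full statistical
pipeline used to calibrate it, for researchers in agricultural-machinery
design and plant biomechanics:

- **Stem construction** — a circular cross-section is packed with equal
  spheres (radius 0.5 mm by default) on a square lattice and stacked axially
  into a cylinder; one isotropic particle type represents epidermis, xylem
  and pith.
- **Mechanics** — Hertz–Mindlin contact plus beam-like bonds between
  neighbouring spheres. Each bond of radius `R_ab` (area `A_b = πR_ab²`,
  polar moment `J = πR_ab⁴/2`) accumulates force and torque incrementally,

      dF_n = −v_n K_n A_b dt,   dF_t = −v_t K_s A_b dt,
      dM_n = −ω_n K_s J dt,     dM_s = −½ ω_t K_n J dt,

  and ruptures permanently when `−F_n/A_b + 2|M_s|R_ab/J > σ_max` or
  `|F_t|/A_b + |M_n|R_ab/J > τ_max`.
- **Virtual tests** — rigid-tool compression, three-point bending,
  double-support cutting and gripped tension, reduced to force–displacement
  curves, peak forces and elastic slopes.
- **Calibration** — Plackett–Burman screening of eleven contact/bond
  factors, steepest ascent, a 27-run face-centred central composite design
  with a second-order response surface (`F_max = β₀ + Σβᵢxᵢ + Σβᵢⱼxᵢxⱼ +
  Σβᵢᵢxᵢ²` in coded units) and ANOVA, and constrained optimisation to the
  laboratory mean compression force (1553.51 N).
- **GA-BP-GA surrogate** — a genetic-algorithm-initialised 4–S–1 neural
  network maps `(K_n, K_s, τ_m, R_ab)` to peak force; a second GA inverts
  the trained net to the target force.

The published measurement and calibration tables ship as CSV fixtures
(`stemdem.fixture("table1")` … `"table8"`), printed anomalies flagged, so
every statistical step can be re-run against the original numbers.

## Worked example

Fit the response surface to the published 27-run design, optimise it to the
laboratory mean force, then train and invert the surrogate:

```python
import stemdem as sd

design = sd.datasets.table6_design()          # 27-run CCD with responses
res = sd.fit_quadratic(design)
print(res.summary())

problem = sd.optimize_to_target(res, sd.TargetOptimization(
    target_force=1553.51,
    bounds={"K_n": (1e10, 5e10), "K_s": (1e10, 5e10),
            "tau_m": (1e7, 1e10), "R_ab": (0.6, 1.0)},
    seed=0))
print({k: f"{v:.3g}" for k, v in problem.solution.items()},
      f"predicted {problem.predicted:.2f} N")

ts = sd.training_set_from_quadratic_grid(res.quadratic)
net, report = sd.train_bpnn(ts, sd.SurrogateConfig(hidden_nodes=13, seed=0))
inv = sd.invert_surrogate(net, 1553.51)
print(f"test R = {report['test_r']:.4f} after {report['epochs']} epochs")
print("GA-BP-GA optimum:",
      {n: f"{v:.3g}" for n, v in zip(["K_n","K_s","tau_m","R_ab"], inv["params"])},
      f"-> {inv['predicted']:.2f} N")
```

prints

```
Second-order response surface (coded units)
==============================================
intercept     1317.76
K_n            359.86
K_s            100.91
tau_m           95.16
R_ab           494.70
K_n:K_s         22.99
K_n:tau_m      134.24
K_n:R_ab       210.85
K_s:tau_m      -48.36
K_s:R_ab       112.04
tau_m:R_ab      27.73
K_n^2          -59.23
K_s^2         -382.79
tau_m^2        -63.51
R_ab^2          84.08
----------------------------------------------
R^2 = 0.9652   adj R^2 = 0.9247
model F = 23.80 on (14, 12) df   CV = 16.18%
{'K_n': '2.7e+10', 'K_s': '3.85e+10', 'tau_m': '6.91e+09', 'R_ab': '0.909'} predicted 1553.51 N
test R = 0.9978 after 3 epochs
GA-BP-GA optimum: {'K_n': '3.31e+10', 'K_s': '4.58e+10', 'tau_m': '7.67e+08', 'R_ab': '0.935'} -> 1553.49 N
```

The fitted surface reproduces the published regression equation and fit
statistics; the optimiser finds bond-parameter combinations whose predicted
peak compression force matches the laboratory mean to well under 0.1 N, and
the surrogate net (trained to MSE ≤ 10⁻³ in a few epochs) inverts to the
same target within hundredths of a percent. The quadratic surface is flat
near its target contour, so matching combinations are not unique — the GA
solution differs from the published one, which is expected.

Simulations run the same way from Python
(`sd.run_test(model, sd.LoadCase.bending(), sd.CALIBRATED_OPTIMUM_BOND)`) or from
the shell:

```sh
stemdem build --diameter 9.3 --length 90 --particle-radius 0.5 --out model.csv
stemdem test --case compression --outdir run1/
stemdem calibrate ccd --responses runs.csv --target 1553.51 --out anova.csv
stemdem surrogate train --data samples.csv --out net.json
stemdem fixtures table6
```

One caveat worth knowing before trusting fracture predictions: with the
published optimal parameters the printed rupture criteria are unreachable at
laboratory displacement scales, so simulated force-curve collapse under
radial compression comes from lattice snap-through, not bond rupture; see
`docs/methods.md` for the quantitative analysis.

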