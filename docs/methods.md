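# Methods

`stemdem` models woody shrub branches as bonded assemblies of equal spheres
and calibrates the bond law against laboratory peak forces.  This note
records the model, its numerical treatment, the calibration statistics, the
design choices that were genuinely open, and the limits of what the tests
demonstrate.

## Geometry

A branch segment is a circular cylinder.  The cross-section is packed on a
**square lattice** with pitch equal to one particle diameter, seeded at the
section centre; a lattice point is kept only when its distance from the
centre is at most `section_radius − particle_radius`, so every sphere lies
fully inside the contour.  Because exact tangency to the contour is
impossible on a lattice, the working model diameter (9.30 mm) is slightly
below the measured mean branch diameter (9.50 mm).  Cross-sections are
stacked axially without gaps (axial pitch = particle diameter, no stagger).
The default particle radius is 0.5 mm, half the 1 mm meshing pitch used to
place sphere centres.  Epidermis, cortex, xylem and pith are deliberately
collapsed into a single isotropic particle type; the material is treated as
isotropic because the loading of interest is radial.

A hexagonal packing would be denser and less anisotropic; the square lattice
is used because it is the straightforward reading of grid-based filling, and
its artefacts are discussed under *Limitations*.

## Bond mechanics

Particles within a centre distance of `2 R_ab` of each other are glued by a
virtual cylindrical bond of radius `R_ab`, section area `A_b = π R_ab²` and
polar moment `J = π R_ab⁴ / 2`.  The bond search deliberately reaches beyond
physical contact: calibrated bond radii (0.6–1.0 mm) exceed the 0.5 mm
particle radius, so bonds connect axial, lateral and diagonal neighbours.

Each bond accumulates force and torque incrementally from the relative
velocity of its two particles at the bond midpoint (v: translational,
ω: angular; n and t: normal and tangential components):

    dF_n = −v_n K_n A_b dt        dF_t = −v_t K_s A_b dt
    dM_n = −ω_n K_s J dt          dM_s = −(1/2) ω_t K_n J dt

Sign convention: `v_n > 0` means separation, so a stretched bond carries
`F_n < 0` and `−F_n/A_b` is the positive tensile stress.  The tangential
force and bending torque are re-projected into the current contact plane
each step (small-rotation co-rotation).  A bond breaks permanently when

    −F_n/A_b + 2|M_s| R_ab/J  >  σ_max     (normal criterion)
     |F_t|/A_b + |M_n| R_ab/J  >  τ_max     (shear criterion)

Torque and tangential contributions enter as magnitudes: the printed signs
of these criteria are inconsistent under symmetric loading, and magnitudes
are the only reading under which a symmetric load state gives a symmetric
rupture decision.  `R` in the criteria is taken to be the bond radius
`R_ab`, consistent with the bonded-beam analogy.  The calibration varied the
critical *shear* stress while holding the normal threshold at 5.005 GPa (the
midpoint of its screening interval), so the optimised 6.57×10⁸ Pa value is
exposed as `tau_max`.

In parallel with bonds, overlapping spheres (and sphere–tool pairs) interact
through Hertz–Mindlin contact: Hertzian normal elasticity
`F = (4/3) E* √R* δ^{3/2}` with restitution-consistent viscous damping
(damping ratio `−ln e / √(ln²e + π²)`), a regularised Coulomb tangential
force capped at `μ_s |F_n|`, and a rolling-resistance torque bounded by
`μ_r |F_n| R*`.  The tangential regularisation (`tanh(|v_t|/v_reg)`,
`v_reg = 1 mm/s`) behaves as a stiff viscosity near sticking; both it and
the rolling torque are additionally capped at one tenth of the explicit
step's viscous stability bound (`0.1 m |v_t| / dt`), without which large
normal forces make the friction term numerically unstable.

## Integration

Semi-implicit (symplectic) Euler on the Newton–Euler equations, with Cundall
local damping: each force/torque component is reduced by
`damping × |component|` opposing the velocity sign.  At equilibrium the net
force vanishes, so this damping does not bias quasi-static responses; the
default coefficient is 0.05, and post-fracture regimes (rupture avalanches
release stored contact energy violently) are best run at 0.5–0.7.

The default time step is `0.2 × min(Rayleigh bound, bond bound)` with the
Rayleigh surface-wave bound `π r √(ρ/G) / (0.163 ν + 0.877)` and the bond
oscillation bound `√(m / (K_n A_b))` (≈ 4.2×10⁻⁷ s for the calibrated
parameters).  Neighbour lists (scipy cKDTree, skin 0.4 r) are rebuilt
between kernel chunks sized so no particle can cross half the skin within a
chunk.  Instability (NaN or particle speeds beyond 100 m/s) aborts with a
diagnostic rather than returning garbage.

Energy bookkeeping (kinetic + bond strain + Hertz contact strain) backs two
run-time guards: a quasi-staticity flag (kinetic energy must stay below 1%
of accumulated strain energy wherever meaningful strain energy exists) and
the dissipation property test.

## Virtual tests

Four load cases mirror the laboratory programme, all driven at a scaled
speed (default 0.05 m/s; the physical 10 mm/min is unreachable for an
explicit integrator) with the quasi-staticity flag recorded per run:

- **compression** — 20 mm segment radially squeezed between flat platens
  (the laboratory specimen length is not reported; 20 mm matches the
  millimetre-scale rupture displacements of the calibration);
- **bending** — three-point bending, 60 mm span on a 90 mm specimen, rigid
  5 mm-radius cylinders as supports and indenter;
- **shear** — double-support cutting: a 1.5 mm blade (its 150° wedge edge
  modelled as the tangent cylinder of radius = half thickness) descending
  into a slotted support whose gap is blade thickness + 2 mm clearance;
- **tension** — 10 mm of particles at each end kinematically driven as
  grips.

Reaction forces on the moving tool are averaged over each 0.01 mm sampling
interval of tool travel.  Curve reduction: global peak with smallest-travel
tie-break; elastic slope by ordinary least squares on the pre-peak samples
within 20–80% of the peak force; relative errors use the laboratory
reference as denominator by default (the measured-denominator convention is
available, since one published tensile comparison is only consistent with
it).

## Calibration statistics

- **Screening**: the classical 20-run Plackett–Burman array (cyclic
  generator plus the all-minus run) over six measured contact coefficients
  and five bond parameters, plus one centre point.  Effects are high–low
  contrast means; Pareto ordering uses the t statistics of the saturated
  first-order regression.  Applied to the published response table this
  reproduces the published ranking (K_n, τ_m, K_s, R_ab leading).
- **Steepest ascent**: bookkeeping of the relative error
  `100 |F_max − F_ave| / F_ave` against the laboratory mean (1553.51 N).
- **Response surface**: face-centred central composite design for four
  factors (16 corners + 8 axial points at ±1 + 3 centre replicates = 27
  runs; the design table's three centre rows override the text's "five
  centroids").  The full second-order model is fitted by OLS in coded
  units (statsmodels), exposed as `ResponseSurface(...).fit()` returning a
  results object with coefficients, partial (Type III) ANOVA with
  lack-of-fit vs pure error from the centre replicates, R², adjusted R²,
  CV and a text `summary()`.  Refitting the published 27 responses
  reproduces the published equation and headline statistics (intercept
  1317.76 N, R² 0.9652, adjusted R² 0.9247, model F 23.8).
- **Target inversion**: multi-start L-BFGS-B minimisation of
  `(prediction − target)²` over the constraint box, deterministic for a
  given seed.  Note: the *published* surface-optimisation solution decodes
  through the published equation to ≈1360 N, not the 1553.51 N target; the
  toolkit's optimiser finds in-box solutions matching the target to
  <0.1 N, and the discrepancy is recorded in a test rather than hidden.

Factor coding ranges: K_n, K_s ∈ [1, 5]×10¹⁰ N·m⁻³, τ_m ∈ [10⁸, 10¹⁰] Pa
(centre 5.05×10⁹, implied by the ascent outcome), R_ab ∈ [0.6, 1.0] mm.

## Surrogate inversion (GA-BP-GA)

A 4–S–1 feed-forward net (tansig hidden layer, linear output) maps
(K_n, K_s, τ_m, R_ab) to peak force.  Inputs and output are normalised to
[−1, 1] over the whole data set.  Hidden-layer size follows
`S = ceil(√(n_in + n_out)) + c`, c = 1…10, giving candidates 4–13 (the
rounded form of the usual rule yields 3–12 and cannot reproduce the stated
range); `select_hidden_nodes` trains each candidate five times and takes the
lowest mean validation MSE.

Training is GA-then-gradient: a real-coded GA (population 200, 200
generations, normalised geometric ranking selection with probability-of-best
0.09, arithmetic crossover at rate 0.8, single-gene uniform mutation at rate
0.2) minimises training MSE over the flat weight vector, then the gradient
trainer refines the best individual to a target MSE of 0.001 within 200
epochs.  The default trainer is **Levenberg–Marquardt** with the analytic
Jacobian of the small net: plain gradient descent with momentum (retained
as `trainer="gdm"`) cannot reach the required accuracy in 200 epochs at
learning rate 0.001, whereas LM converges in 2–3 epochs — which is also the
convergence behaviour reported for the reference workflow.  On noiseless
responses of the fitted quadratic over the 3⁴ coded grid (81 samples,
70/30 split), test-set correlation exceeds 0.99 at S = 13 for ~9 of 10
seeds.

The second GA inverts the trained net to the 1553.51 N target over the
physical box (selection pressure 0.8, arithmetic crossover at rate 1.0 —
the sensible reading of a printed "crossover coefficient 2" — mutation 0.2,
100 generations); inversion residuals are far below 1%, and end-to-end
recovery through a known monotone truth function lands within 2% of target.
Where only run means are available, the 81-sample training set can also be
synthesised as 27 CCD runs × 3 repeats with Gaussian noise at the
pure-error standard deviation (√33053 ≈ 182 N).

## The rupture-scale inconsistency

A result every user should know: with the calibrated optimum
(K_n = 3.67×10¹⁰ N·m⁻³, σ_max = 5.005×10⁹ Pa, τ_max = 6.57×10⁸ Pa,
R_ab = 0.78 mm) the rupture criteria above are **unreachable at laboratory
displacement scales**.  The per-bond critical tensile displacement is
σ_max/K_n ≈ 0.14 m, the critical tangential displacement τ_max/K_s ≈ 19 mm,
and the critical relative rotations σ_max/(K_n R_ab) ≈ 175 rad and
τ_max/(K_s R_ab) ≈ 25 rad.  In a simulated 9.3×20 mm radial compression to
4 mm, acting bond stresses peak near 3×10⁶ Pa — two orders of magnitude
below the thresholds — and no bond breaks.  The compression curve still
shows the characteristic three-phase shape (elastic rise to ≈3 kN, a >90%
collapse near 0.8 mm, compaction re-rise), but the collapse is a snap-through
of the square-lattice columns, not bond rupture.  Since the reference
simulations report fracture at ≈2 mm with these same parameter values, the
commercial solver they used must apply internal semantics different from the
printed equations.  This package implements the printed equations; rupture
behaves exactly as specified (verified against closed forms at reachable
thresholds, e.g. σ_max ≲ 10⁷ Pa, where rupture-coincident force drops are
demonstrated), and the acceptance check tying the collapse of the
calibrated-parameter curve to bond breakage is left failing, deliberately,
as a faithful record of this inconsistency.

## What the tests do and do not show

The synthetic inputs are exact closed-form oracles (two-particle bond
kinematics, series-spring cantilever, Hertz closed form, quadratic response
surfaces, monotone truth functions) plus the published design/response
tables shipped verbatim as fixtures (printed anomalies flagged, never
corrected).  Passing tests therefore demonstrate that the mechanics,
statistics and optimisation are implemented correctly and reproduce the
published derived quantities — they do not demonstrate that the bonded
square-lattice model predicts real branch fracture forces; that comparison
requires the full-scale runs (`scripts/full_scale_compression.py`) and,
per the section above, different rupture thresholds than the printed
optimum.

## Numerical choices and problem sizes

Default test/acceptance problem sizes are chosen for desktop runtimes:
scaled compression on a 9.3×20 mm specimen (1140 particles, ~8500 bonds,
2.5 mm travel, ≈10⁵ steps, ~1.5 min), property oracles on 2–15 particle
chains, surrogate loops on 81-sample sets.  The kernel is a numba-compiled
scalar loop; first use costs a few seconds of JIT compilation (cached).
Tool-force curves are interval averages; elastic-slope fits skip the
contact-establishment toe.  Ties in peak extraction break toward smaller
displacement; degenerate inputs (empty curves, zero travel, constant
normalisation columns, rank-deficient designs) raise explicit errors.

## Limitations

- Square-lattice packing introduces preferred planes; its snap-through under
  radial compression is a packing artefact of physical appearance (force
  drop) but not of physical origin (no fracture).
- No tapered stems, no epidermis/xylem layering, no moisture dependence.
- Memoryless regularised friction (no tangential contact history), adequate
  for quasi-static loading, imprecise for oscillatory micro-slip.
- The loading rate is scaled up ~300× from the laboratory rate; the
  quasi-staticity flag guards the interpretation but transient effects near
  collapse are inherently dynamic.
- Fracture-morphology comparison is out of scope.
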