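# Methods

## Model

The package couples three standard pieces of photobioreactor engineering
into one steady-state analysis.

**Light field.** A flat culture of homogeneous biomass *X* attenuates light
according to Lambert–Beer, I(z) = I₀·exp(−k_a·X·z). No scattering or
two-flux correction is applied; the optical depth k_a·X·z is dimensionless
by construction (m² g⁻¹ · g m⁻³ · m).

**Kinetics.** The gross specific growth rate is a reparameterized Haldane
law, μ(I) = μ_max·I / (I + K_I·(I/I_opt − 1)²). The parameterization is
chosen so that the curve attains its maximum μ_max exactly at I = I_opt,
which makes both parameters directly interpretable. A first-order decay
k_d accounts for respiration and maintenance. Nutrients and CO₂ are assumed
in excess; temperature and pH effects are outside scope.

**Reactor balance.** The reactor is treated as a CSTR: concentrations are
homogeneous while light is not, so the volumetric growth rate is averaged
over the depth before entering the balance dX/dt = −X/τ + r̄_x(X). Steady
states solve μ̄(X) = 1/τ + k_d, where μ̄ is the depth-averaged gross
specific rate.

### Parameters

| symbol | meaning | units | bundled values |
|---|---|---|---|
| μ_max | maximum specific growth rate | d⁻¹ | 1.8–2.1 |
| K_I | half-saturation of the light response | µmol m⁻² s⁻¹ | 110 (all thicknesses) |
| I_opt | irradiance of maximal growth | µmol m⁻² s⁻¹ | 50–405, grows with light path |
| k_d | decay (respiration/maintenance) rate | d⁻¹ | 0.45 (all thicknesses) |
| k_a | mass extinction coefficient | m² g⁻¹ | 0.098–0.9, falls with light path |

The bundled per-thickness sets (2/5/8/15/35 mm, *Tetradesmus obliquus*)
are fitted values; the thickness dependence of I_opt and k_a is the
package's central reporting output (`report_thickness_trends`, with I_opt
conventionally normalized on 413 µmol m⁻² s⁻¹).

## Numerical choices

**Depth average.** `depth_averaged_rate` defaults to adaptive quadrature
(scipy `quad`, relative tolerance 1e−10). A closed form obtained by the
substitution u = I(z) — the integrand becomes 1/(quadratic in u), an
arctan antiderivative whenever 4·K_I/I_opt > 1, which holds for every
bundled set — is the fast vectorized path used by the steady-state solvers;
the two are cross-checked against a 1e5-point Simpson oracle to 1e−8
relative in the tests. For optical depths below 1e−9 the average collapses
to the midpoint value to avoid catastrophic cancellation.

**Steady states.** μ̄(X) is unimodal in X under Haldane inhibition, so
μ̄(X) = 1/τ + k_d has at most two positive roots. The solver scans a
geometric grid on X ∈ [1e−3, 1e5] g m⁻³ (configurable), brackets sign
changes and refines by Brent's method to 1e−10 relative. All roots are
reported; the largest is labelled stable (μ̄ is locally decreasing there —
the attractor reached from a healthy inoculum). Washout is reported when no
positive root exists, which is guaranteed whenever 1/τ + k_d ≥ μ_max; roots
that would fall below the scan floor are reported as washout rather than as
tiny concentrations, avoiding spurious numerical roots. A batched variant
(`steady_state_batch`) solves many operating points at once with a
vectorized log-space bisection whose iteration count follows from the
geometric grid step; it is the hot path of the likelihood.

**Transients.** The dynamic balance is integrated with LSODA and
non-negativity clamping; large k_a·X makes the right-hand side sharply
varying at high X, so a stiff-capable method is used. Terminal agreement
with the steady-state solver to 0.1% is an acceptance test.

**Degenerate inputs.** I₀ = 0 gives μ̄ = 0 (dark reactor, washout);
X = 0 is always an equilibrium; the photic depth at X = 0 is ±∞ with the
sign of ln(I₀/I_opt), since with no biomass there is no attenuation and the
photic zone is either everything or nothing. At I₀ = 0 the photic depth is
the −∞ sentinel.

## Estimation

Per-thickness maximum likelihood with (K_I, k_d) fixed at (110, 0.45) and
(μ_max, I_opt, k_a) free, reproducing the standard scheme for this kind of
dataset: a unique parameter set across thicknesses is not attainable, so
each light path is fitted separately.

**Noise model.** Default is constant-CV Gaussian — σ proportional to the
predicted concentration, floored at 10 g m⁻³ so washout predictions retain
finite variance. Cell-count error scales with magnitude, making relative
noise the natural default; a homoscedastic option (`"const"`, equivalent to
least squares) is provided. The scale parameter is profiled out
analytically, so the optimizer sees a concentrated NLL in the three kinetic
parameters only. Washout observations are treated as measurements of 0 with
the floor σ, not dropped.

**Optimization.** The concentrated NLL is multimodal and exactly flat on
washout plateaus (all predictions zero), where finite-difference gradients
vanish. The search is therefore staged: a seeded Latin-hypercube scan of
32× the multistart count ranks candidate basins in log-parameter space; the
best 8 points get bounded Nelder–Mead polishes; the incumbent receives a
final tighter polish. Standard errors come from the observed-information
(finite-difference Hessian) approximation at the optimum. Identical
(table, spec, seed) inputs give bit-identical estimates; per-thickness
child seeds derive from the global seed and the thickness via a
SeedSequence, so blocks are independently reproducible.

**Bounds.** μ_max ∈ [0.1, 10] d⁻¹, I_opt ∈ [5, 2000] µmol m⁻² s⁻¹,
k_a ∈ [0.01, 5] m² g⁻¹ — wide enough to contain every bundled value with
an order of magnitude to spare.

## Synthetic data

The generator emulates the five-thickness experimental envelope:
2 mm (τ = 1.5 d), 5 mm (1 d), 8 mm (1 and 2 d), 15 mm (1.43 and 2.5 d),
35 mm (1.05 d); irradiance grids of zero plus eight log-spaced levels from
20 µmol m⁻² s⁻¹ up to 500 (thin, ≤ 8 mm) or 1200 (thick) µmol m⁻² s⁻¹;
three replicates per cell. Log spacing resolves the photolimited rise and
the inhibited fall with few points; 20 µmol m⁻² s⁻¹ is a realistic lowest
non-zero lamp setting.

Noise is multiplicative Gaussian with a chosen CV (default 5%), truncated
at zero, placed directly on the steady-state mass concentration; washout
cells yield zero plus floor noise. What real data have and this generator
does not: the cell-counting stage and the count-to-mass conversion,
transient acclimation, biofouling and contamination failure modes, and
day-to-day drift. Passing recovery tests therefore demonstrate estimator
correctness and identifiability under the assumed noise structure, not
robustness to those real-world effects.

## Known limitations

* **I_opt identifiability at 35 mm.** Under the default design the 35 mm
  steady-state curve is still rising at the 1200 µmol m⁻² s⁻¹ grid edge, so
  I_opt is constrained only through the curvature of the saturated branch.
  At 5% CV the ML estimator's sampling spread for the 35 mm I_opt has a
  median relative error of roughly 15% over seeded replications (all other
  parameter/thickness combinations recover within 10%, most within a few
  percent). The estimator is verified to reach the global optimum of the
  likelihood; the spread is an information limit of the design, and would
  shrink with irradiance levels beyond the plotted range or more
  replicates.
* The 15 and 35 mm duty-cycle value of 0.2 reported for such systems
  depends on the specific (I₀, X) pair used, which is not fixed by the
  analysis; the package computes φ for any supplied operating point but
  pins no particular thick-reactor value.
* Steady-state multiplicity: the largest-root ("healthy inoculum")
  convention is a modelling choice; the low branch is reachable from small
  inocula, as the transient simulator shows.
* Lambert–Beer with a single fitted k_a is known to misrepresent very thin
  light paths — that is precisely the thickness trend the analysis
  quantifies — so extrapolating a fitted set to a different thickness is
  unsupported.

## Problem sizes used in the tests

Quadrature fidelity is checked on 1000 randomized draws against a
1e5-point Simpson rule; dynamics/steady-state consistency on 50 randomized
operating points; parameter recovery on 20 seeded replications of the full
five-thickness design (about 190 observations each), chosen to estimate
median recovery error stably while keeping the suite comfortably
single-core.
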