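# Methods

This note records the model equations as implemented, the numerical
choices, what the synthetic-data generator does and does not emulate, and
the design decisions taken where the problem was genuinely open.

## Water flow

The column is 20 cm deep and 15.4 cm in diameter, split into two horizons
(0 to −10 cm, −10 to −20 cm) with van Genuchten–Mualem hydraulics

θ(h) = θr + (θs − θr)·[1 + (α|h|)^n]^(−m),  m = 1 − 1/n,
K(h) = Ks·Se^0.5·[1 − (1 − Se^{1/m})^m]²,

(Mualem connectivity exponent 0.5).  Fixed values: θr = 0.18, θs = 0.51,
Ks = 70 cm/day in both horizons; α and n per horizon are calibrated
(medians 0.013/2.07 and 0.022/2.45).

Root water uptake is S(z,t) = α_F(h, Tp)·b(z,t)·Tp with the
piecewise-linear Feddes stress α_F (thresholds −15, −30, −300/−500,
−8000 cm; the P2 threshold interpolates between its high- and
low-demand values over Tp ∈ [0.1, 0.5] cm/day, the flow-solver defaults).
The root distribution b(z,t) uses a rooted depth growing logistically
(rate 0.2/day, 2 cm initial, 20 cm asymptote) with density decreasing
linearly to the rooting front and renormalized on the grid at every step —
the shape is our choice; only the logistic rate is a fitted quantity.

Evapotranspiration demand is partitioned by Beer-law extinction,
Tp = ET·(1 − e^{−0.463·LAI}); the partition rule was an open choice and the
soil-cover-fraction variant would be equally defensible.

### Numerics

Mass-conservative mixed-form Picard iteration (storage expanded as
θ^m − θ^n + C(h^m)(h^{m+1} − h^m)) on a control-volume grid of 100
elements refined geometrically to a 0.05 cm surface element.  Arithmetic
face conductivities; Thomas solver; the whole time loop is numba-compiled.
Hydraulic functions are evaluated from per-horizon lookup tables uniform
in pF = log10|h| (800 points over pF −3…7.5, rebuilt per parameter set);
the interpolation error is far below the spatial discretization error and
removes the power-law evaluations from the hot path.

Convergence uses a mixed criterion |Δh| < tol_abs + tol_rel·|h| with
tol_abs = 10⁻⁴ cm and tol_rel = 10⁻⁴.  A purely absolute 10⁻⁴ cm test at
dry heads (|h| ~ 10³ cm) would demand ~10⁻⁷ relative precision — far
beyond the discretization error — and inflates iteration counts several
fold; the relative term bounds the head error at 0.01%.  Time stepping is
adaptive: grow 1.5× while iterations stay below half the maximum, shrink
on failure with a damped regrowth cap, restart small when a day's
irrigation forcing switches (a fresh wetting front), and halve on
non-convergence down to dt_min.  Calibration runs additionally carry a
total step budget; a parameter set that exhausts it (pathological corners
such as n → 1.1 with α → 0.1) is reported as a solver failure, which the
likelihood maps to −∞ (a rejected sample).

Boundary handling: atmospheric flux at the surface switches to a Dirichlet
head at h = −10⁵ cm when evaporation dries the surface out, and to h = 0
when infiltration would pond (excess recorded; irrigation rates here never
produce it).  The bottom seepage face is zero-flux while unsaturated and
releases water only when the bottom node saturates (never, in the
reference scenario — consistent with the experiment, where no outflow was
observed).

The water ledger (infiltration, actual evaporation and transpiration,
bottom outflow, storage change) closes to ~10⁻⁸ relative in the reference
scenario; the acceptance threshold is 0.5%.

## Solute transport

Operator splitting per flow-output interval: (1) implicit upwind
advection–dispersion with the Freundlich term linearized around the
current iterate and Picard-iterated to 10⁻⁶ relative; (2) exact
exponential decay in each phase with the transformed moles routed to EPX
in the same phase (liquid CBZ → liquid EPX, sorbed CBZ → sorbed EPX); (3)
explicit capped root uptake r_a = S·min(C, C_max), removed from the liquid
phase, with the integrated rate passed to the plant model.

Dispersion is D = λ|q|/θ with λ = 1 cm; molecular diffusion is omitted
(only dispersivity is parameterized).  In the θD·∂C/∂z flux the water
content cancels, so the dispersive conductance is simply λ|q|/Δz.  The
Freundlich slope ds/dC = K_f·β·C^{β−1} diverges at C → 0 for β < 1; it is
frozen below 10⁻⁹ µg/cm³ (1 ng/L), which only affects the numerically
inert leading edge of the front.  Sorption uses mass units (µg, cm³, g) as
measured; state is molar throughout; reporting converts to ng/g.

EPX shares CBZ's K_f and β, and its own degradation in soil is neglected.
The Cauchy inflow carries solute only with irrigation water; evaporation
removes none (open question resolved as solute-free evaporation).  Uptake
is evaluated after sorption equilibration within a step.

Per-species molar ledgers (applied = stored + taken up + transformed ±
chain transfer) close to ~10⁻⁹ relative; acceptance threshold 0.5%.

## Plant uptake

Amounts A [mol] per species and compartment.  With M_j(t) the logistic
fresh masses (M(t) = Mmax/(1 + (Mmax/M0 − 1)e^{−Kgr·t}), evaluated in the
overflow-safe form) and Q(t) = Ta·A_column the transpiration stream:

dA_R/dt = U − Q·A_R/(K_RW·M_R) − τ_R·A_R
dA_S/dt = Q·A_R/(K_RW·M_R) − Q·A_S/(K_SW·M_S) − τ_S·A_S
dA_L/dt = Q_L·A_S/(K_SW·M_S) − τ_L·A_L
dA_F/dt = Q_F·A_S/(K_SW·M_S) − τ_F·A_F

with Q_L : Q_F = S_A,L·M_L : S_A,F·M_F, every τ-term a source for EPX in
the same compartment, and EPX transported identically but not further
degraded.  The cascade routes the full stream through roots and stem and
splits it only at the leaves/fruits level; the compartment water contents
W are metadata (fresh/dry conversions), not used in the dynamics.  Fruits
appear at day 25 with a 10⁻³ g seed mass replacing the zero initial mass.

The system is linear with time-varying coefficients and is integrated by
fixed-step RK4 (default 0.02 day; coefficients and uptake series
interpolated linearly), numba-compiled.  Against a frozen-coefficient
matrix-exponential oracle it agrees to better than 10⁻⁶ relative.  The
plant ledger (cumulative uptake = stored CBZ + stored EPX) closes to
~10⁻¹³.

Couplings are one-way: flow → transport → plant; no feedback of plant
content to the soil.

## Calibration

Per observation set j: ℓ_j = −(k/2)·ln(2πσ_j²) − Σᵢ(Hᵢ − ȳᵢ)²/(2σ_j²),
with σ_j a known input (from replicate spread), never inferred.  The total
log-likelihood sums the sets after one forward run.  Priors are uniform
over the calibrated bounds; C_max,EPX's lower bound of 0 is handled
linearly.

The nested sampler is a static n_live-point sampler with constrained
random-walk replacement: per iteration the worst live point is replaced by
a walk (proposal scale 2.38/√d times the per-dimension live spread, scale
factor adapted toward 50% acceptance, reflection at the unit-cube
boundary) accepted only above the current likelihood threshold; evidence
accumulates with widths X_i = e^{−i/n_live}; termination when the
remaining live mass cannot move ln Z by more than dlogz; the final live
points are shelled in.  The evidence error estimate is √(H/n_live).
Against the conjugate 1D Gaussian oracle the evidence is correct to well
within 0.2 nats.  Defaults: n_live 300–500, dlogz 0.01–0.1 depending on
use; forward failures map to −∞.

Full 15-parameter calibration with the complete coupled model is
supported through the same interfaces but is computationally heavy
(~30 ms–1 s per forward run depending on configuration); the shipped
experiments are the two reduced problems that carry most of the
information: plant-only (6 parameters, soil frozen from a median run) and
flow-only (4 VGM shape parameters, 20-element grid, daily sensor series).
In both, posterior medians recover the generating truths within a few
percent at replicate-level noise, and the 90% intervals cover them.

## Sensitivity analysis

RBD-FAST: one base curve s_k evenly spaced on (−π, π), per-factor random
permutations, x = G⁻¹(½ + arcsin(sin s)/π) mapped to the factor bounds;
for each factor the outputs are reordered by that factor's s and the power
at the fundamental plus 6 harmonics, over the total variance, estimates
S1, with the standard bias correction S1 ← S1 − λ(1 − S1), λ = 2M/N.
Validated against the Ishigami function's closed-form indices (±0.05 at
N = 3000) with a dummy-factor type-I check (< 0.05).  The quantity of
interest is the fruit CBZ concentration on the final day from a full
coupled run; forward failures are imputed by the last successful output
and logged.

## Synthetic experiment generator

The generator emulates: the column geometry and 0.24 cm³/cm³ initial
water content; demand-driven irrigation (dose when the simulated
column-average θ falls below 0.26, refilling storage to 0.30 — chosen so
the root-zone pressure head oscillates near the optimal Feddes plateau,
matching the experiment's stated "optimal conditions" watering); CBZ
dosing at 0.15 µg/cm³ from day 16 (producing soil concentrations of
hundreds of ng/g by day 48); ET demand growing with canopy development to
~3.8 cm/day on a pot-area basis (~230 cm³/day per plant) with lognormal
day-to-day weather noise; daily θ/h sensor series at 2.5/15 and 5/15 cm;
destructive samplings at days 16/23/30/41/48; and replicate-level Gaussian
noise with per-set σ (θ: 0.01 absolute; h: 10% of the series RMS;
concentrations: 15%) — stand-ins for real replicate spreads, recorded in
the truth metadata as synthetic.

It does not emulate: control (fresh-water) columns, metabolites beyond
EPX, within-season changes of soil hydraulic properties or plant water
content, sensor drift, or spatial heterogeneity between replicate columns.
Passing recovery tests therefore demonstrate that the inference machinery
is consistent and well-calibrated under the model's own assumptions — not
that the model is structurally adequate for any particular real dataset.

## Problem sizes used in the shipped experiments

Forward reference runs use 50 elements (0.1-day output); the flow-only
calibration uses a 20-element grid with daily output and ~10⁴ likelihood
evaluations (80 live points); the plant-only calibration uses 300 live
points and ~10⁵ evaluations of the compiled plant kernel.  These sizes
were chosen so a complete recovery experiment runs in minutes on one CPU
while leaving the posterior medians within a few percent of the truths;
the grid-convergence tests bound the coarse-grid bias well below the
observation noise.

## Known limitations

- The maximum-uptake-concentration (C_max) cap is an empirical device
  without mechanistic grounding; it is the dominant control on total
  plant burden.
- No phloem return flow, no gaseous exchange, no volatilization, no
  EPX back-transformation, no further EPX metabolism in the plant.
- Hysteresis, dual porosity, temperature effects and 2D/3D flow are out
  of scope; ponding/runoff is excluded (excess infiltration is clamped
  and recorded, not routed).
- The nested sampler is a straightforward single-ellipsoid-free MCMC
  variant; heavily multimodal posteriors would need a more elaborate
  region construction than the problems here require.
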