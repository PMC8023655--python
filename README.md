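# soilplant

Mechanistic modelling of pharmaceutical uptake in the soil–plant
continuum, built around a greenhouse experiment in which green pea plants
(*Pisum sativum* L.) grown in 20 cm soil columns were irrigated with
carbamazepine (CBZ)-spiked water.  The package simulates how CBZ moves
from irrigation water through the soil into roots, stem, leaves and
fruits, where it is metabolized into carbamazepine-10,11-epoxide (EPX),
and provides the Bayesian calibration and global sensitivity machinery to
confront the model with data.

It is a library first: import it, build a scenario, run it.  The
`examples/` directory holds short narrative scripts, and a thin
`soilplant` CLI wraps the pipeline stages (`simulate | synth | calibrate |
gsa | report`) for shell use.

## The model

**Water flow.** 1D Richards equation over a two-horizon column,

∂θ/∂t = ∂/∂z [ K(h) (∂h/∂z + 1) ] − S(z,t),

with van Genuchten–Mualem hydraulics θ(h), K(h) (parameters θr, θs, α, n,
Ks per horizon), an atmospheric upper boundary (irrigation/evaporation
with head-limited switching), a seepage face at the bottom, and a root
water extraction sink S = α_F(h, Tp)·b(z,t)·Tp built from the
piecewise-linear Feddes stress function α_F and a logistically growing
root distribution b.  Evapotranspiration demand is split into evaporation
and transpiration by Beer-law canopy extinction of the leaf area index.
Numerics: mass-conservative mixed-form Picard iteration on a top-refined
100-element grid with adaptive time stepping (compiled with numba).

**Solute transport.** Advection–dispersion–reaction for CBZ and EPX,

∂(θC_i)/∂t + ρ ∂s_i/∂t = ∂/∂z[ θD ∂C_i/∂z − qC_i ] − r_a,i + φ_i,

with Freundlich sorption s = K_f·C^β (EPX shares CBZ's sorption
parameters), sequential first-order decay CBZ→EPX in both phases
(μ_L = μ_S = 0.0068 day⁻¹), a Cauchy inflow boundary, zero gradient at the
bottom, and passive root uptake r_a = S·min(C, C_max) capped at the
maximum uptake concentration.  All chemistry is carried in molar units;
outputs are reported in ng/g.

**Plant uptake.** Four compartments (roots, stem, leaves, fruits) with
logistic growth; the xylem stream Q = Ta·A carries chemical out of each
tissue at Q·A_i/(K_PW·M), splits between leaves and fruits by
specific-area-weighted mass, and a first-order rate τ per compartment
transforms CBZ into EPX in place.  Phloem return flow is neglected.

**Calibration.** Gaussian likelihood per observation set with a known
(replicate-derived) σ, summed over the 14 sets (θ and h at two depths
each, soil CBZ/EPX, tissue CBZ/EPX × 4); uniform priors over the
calibrated parameter bounds; nested sampling (in-package, MultiNest-style
constrained random walks) returning weighted samples, 5/50/95% quantiles,
evidence, predictive-check ensembles and a convergence report.

**Sensitivity.** RBD-FAST first-order indices S1 of the fruit-CBZ
quantity of interest: one randomized periodic design, N runs for all d
factors, spectral estimation with 6 harmonics and bias correction.

## Worked example

```bash
python examples/forward_simulation.py
```

prints, for the calibrated median parameter set:

```
irrigation: 38 events, 57.0 cm total over 48 days
water balance: infiltration 57.0 cm, transpiration 57.7 cm,
bottom outflow 0.00 cm, closure error 3.6e-09

day-48 concentrations [ng/g]:
  soil_CBZ        777.8   (0-5 cm soil layer)
  soil_EPX         65.6   (0-5 cm soil layer)
  roots        CBZ   40.65   EPX   4.11
  stem         CBZ   12.97   EPX   6.29
  leaves       CBZ    0.85   EPX   7.46
  fruits       CBZ    0.85   EPX   0.44
```

CBZ persists in the soil at concentrations two orders of magnitude above
the plant tissues (the C_max cap limits root entry); inside the plant,
roots and stem act as reservoirs while the leaves — with by far the
largest transformation rate τ_L — accumulate the most EPX.  Edible fruits
see little of either compound.

`examples/plant_recovery.py` runs a full Bayesian recovery experiment in
about a minute and prints the posterior quantile table next to the
generating truths; `examples/sensitivity_analysis.py` validates the
RBD-FAST estimator against the Ishigami function's closed-form indices.

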