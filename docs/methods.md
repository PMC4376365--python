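# Methods

This note documents the model, its numerical treatment, the parameter
defaults, and the design decisions taken where more than one reasonable
choice existed. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Model structure and assumptions

The simulation couples two descriptions of a colony on agar:

1. **The shared environment** — per-substrate concentration fields
   φ(x, t) (mol l⁻¹) on a cubic lattice of spacing λ, with three site
   types. *Air* sites are clamped concentration sources (a thin water film
   in Henry's-law equilibrium with the atmosphere); *agar* sites diffuse
   with slightly reduced coefficients and can carry Dirichlet boundary
   values on the dish walls and floor; *cell* sites hold biomass as a
   continuous volume fraction ρ per regulatory state.
2. **The cells' metabolism** — a stoichiometric flux-balance model solved
   per cell site under availability constraints derived from the local
   fields, yielding a specific growth rate g (hr⁻¹) and exchange fluxes
   (mmol gDwt⁻¹ hr⁻¹).

Two assumptions carry the whole construction. First, *quasi-steady state*:
substrate fields relax in seconds while the colony changes over minutes, so
each colony update can operate on converged concentration profiles — which
is also precisely the regime in which a steady-state FBA description of the
cells is defensible. Second, *deterministic mean-field biology*: all cells
in a site behave identically and optimally; there is no stochastic gene
expression, no cell death, and no mechanical detail beyond volume exclusion.

## Kernels

**Diffusion.** Explicit seven-point stencil; the face flux averages the two
sites' diffusivities arithmetically, which keeps the flux continuous across
material boundaries. Faces between air and non-air sites are one-way
(into the condensed phase only): oxygen is absorbed from the air but
aqueous solutes never evaporate. Hindered substrates (those that cannot
cross membranes — glucose, acetate) see D_eff = D·(1−ρ)/(1+ρ/2) inside the
colony; oxygen diffuses through cells unhindered. Updates are Jacobi
(simultaneous), making results independent of traversal order and of any
future parallel decomposition. Stability requires Δτ ≤ λ²/(2·D_max); the
runs here use a further safety factor (see *Problem sizes*).

**Active uptake.** Glucose import follows Michaelis–Menten kinetics into a
per-site intracellular pool shared by all states (per-state pools are not
identifiable from the model structure; the FBA constraint divides by total
ρ). The transfer per sub-step is capped at the available extracellular
pool, so positivity never forces a smaller Δτ; cap events are counted and
reported.

**FBA.** Availability constraints convert local pools into the maximum
specific uptake sustainable for one sub-step, then cap at the transporter
kinetics (glucose 10.4, oxygen 31.8, acetate 16.0 mmol gDwt⁻¹ hr⁻¹). The
LP maximizes biomass; because the optimal flux distribution is generally
degenerate (acetate secretion at fixed growth can be rearranged), a
parsimonious second stage minimizes total absolute flux at the optimum,
making exchange fluxes unique and lookup tables reproducible. Infeasible
programs return zero growth and fluxes, flagged. With molecular crowding
enabled, a single linear budget Σ_r a_r·|v_r| ≤ 1 is added via the solver's
forward/reverse flux split.

**Lookup tables.** The inner loop would otherwise require ~10⁶ LP solves
per simulated second. Tables store the parsimonious solution on a
rectangular grid over the constraint vector (default 17 linear nodes per
tracked substrate from 0 to the kinetic cap; the scaled-down runs use 9),
per cell state, keyed to a model checksum. Queries interpolate
multilinearly and additionally clamp each uptake to the queried constraint
so interpolation can never consume more than is locally available — this
clamp is what lets a constant-sink table reproduce exact zero-order
consumption profiles down to empty pools. Node queries are exact by
construction; off-node error is bounded by the curvature of the piecewise
linear LP value function between nodes and halves (or better) under 2×
refinement.

**Growth and expansion.** ρ grows exponentially with each state's own
table growth rate. Over-filled sites shed volume through each face at
(1/12)·(overfill difference); the 1/12 = ½·⅙ contains the convergence
damping. Sweeps are Jacobi and repeat until the worst over-filling is
within Δρ = 0.01 of ρ_max (residuals decrease monotonically; a 10⁴-sweep
cap guards against pathological states). Transfers split among co-resident
states by the donor's fractions, carry intracellular pools in proportion,
convert air to cell sites, and never displace agar — colonies grow up and
outward only, consistent with the observed hemispherical-cap habit.

**Regulation.** First-order switching between states with rates given by a
clamped quadratic polynomial of two local concentrations, integrated by
explicit Euler at the colony cadence. Outflow is summed over all declared
transitions out of a state (required for conservation; with a single
transition it reduces to the obvious form), and any step that would
overdraw a state is scaled back proportionally so Σᵢρᵢ is conserved
exactly. A warning fires when k·t_grow exceeds 1.

**Forward projection.** After the steady-state stage, the mean per-site
field drift over the last 5% of sub-steps is extrapolated over the
remaining t_grow − t_ss, floored at zero — this is what lets the agar
reservoir deplete at the correct rate even though diffusion runs only 1/60
of wall time. Only the depletion side (negative drift) is projected by
default: extrapolating the accumulation side multiplies any not-yet-
converged diffusion transient by t_grow/t_ss ≈ 10², which is numerically
explosive (a spreading plume re-amplified every cycle). Accumulating
fields (secreted acetate) instead converge to their quasi-steady plume
through the relaxation windows themselves. Projected increases are
additionally capped at each substrate's source concentration, since pure
diffusion cannot overshoot its source. The public operation exposes an
`include_production` flag for the unrestricted semantics.

## The batch acetate-switch model and its calibration

The 0-d companion model tracks glucose-consuming and acetate-consuming
biomass (M_glc, M_ace, gDwt l⁻¹) and the two substrate concentrations, with
growth, consumption (v_glc, v_ace), acetate production by glucose consumers
(ε_ace), and interconversion through the same polynomial switching rates
used spatially. As printed, such rate equations let biomass keep growing
after its substrate is exhausted and drive concentrations negative; both
growth and consumption therefore carry a smooth Monod-style gate
φ/(φ + 10⁻⁶ M) that vanishes with the substrate — an implementation of the
"floor at zero" rule that keeps the ODE right-hand side smooth.

Calibration is staged to mirror how the data determine the parameters:

1. g_glc, g_ace by log-linear regression of the single-substrate biomass
   curves (points with substrate above 5% of its initial value);
2. v_glc, v_ace, ε_ace from the same cultures' concentration curves with
   stage-1 rates fixed — with M(t) = M₀e^{gt} these fits are closed-form
   linear least squares;
3. the free switching coefficients from the mixed (diauxic) culture with
   everything else fixed, by Levenberg–Marquardt on scaled coefficients.
   The cost landscape has sharp thresholds, so a coarse deterministic grid
   over coefficient magnitudes (0.1–100× a characteristic scale) is
   screened first and the best candidates polished. When per-state biomass
   is available (the synthetic data provide it, emulating labelled
   subpopulations), it enters the residual and sharpens identifiability of
   the switching terms considerably.

Under-determined stages (missing cultures, rank-deficient bases) raise a
`CalibrationError` naming the stage.

The shipped default switching coefficients are **not literature values**:
they were chosen once as a self-consistent synthetic truth — leaving the
glucose state requires acetate and is suppressed while glucose exceeds
~0.2 mM (α₂ = 0.3 M⁻¹s⁻¹, α₅ = −1.5·10³ M⁻²s⁻¹); returning scales with
glucose (α₁ = 0.15 M⁻¹s⁻¹). The magnitudes give switching transients of
tens of minutes, slow enough to be identifiable from realistically sampled
batch curves and comfortably inside the explicit-Euler stability margin at
the colony cadence. User-supplied coefficient sets are accepted everywhere.

## What the synthetic data emulate — and what they do not

`fixtures.synthetic_batch_data` produces the three culture conditions a
calibration experiment would run (glucose-only, acetate-only, mixed
diauxic), sampled at 19-min intervals (3-min for the mixed culture, whose
switching transients are faster than the coarse grid) with multiplicative
log-normal noise of chosen coefficient of variation. It emulates ideal
well-stirred batch cultures: no lag phases, no measurement-limit censoring,
no autocorrelated instrument drift, and noise independent across time
points. Passing the recovery tests therefore demonstrates the estimator's
correctness and precision under the stated noise model, not robustness to
the systematic errors of real growth-curve data.

The toy metabolic model (6 metabolites, 8 reactions) realizes the three
phenotypes that drive colony structure — respiration (glc + 3 O₂ → 6
precursor), overflow (glc → 2 ace + 1 precursor), acetate oxidation (ace +
2 O₂ → 2 precursor), biomass (65 precursor → growth) — with yields tuned
once so the fully constrained aerobic doubling time is ~43 min. Its
crowding coefficient sets realize both regimes: one where the budget binds
at the kinetic caps (aerobic overflow appears) and one where it does not.
It stands in for a genome-scale reconstruction at desk scale; quantitative
colony observables (consumed fractions, advantage percentages) depend on
its yields and are not expected to match genome-scale values.

## Problem sizes and numerical choices

* Headline parameter defaults: 320×320×192 sites at λ = 10 µm (3.2×3.2×
  1.92 mm, agar 0.96 mm), Δτ = 1 ms, t_ss = 1 s, t_grow = 60 s,
  ρ_max = 0.65, Δρ = 0.01, m_cell = 2.58·10⁻¹³ g, V_cell = 10⁻¹⁸ m³;
  diffusivities and uptake kinetics as in `lattice.default_substrates`.
  Every value is overridable in the config.
* The scaled-down colony scenario (tests, acceptance script) uses
  64×64×48 sites, agar 160 µm, Δτ = 4 ms (factor ~4.8 below the
  λ²/(2·D_O₂) bound and 0.62 of the 3D explicit limit λ²/(6D)),
  t_ss = 1 s, t_grow = 120 s, 12 simulated hours, 9-node tables — sizes
  chosen once so a full two-variant comparison completes in minutes on a
  single core. It is seeded with one site at ρ_max (~650 cells, an
  established microcolony): at the toy model's ~0.97 hr⁻¹ ceiling a
  single-cell seed cannot form a colony thicker than the oxygen penetration
  depth within half a day, so nothing would be learned from the longer run.
* Negative-concentration tolerance 10⁻¹⁵ M separates float noise from true
  instability; breaching it aborts with a diagnostic.
* Colony radius and height use the half-maximum contour (Σρ ≥ ρ_max/2) —
  scale-free, and a single-site colony reports radius 0, height λ. Oxygen
  penetration is measured along the four cardinal rays through the seed in
  the first cell layer above the agar, from each ray's colony edge inward
  to the first site below 1% of the air value. Colony-wide "average
  uptake/production" are biomass-weighted means of the positive/negative
  parts of the recorded exchange fluxes.
* The exponential-to-linear transition of the radius is found by a
  two-segment changepoint fit (exponential head, linear tail, breakpoint at
  the minimum total squared error), accepted only when it beats both
  single-regime fits on AIC.
* The regulated run's returned lattice ends on a converged relaxation
  window so that fields and recorded fluxes are mutually consistent for
  zone analyses.
* Determinism: the core loop contains no random numbers; all stochasticity
  (synthetic noise, random table queries in tests) flows from explicit
  seeds.

## Known limitations

* Mean-field, deterministic: no cell-to-cell variability, no stochastic
  switching, no lag ("retooling") state between the glucose and acetate
  phenotypes — the model switches directly, which overestimates acetate
  uptake at intermediate concentrations.
* Mechanics are volume exclusion only: no friction, surface tension or
  extracellular matrix, and cell volume cannot displace agar.
* The early 2D-to-3D transition of real microcolonies is not represented;
  simulated young colonies are too tall.
* The quasi-steady treatment under-resolves any substrate whose relaxation
  time approaches t_grow; with the default t_ss = 1 s windows this is
  detectable as a drift in the convergence diagnostic, which is reported
  per cycle.
* Tracked substrates must be chosen in advance (table axes); metabolites
  outside the table (e.g. formate, ethanol) are invisible to the spatial
  model even if the metabolic model secretes them.
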