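# Methods

## The model

`synthgut` implements a mechanistic kinetic model of a defined three-strain
gut community grown in pH-controlled batch fermentors on fructose:

* **RI** — *Roseburia intestinalis* L1-82, a butyrate producer,
* **FP** — *Faecalibacterium prausnitzii* A2-165, a butyrate producer,
* **BH** — *Blautia hydrogenotrophica* S5a33, an acetogen.

Thirteen state variables evolve in time: three abundances `X_i`
(10⁸ counts/mL), three lag variables `Q_i` (dimensionless) and seven
metabolite concentrations `S` (mM: fructose, formate, acetate, butyrate, the
"unknown compound", H₂ and CO₂).

Growth follows Monod kinetics with obligatory (multiplicative) and
facultative (weighted) substrate dependencies:

    dX_i/dt   = Φ_i X_i
    Φ_RI      = Γ(Q_RI) μ_RI · M(S_fru, K_RI,fru) · (1 + ω_RI M(S_ace, K_RI,ace))
    Φ_FP      = Γ(Q_FP) μ_FP · M(S_unk, K_FP,unk) · M(S_fru, K_FP,fru)
                · (1 + ω_FP M(S_ace, K_FP,ace))
    Φ_BH      = Γ(Q_BH) μ_BH · ( M(S_fru, K_BH,fru) + ω_BH M(S_for, K_BH,for) )

with `M(S, K) = S/(K+S)` and the lag weighting `Γ(Q) = Q/(1+Q)`,
`dQ_i/dt = μ_i Q_i`. The lag duration is the time until `Γ = 1/2`,
i.e. `lag = −ln(Q_i(0))/μ_i`. RI and FP require fructose (FP additionally an
unidentified heat-labile medium co-factor, tracked as an unobservable state
initialized at 30 mM); acetate is facultative for both. BH grows additively
on fructose and formate, so it grows on formate alone; its formate term
carries the facultative weight `ω_BH`.

Metabolite dynamics are linear combinations of `Φ·X` terms with consumption
yields `ν` and production yields `α` (mM per 10⁸ counts/mL). Acetate
consumption by RI/FP is driven by auxiliary rates
`Φ_i,acetate = Γ μ_i ω_i · (obligatory Monod factors) · M(S_ace, K_i,ace)`,
and BH's fructose/formate consumption by the two additive components of
`Φ_BH`. Butyrate is only produced; the unknown compound only consumed. H₂
and CO₂ are cumulative amounts expressed in mM of the liquid volume with no
outgassing or gas re-uptake: gas consumption by the acetogen is deliberately
not modeled, reflecting the heterotrophic growth regime of the fermentations
this model describes.

Two presentation notes on the rate equations. The second partial rate of BH
is the formate component `Φ_BH,formate = Γ μ_BH ω_BH M(S_for, K_BH,for)`
(its subscript is sometimes typeset identically to the fructose component);
and the H₂ yield on the BH term of `dS_H2/dt` is the per-strain yield
`α_BH,H2`, consistent with every other equation. The facultative weight is
written `ω` (sometimes `w`) — one parameter per strain. The middle factor of
`Φ_FP,acetate` is the fructose Monod term, by symmetry with `Φ_FP`.

Model assumptions: negligible death, production proportional to growth, no
abiotic transformation of metabolites, and interaction-independent
metabolism (the same parameters should hold alone or in community — testing
that assumption is the point of the two parameterization protocols).

### Numerics

The right-hand side is compiled (numba) and integrated with LSODA at
`rtol 1e-8`, `atol 1e-10` by default — Monod terms with half-saturation
constants far below the substrate pool make the system moderately stiff
near substrate exhaustion. Monod terms evaluate `max(S, 0)`: adaptive
solvers may legitimately step a concentration slightly below zero, and the
model is only defined for `S ≥ 0`. Solver failure raises an error carrying
the last time reached. A fixed-step fourth-order Runge-Kutta reference
reproduces all 13 states to ~10⁻⁵ (relative to each state's scale) on the
fixture tri-culture; refining the tolerance tenfold moves 48-h end-point
abundances by <0.1%.

## Parameter fitting

The objective is a normalized root-mean-square error. For each observed
variable in an experiment, residuals (model − replicate-mean observation)
are divided by the per-experiment maximum of that variable's replicate
mean; this puts counts (~10⁰–10¹ in units of 10⁸/mL) and concentrations
(~10¹–10² mM) on one scale. Residuals are pooled over all variable–time
pairs into one RMSE per experiment (a per-variable pooling mode is
config-switchable), and a stage's objective is the mean over its
experiments. Variables with an all-zero maximum are skipped with a warning;
measured-but-unmodeled variables (lactate, ethanol) are ignored.

Samples after the end of the log phase are excluded from the abundance
residuals: for each strain, samples strictly after the peak of the
replicate-mean abundance that fall below 90% of that peak are flagged as
declining. The 90% rule turns a judgment usually made by eye into a
reproducible one; a post-peak plateau is not decline. Metabolite samples at
excluded times are retained by default (config-switchable).

Minimization is derivative-free Nelder-Mead in log10 parameter space
(positivity by construction), run as several re-seeded passes whose initial
simplex edge shrinks geometrically (0.08 decades, ×0.25 per pass): the
first pass explores, later ones polish. An optional kinetics-polish phase
re-runs the simplex over only the growth-kinetics coordinates
(μ, K, ω, Q0) with the yields frozen — yields enter the trajectories
essentially linearly and converge almost exactly, while the kinetics
subspace is ill-conditioned and benefits from lower-dimensional simplex
work. Each experiment's initial lag variables `Q_i(0)` are nuisance
parameters bounded in [10⁻⁶, 10], co-estimated in any stage whose
experiments include the strain; `estimate_Q0` additionally offers a
reproducible 1-D grid search replacing by-eye reading of log-scale growth
plots. Identical inputs, initial guess and budget give bit-identical
results.

Two protocols:

* **Parameterization 1** — each strain's full parameter set from its
  mono-cultures only (RI and FP with 50 mM initial acetate, BH with 50 mM
  initial formate).
* **Parameterization 2** — a four-stage protocol with earlier stages
  frozen: (1) FP from its mono-cultures; (2) BH's yield parameters (ν, α)
  from FP/BH bi-cultures with initial acetate; (3) BH's growth kinetics
  (μ, K, ω) from the same bi-cultures; (4) RI's full set from RI/BH
  bi-cultures with initial acetate. Fitting everything at once does not
  converge because of the nonlinear growth functions. Where the BH
  production yields belong is genuinely open; they are grouped with the
  consumption yields in stage 2 because both are yield-type parameters
  estimated from the same mass-balance information. Stage order can be
  permuted (with a protocol-deviation warning). Per-stage evaluation
  budgets let a caller spend optimizer effort where the dimensionality is
  highest. Held-out designs (the no-acetate bi-cultures) are predicted by
  forward simulation without refitting.

### Practical identifiability

A structural caveat documented here because it bounds what parameter
recovery can show. In a batch mono-culture every substrate concentration
is an exact affine function of the strain's accumulated biomass
(`S = S₀ − ν·ΔX`, products likewise), so along a trajectory the growth
factors collapse into a single composite function of `X`: distinct
combinations of (μ, K, ω, Q0) can reproduce the data essentially exactly,
and a fit can reach the solver's noise floor with individual Monod
constants tens of percent from the generating values. Replicates with
different inocula trace different substrate-vs-biomass paths and break
part of this collapse, which is why the synthetic study's biological
replicates deliberately span an order of magnitude in inoculum; bi-cultures
break more of it (a partner reshapes the substrate trajectories). Yields
are always recovered essentially exactly; maximal growth rates to a few
percent; individual half-saturation constants remain the sloppiest
directions, and a derivative-free simplex can settle in near-equivalent
pockets tens of percent from the generating values. Consumers of fitted
parameters should treat single K values as weakly determined and the
predicted trajectories (which is what the fit constrains) as the robust
output.

## Fermentation balances

`net_deltas` reports final-minus-first concentrations averaged over
technical replicates (consumption negative); transients such as the
produced-then-consumed formate peak cancel by construction. Carbon
recovery is 100 × (carbon in net-produced metabolites)/(carbon in
net-consumed metabolites) with carbon atoms per molecule: fructose 6,
butyrate 4, lactate 3, acetate 2, ethanol 2, formate 1, CO₂ 1, H₂ 0;
biomass carbon and the unknown co-factor are excluded. The O/R balance
follows the classical available-hydrogen convention — oxidized equivalents
(CO₂ ×2, formate ×1, with net-consumed formate entering negatively) over
reduced-product equivalents (butyrate ×2, ethanol ×2, H₂ ×1) — and is
undefined (an explicit error) when the reduced sum is zero. Because the
balances are ratios, recovery computed on replicate-mean deltas is not the
mean of per-replicate recoveries; only single-replicate rows are exact
anchors. Both tables are overridable.

## Dominance scans

`scan_lag` and `scan_init` map which butyrate producer co-dominates (BH
always reaches high abundance): each cell of a 25×25 grid is one full
tri-culture simulation summarized as log₁₀(X_FP(t_e)/X_RI(t_e)) at
t_e = 48 h, the fermentation duration. Fixed conditions default to the
average tri-culture values: inocula 0.58/0.04/0.21 ×10⁸ counts/mL
(RI/FP/BH) for lag scans, lags 0.33/0.08/0.1 h for initial-abundance
scans; lag axes span 0–8 h, abundance axes are log-spaced. Cells are
independent (permutation-invariant); a failed cell is flagged and the scan
continues; zero-abundance cells store ±infinity. `classify_dominance`
labels FP above ratio 1, RI below, flags exact ties, and reports agreement
with an observed dominance when given one.

## Synthetic data generator

The generator emulates the study's fermentation tables so the pipeline is
testable without the deposited data: designs with 50 mM fructose, 50 mM
co-substrate (acetate and/or formate) where added, the unknown co-factor
at 30 mM; the irregular sampling grid (10 min, then 2, 3, 5, 6, 7, 9, 10,
11, 13, 14, 15, 17, 18, 24, 30, 48 h); technical triplicates. Counts
receive multiplicative log-normal noise (default CV 10%) and an
exponential decline tail (0.05 /h) after growth stops — the model itself
assumes negligible death; the tail exists so decline exclusion has
something to exclude. Concentrations receive additive Gaussian noise
(default sd 0.5 mM) floored at zero. Both defaults are the order of the
technical scatter visible in the study's triplicates. One seed fixes all
randomness; ground truth (parameters, lag variables, noiseless
trajectory) travels with every experiment.

The fixture parameter set is fixed and versioned. Growth rates span
0.45–0.9 /h; half-saturation constants 8–40 mM, deliberately on the scale
of the substrate pools so each Monod factor traverses its curved range
over a run (a fixture in the fully saturated regime would make its own
recovery test meaningless); facultative weights are large (ω_RI = 2,
ω_FP = 1.5) so the acetate term is a major, time-varying growth
component; yields are sized so 50 mM fructose supports a few 10⁸
counts/mL. Under this set RI and FP deplete fructose in mono-culture
within 48 h, BH consumes formate, and tri-culture dominance flips across
both default scan grids. The default roster mirrors the study's design
matrix: five mono-cultures, eight bi-cultures (including the no-acetate
designs), six tri-cultures with inoculum proportions straddling the
dominance boundary so both RI- and FP-dominant outcomes occur.

What the generator does **not** emulate: biological replicate-to-replicate
parameter variation (all experiments share one truth), pH excursions,
measurement dropout, lactate/ethanol side products, gas-phase transport,
or any model-misspecification — passing recovery tests therefore shows the
pipeline is correct and calibrated, not that the model is true of real
communities.

## Problem sizes used by the test suite

Unit tests run single simulations and single-stage fits in seconds. The
study-scale checks use: the full 19-experiment synthetic study; a 25×25
lag scan (625 simulations); a noise-free staged fit with per-stage budgets
of 3000–10000 objective evaluations; and 20 noisy replicate studies fitted
at 800 evaluations per stage. These sizes were chosen so the whole suite
completes on a single CPU in well under half an hour while the recovery
checks remain at full study scale.

## Known limitations

* Individual Monod constants are weakly identified from batch data (see
  Practical identifiability); report trajectories, not single K values.
* The model is not carbon-closed: biomass and the unknown compound absorb
  and emit carbon, so no conservation law is asserted on simulated
  trajectories beyond the printed sign structure of each rate equation.
* No uncertainty quantification (no profile likelihood or bootstrap), no
  gradient-based or global optimizers, no chemostat/dilution terms, no
  stochastic simulation, and no hydrogen-inhibition or CO₂-uptake growth
  variants.
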