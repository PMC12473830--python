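# Methods

## Transport model

All mass transfer is compartmental and linear: for compartments 1 and 2
joined by an interface, the flux is `J = P·A·(C₁ − C₂/Kp)` with
permeability `P` (cm/h), exchange area `A` (cm²) and steady-state
partition coefficient `Kp = C₂/C₁`.  Each compartment is well mixed and
obeys `V·dC/dt = ΣJ_in − ΣJ_out`.  The implementation integrates
*amounts* (µg) rather than concentrations so that total mass of a closed
system is the plain sum of the state vector; simulations verify
conservation to a relative 10⁻⁶ at every output time and raise if it is
violated.  Internal units are fixed (h, mL, cm², cm/h, µg, µg/mL,
g/cm³); any conversion happens at I/O boundaries.

A single interface per compartment pair is enforced: the driving force
`C₁ − C₂/Kp` is already bidirectional, and a second (reverse) interface
would double-count transfer.

**Lag times.** Delayed release onset is modelled as a hard gate: the flux
across a lagged interface is identically zero for `t < lag`.  The
integrator (stiff-capable LSODA, default `rtol 1e-8`, `atol 1e-10`, with
the analytic rate matrix supplied as the Jacobian) is restarted at every
lag boundary so the discontinuity never interacts with step-size
control.  A transit-compartment formulation would smooth the onset but
add a parameter; the gate is the minimal mechanism and is exactly
testable (downstream amounts are zero through the lag).  The gate sits on
the particle → continuous-phase interface, attributing the delay to the
formulation's release step rather than membrane entry; the builder makes
the location configurable.

## IVRT stage

The gel is a two-phase system: drug-loaded solid particles (discrete
phase, DP; density 1.3 g/cm³) suspended in a continuous phase (CP,
1.0 g/cm³).  All drug starts in DP — micronised suspended drug is the
physically sensible initial condition for a highly lipophilic compound —
with the initial split configurable.  Phase volumes follow from the
applied gel mass (500 mg), the discrete mass fraction (default 0.01) and
the phase densities.  A 0.1% w/w gel therefore loads 500 µg.

The Franz cell uses a 5.1 mL receptor, 0.69 cm² orifice, and a cellulose
membrane modelled as a well-mixed compartment of volume
area × 25 µm × porosity 0.7, non-selective (Kp = 1) on both faces.
Cumulative release per area is the receptor amount divided by the orifice
area.  Sample-and-replace measurements are reconstructed by
`Q(tₙ) = (Cₙ·V_rec + Σ_{i<n} Cᵢ·V_s)/A`, which adds back the drug removed
with each 0.5 mL aliquot.

**Shipped release parameters.** The real calibrated values for marketed
gels are not public; the package ships synthetic defaults chosen once so
the simulated study is realistic and fully identifiable: receptor
concentrations below the 0.05 µg/mL LOQ at early times and well above it
later; cumulative 24-h release of a few µg/cm²; release-rate ordering
Differin > AcneFree > Effaclar with lags 0 / 3.5 / 5.5 h.  `Kp(DP→CP)`
(~10⁻⁴) caps the released fraction (the particle phase strongly retains
a logP ≈ 6.9 compound); `P(DP→CP)·A` is set so the continuous phase
approaches its partition ceiling on a multi-hour timescale.  That last
choice matters: if phase equilibration is fast, the release curve carries
no information about `P` and the rate parameter is unidentifiable — the
shipped regime lets rate, extent and lag all be recovered from the curve
shape.

## IVPT stage

The dermatomed-skin model has compartments DP, CP, SC, SB (sebum /
follicular pathway), VE, DM and a 4.9 mL receptor, with interfaces
DP→CP, CP→SC, CP→SB, SB→SC, SB→VE, SB→DM, SC→VE, VE→DM, DM→REC.  The
sebum compartment is fed from the gel's continuous phase (the only depot
present) through a follicular area fraction of 0.1% of the 0.69 cm² skin
area, and its volume defaults to 0.1% of the SC volume.

Layer geometry: SC 12 µm, VE 53 µm, DM 735 µm.  The split is chosen so
thickness × area × density (epidermis 1.2, dermis 1.5 g/cm³) reproduces
tissue weights of ~1, ~4.4 and ~75 mg and sums to the 800 µm total used
for the study skin; only the weights and the total are constrained by the
experimental setup, so the split is a package choice and configurable.

Tissue accumulation divides the SC+VE (plus, by default, sebum — the
infundibulum opens at the epidermal level, and mechanical separation
cannot isolate it; configurable to dermis or excluded) amount by the
epidermis weight and DM by the dermis weight.  Recovery is
`100 × (epidermis + dermis + residual donor + receptor)/dose`; on the
closed simulated system this is exactly 100% at every time, which is the
package's mass-balance self-check (experimental recoveries scatter around
100% only through measurement noise, which the synthetic generator
reproduces).

Exposure for the PD stage is the SC concentration (SC amount / SC
volume); infundibular exposure is 0.1% of it, consistent with follicles
occupying ≤ 0.1% of the surface area.

Default skin transport parameters are again synthetic package choices
(large `Kp(CP→SC)` ≈ 300 for lipophilic partitioning into SC lipids, small
dermis→receptor partitioning) selected once for qualitative realism:
predominant epidermal accumulation, dermis two orders of magnitude lower
per weight, and only trace receptor amounts by 36 h.  The shipped
defaults keep the epidermis curve rising slowly through 36 h rather than
fully plateauing; an early plateau would require faster SC uptake than is
consistent with the trace receptor constraint under this parameter set.

## Calibration

Stage 1 (release) frees only {Kp(DP→CP), P(DP→CP), lag}; stage 2 (skin)
frees only {Kp(CP→SC)} and the dermis-involving partition coefficients,
with stage-1 results consumed unchanged and a single skin parameter set
pooled across formulations.  The stage contracts are enforced: a spec
that tries to free any other parameter raises.

The original workflow this mirrors calibrated manually; manual iteration
is not reproducible engineering, so the package uses bounded Nelder–Mead
on an SSE objective (optionally 1/ō² weighted), with log₁₀ search scales
for the positive multiplicative parameters and optional seeded
multi-start.  The reported result is never worse than the starting
point.  Observed zeros (below-LOQ substitutions) are kept for plotting
and RMSE/bias/R²/r but excluded from MAPE and AFE, whose denominators
they would destroy; every metric reports the number of pairs it used,
and a metric with fewer than two valid pairs is NaN, never 0.  AFE is the
signed geometric-mean fold error `10^mean(log₁₀ p/o)`; the absolute
variant (AAFE) is computed alongside because "fold error" is ambiguous in
common usage.

Morris screening uses standard one-at-a-time trajectories on the unit
hypercube with `Δ = levels/(2(levels−1))`, reporting µ* (mean |elementary
effect|), σ (EE standard deviation) and µ.  Elementary effects are per
unit-scaled step, so an additive linear function with slope `a` over its
range yields µ* = |a| exactly — the analytic anchor the tests use.
Trajectories producing non-finite output are dropped and counted.

A caveat the analysis scripts surface deliberately: with tissue data at
four sampling times, the stage-2 partition coefficients are only weakly
identified (the objective is nearly flat in `Kp(CP→SC)` far from
equilibrium, and `Kp(DM→REC)` is invisible when receptor amounts are
negligible).  This practical non-identifiability is the quantitative
reason the workflow calibrates as few skin parameters as possible.

## Population PD

Structure: `E = E0 + Emax·Cⁿ/(EC50ⁿ + Cⁿ)`, implemented literally with
`Emax` allowed either sign (the measured endpoints — SC thickness, pore
area — decrease, so `Emax` is negative while `E0`, the baseline, is
positive).  `E0` is a constant per subject; an exponential time-decay
baseline is available behind a flag but off by default.  Residual error
is proportional, `y = f(1 + b·ε)`, `ε ~ N(0,1)` (the exponent of the
`b·f^c` form is fixed at c = 1).  Between-subject variability is
log-normal and multiplicative per parameter, `θᵢ = θ_pop·e^ηᵢ`,
`ηᵢ ~ N(0, ω²)`; which parameters carry ω² is configurable.  The example
and recovery setups put it on Emax and E0: under proportional error the
per-subject EC50 estimate is heavily shrunk (its sensitivity peaks at
only |Emax|/4 around EC50), so EC50 variability is close to
unidentifiable at realistic sample sizes, whereas baseline and maximal
effect are directly anchored by the design.

**Estimation.** The reference workflow used SAEM in a commercial tool;
its stochastic E-step is heavy to validate at desk scale, so this package
uses a deterministic nested optimisation with the same contract: for
candidate population parameters, each subject's empirical Bayes estimate
(the posterior mode of η, minimising
`−2 log p(y|η) + Σ η²/ω²`) is located by a damped Newton iteration with
finite-difference derivatives (gradient-descent fallback, warm-started
across outer iterations, and always compared against a zero start so the
objective is reproducible); the marginal −2 log-likelihood (OFV) is the
Laplace approximation around that mode, reusing the Newton Hessian; and
Nelder–Mead minimises the total OFV over (log-scaled θ_pop, ω², b), with
simplex restarts at the incumbent because plain Nelder–Mead is prone to
premature collapse above four dimensions.  The best-so-far OFV trace is
monotone by construction.  Information criteria: AIC = OFV + 2P,
BIC = OFV + P·ln N_subjects, and BICc splits the penalty — subject-level
parameters (fixed effects, ω²) at ln N_subjects, observation-level
parameters (b) at ln N_observations — one defensible reading of
"corrected BIC" among several in use.

Two numerical facts worth knowing.  First, under proportional error the
likelihood's `2·log(b·f)` scale term biases the MAP/MLE away from zero
residual by O(b²); "noiseless data ⇒ η = 0" holds only in the small-b
limit, which is how the identity tests are phrased.  Second, θ and ω
recovery quality is a property of the study configuration: the
rich-design recovery checks use an exposure series that anchors the
baseline (C = 0), brackets EC50 and reaches saturation — a design
confined to C ≲ 2·EC50 leaves Emax and EC50 strongly confounded
regardless of sample size — and place BSV on the parameters that design
identifies (Emax, E0).

**Diagnostics.** VPC simulates replicate datasets under the model and
reports the 10/50/90 percentile trajectories with 90% confidence bands;
random-effect draws with non-positive predicted response are resampled
and counted.  IWRES = (y − fᵢ)/(b·fᵢ).  NPDE uses the simulation rank
transform `Φ⁻¹((rank + 0.5)/(K + 1))` with K = 500 by default; the full
decorrelation step of the original NPDE construction is omitted (sparse
designs give near-diagonal covariance), which the moment checks tolerate.
EBE summaries report per-formulation medians and IQRs of individual
parameter values.

## Synthetic data

The generators emulate the study designs end to end: 6-replicate IVRT
with explicit sample-and-replace withdrawal, multiplicative (default CV
5%) plus optional additive noise, and below-LOQ censoring to zero with a
`bloq` flag (LOQ 0.05 µg/mL); 6-replicate IVPT at 8/12/24/36 h whose
noise-free recovery components balance to exactly 100%; and a 6-subject
clinical design at baseline / 5 h (the 4–6 h window) / 48 h, subjects
allocated round-robin across the three formulations.  Every dataset is
seeded and byte-reproducible and ships its generating parameters for
recovery testing.

What the generators do *not* emulate: inter-donor skin variability,
time-correlated measurement drift, formulation rheology, and the real
(unreported) noise magnitudes — replicate CVs are conventions.  Passing
recovery tests therefore demonstrates correctness of the estimation
machinery under the assumed error model, not robustness to real-data
pathologies.

## Problem sizes and tolerances

Default simulations use ~100-point time grids over 24–48 h.  Recovery
checks use: noiseless single-replicate IVRT (release parameters within
1%), 6-replicate 5%-CV IVRT (within 15%), and a 50-subject × 10-time
rich PD design (θ within 15%, ω within 30%) — sizes chosen to make the
statistical claims testable at desk scale.  VPC coverage checks use 500
fresh observations against 1000-replicate bands (the 10,000-replicate
setting is available); conservation and oracle comparisons use relative
tolerances 10⁻⁶ (closed forms), 10⁻⁵ (matrix-exponential oracle) and
10⁻¹⁰ (metric battery).

## Repository shape

The package is an analysis project: computation lives in `src/dermapk/`
(so tests and the acceptance script import it), and the numbered scripts
under `analysis/` are thin narrative drivers that write tables to
`results/`.  There is no console-script CLI; the library functions
(`dermapk.pipeline.run_pipeline`, `validate_dataset`) plus the scripts
are the interface.
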