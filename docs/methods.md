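# Methods

`shadegame` asks how natural selection acts on the *shape* of a shade-avoidance
response curve when the light environment that triggers the response is itself
built by the responding plants.  It couples a deliberately simplified
functional-structural model of *Arabidopsis thaliana* rosettes competing for
light in regular stands to an adaptive-dynamics invasion analysis over a grid
of plasticity strategies.  This note documents the model, its parameters, the
numerical choices, and what the synthetic test scaffolding does and does not
show.

## The plastic response curve

A strategy is the curvature α of the response curve mapping locally perceived
red:far-red ratio (R:FR) to a relative organ growth factor

    F = min(2, (R:FR / RFR_control)^(-α)),       RFR_control = 2.3.

F is 1 for α = 0 and at the control ratio, and is capped at 2 so no organ more
than doubles in a day.  Each day, every petiole still in its growth phase
multiplies its length by F (computed from the R:FR at the petiole midpoint)
*after* its sink-driven growth; the carbon to back the extra length,
(F − 1) · length · linear density, is queued as additional petiole demand for
the next day and is never rolled back if unpaid.  Each growing lamina
down-regulates its demand as

    D = D_p / F^n,

with F from the R:FR at the blade centre.  The scenario exponent n sets the
lamina cost of responding: n = 2 (Average), n = 1 (Weak) and n = 4 (Strong).
The Weak value follows the methods prose of the source analysis; its figure
captions give 0 instead, and both are selectable (`scenario_n`).

## Rosette development

Leaves (petiole + lamina) emerge on a fixed plastochron of 1.5 d after a 3 d
germination lag (~28 leaves in 46 d), in a spiral with divergence 137.5° and a
per-replicate random base azimuth — the main source of replicate-to-replicate
stochasticity besides ray sampling.  Laminas are flat 2:1 ellipses attached at
the petiole tip and continuing along the same inclined direction.  Hyponasty
raises a leaf's elevation by 16° per day (to a maximum of 80°) whenever the
nearest other leaf tip is closer than 2 mm (own and neighbour leaves both
count, toroidal distance) or the blade perceives R:FR < 0.5.  Leaves senesce
after 40 d of age: they leave the light scene and the sink ledger but keep
their biomass in the performance total, since performance is total accumulated
biomass and no shedding rule exists.

## Carbon budget

Photosynthesis per lamina follows a negative-exponential light response,
p_max (1 − exp(−φ I / p_max)) · area · photoperiod, pooled per plant and
partitioned over all growing organs by relative sink strength.  Potential
demands are derivatives of a determinate beta growth curve
W(t) = W_max (1 + (t_e − t)/(t_e − t_m)) (t/t_e)^{t_e/(t_e−t_m)} at organ age;
the root is a pure sink demanding 10 % of total leaf potential demand.  If the
pool falls short every sink gets its pro-rata share; a surplus fills all
demands and splits the remainder 50 % to growing laminas (pro rata, stored as
biomass without area gain) and 50 % to the root.  There is no respiration and
no mortality; growth simply stalls when light capture is insufficient.  Mass
balance is exact: the daily biomass increment of every plant equals its
assimilate plus the seed-scale endowment of newly initiated organs
(0.05 mg lamina + 0.02 mg petiole per leaf).

Defaults (all overridable) were chosen once for realistic Arabidopsis scale
and so that low-density stands approach potential organ sizes while
high-density stands become carbon-limited well before day 46:
p_max = 0.3 mg biomass m⁻² s⁻¹ (≈10 µmol CO₂ m⁻² s⁻¹), φ = 1.5·10⁻³ mg µmol⁻¹,
SLA-like conversion 4·10⁻⁵ m² mg⁻¹, petiole linear density 200 mg m⁻¹, lamina
W_max = 12 mg and petiole W_max = 4 mg with t_e = 20 d, t_m = 9 d for all
ranks.  Under these defaults a lone low-density plant reaches ~150–170 mg by
day 46; stands at 6400 plants m⁻² close canopy within ~10 days and end near
30–40 mg.

## Canopy light

The stand is a regular square grid (spacing = density^(−1/2), focal plant at
the exact centre) treated as an infinite toroidal tiling — the limit of the
published 20×20 plot replication.  A diffuse cosine-weighted sky with
R:FR 2.3 and PAR 220 µmol m⁻² s⁻¹ (9 h photoperiod) is sampled with stratified
Monte Carlo rays carrying red, far-red and PAR weights along a shared
geometric path.  Laminas absorb 0.85 red / 0.15 far-red / 0.85 PAR and split
the remainder equally between reflection and transmission (so plants absorb
red and reflect/transmit far-red); petioles are absorbing interceptors of
negligible area.  Up to two Lambertian scatter bounces are traced; the energy
ledger (absorbed + soil + escaped + truncated = emitted) closes exactly by
construction and is asserted to 1 %.  Because every interaction depletes red
at least as strongly as far-red, no organ ever perceives R:FR above 2.3.

Organ-level *perception* is not read from the Monte Carlo hits — seedling
organs of ~1 cm² in a 0.25 m² unit cell would receive well under one ray per
day — but from sensor rays at each organ's perception point (petiole midpoint,
blade centre): cosine-weighted upward rays attenuate the sky by the
transmittance of every crossed patch (gap fraction), and downward rays gather
first-order scattered light using the Monte Carlo pass's per-patch incident
estimates as Lambertian exitances.  This keeps perception unbiased in organ
size, reproduces lateral far-red enrichment from lit neighbours, and leaves
ray-sampling noise as a realistic stochastic term.  Whole-plant mean R:FR
(the trajectory diagnostic) is instead the ratio of *intercepted* red to
far-red totals from the Monte Carlo pass, so canopy strata count by the light
they actually capture.

Numerical budgets: the published-fidelity configuration uses 20 000 rays per
day; the desk configuration used throughout the test and acceptance runs uses
5×5 stands and ~1 200 rays per day, which resolves every directional contrast
tested while keeping a 46-day stand run to a few seconds.  End-of-development
R:FR is reported as the mean over the last five days: the single-day read-out
carries ~0.07–0.1 SD of pure ray-sampling noise per replicate, which masks
the 1600-vs-6400 plants m⁻² separation that the five-day window resolves.

Known geometric simplifications: the nearest-replica toroidal intersection is
exact only for organs smaller than half the tiling period (safe at rosette
scale); blade-centre sensing approximates whole-blade perception; the sky is
purely diffuse rather than a lamp array.

## Experiments and invasion analysis

A run places one mutant strategy in the centre of a resident stand;
performance is the focal plant's total biomass after 46 days.  The full
published design is 8×8 strategy combinations × 20 replicates × 5 densities ×
3 scenarios = 19 200 runs; per-run seeds derive from a stable SeedSequence
hash of the design coordinates, making any subset bit-reproducible.

Invasion exponents are ln(mean mutant performance / mean resident
performance), diagonal forced to zero, with replicate confidence intervals
mean(x) ± sd(x)/√(n−1) for x_i = ln(perf_i / resident mean).  Following the
published order of operations, *performance* (not exponents) is smoothed with
a tensor-product penalized cubic B-spline: marginal basis of 5 (capped at the
grid size), second-order coefficient-difference penalty whose null space
contains every bilinear surface, penalty chosen by GCV.  The smoothed
invasion surface s(m, r) = ln(ŵ(m, r)/ŵ(r, r)) is zero on the diagonal by
construction.  Singular strategies are roots of g(r) = ∂s/∂m|_{m=r}
(201-point mesh, bisection); a gradient of constant sign yields a
"beyond the tested range" verdict rather than extrapolation.  Classification
uses finite differences with step = range/200: evolutionarily stable if
∂²s/∂m² < 0, convergence stable if dg/dr < 0, cESS if both; with replicate
data attached, derivatives within 2 bootstrap SEs of zero (40 resamples at
the fitted penalty) are declared indeterminate, and roots on the range
boundary are refused.

## Synthetic landscapes and what the tests show

The quadratic family s(m, r) = k(α* − r)(m − r) − h(m − r)² is the minimal
surface with independent knobs for the singular point (α*), convergence (k)
and evolutionary stability (h); replicate performances are
baseline · e^s · lognormal noise, with diagonal cells sharing the resident
noise stream so the estimated diagonal exponent is exactly zero.  It is test
scaffolding, not a claim about the simulator's true fitness surface: passing
recovery tests shows the *analysis pipeline* is correct and calibrated, not
that the simulator matches any particular real stand.

Measured replicate CVs of focal biomass at the desk preset span 0.031–0.130
across densities and strategies; 0.05 is used as the representative
simulator-matched noise.  At that noise, with n = 20 replicates over random
specs (α* ∈ [0.1, 0.6], k, h ∈ {±0.5, ±1}), the pipeline localizes α* within
one grid step in ~90 % of specs (100 % classification at zero noise, and
100 % correct classification among located roots at matched noise).  The
residual failures sit at weak convergence (|k| = 0.5) with α* near the range
edge, where the true selection gradient falls below the smoothing noise
floor; an independent check with R mgcv (tensor smooth, REML, replicate-level
data) recovers fewer (~85 %) on identical matrices, indicating a limit of the
estimator class rather than of this implementation.

## Scaled-down study conditions

All shipped tests and the acceptance script run the desk configuration:
5×5 stands, densities {100, 1600, 6400} plants m⁻², strategy grid
{0, 0.2, 0.4, 0.6}, 4–5 replicates, 1 200 rays per day, 46 days.  Directional
results under these conditions: biomass falls with density (~160 → ~100 →
~40 mg), end-of-development R:FR falls with density, petiole biomass share
rises steeply with α (≈23 % at α = 0 to ≈50 % at α = 0.4 at 1600 m⁻²), the
selection gradient at low α is more positive at 1600 than at 100 plants m⁻²,
and weaker lamina down-regulation (n = 1 vs n = 4) shifts it positive.  The
cue-reliability query (lamina PAR behind petiole R:FR ∈ [0.95, 1.05])
restricts to the second half of the run, where the cue is in steady use;
pooled over all days the highest density is dominated by early-development
transients because its canopy leaves the window within ~3 weeks.

## Known limitations

Single light quality cue (no blue light), no mechanical or hydraulic cost of
elongation, no organ-rank dependence of potential sizes, density-independent
leaf initiation, blade-centre perception, no flowering or multi-generation
dynamics, and no validation against real Arabidopsis stands — the package
reproduces the *structure* of the analysis (feedback between phenotype and
light climate, and the resulting density-dependent selection on plasticity),
not organ-level quantitative fidelity.
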