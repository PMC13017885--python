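# Methods

## Scope and state representation

`wheatgdt` simulates a single wheat plant as six functional organ
compartments (roots, senescent leaf, mature leaf, growing leaf, emerging
leaf, grain) over daily time steps. Organs hold structural dry matter,
labile C and N stores, an accumulated defense-compound pool, a local
stress signal S₀ and a defense coefficient D. All inter-organ flows pass
through a whole-plant common pool of labile C and N; there are no direct
organ-to-organ transfers. Leaf area is structural mass × SLA
(0.025 m² g⁻¹ by default); no separate expansion model is used.

The daily update has three ordered phases — source fluxes and signal
updates (time t), transfers to the pool and signal integration (t+δ),
allocation and growth (t+1). The intermediate instant has no duration:
at the scale of a single herbaceous plant, transport of assimilates and
information is fast relative to a day, so the phases only impose an
order of computation and a one-day delay between perception and
allocation. Source downregulation decided on day t therefore takes
effect on day t+1.

## Gas exchange

Leaf CO₂ assimilation follows the standard biochemical model for C3
photosynthesis: the gross rate is the minimum of the Rubisco-limited
rate `Vcmax(Ci−Γ*)/(Ci+Kc(1+O/Ko))`, the electron-transport-limited rate
`J(Ci−Γ*)/(4Ci+8Γ*)` with J the smaller root of the non-rectangular
hyperbola `θJ² − (αI+Jmax)J + αI·Jmax = 0`, and the triose-phosphate
limit `3·TPU`; day respiration Rd is subtracted. All kinetic parameters
scale from 25 °C by simple Arrhenius functions
`p = p25·exp[Ea(T−298.15)/(298.15·R·T)]`; default kinetics (Kc 404.9
µmol mol⁻¹, Ko 278.4 mmol mol⁻¹, Γ* 42.75 µmol mol⁻¹ and the
corresponding activation energies) are standard tobacco-derived values
used widely for C3 crops, with wheat-typical capacities Vcmax25 = 90,
Jmax25 = 170, TPU25 = 11 µmol m⁻² s⁻¹.

Stomatal conductance uses the Ball–Woodrow–Berry relation
`gs = g0 + g1·max(A,0)·hs/Cs` with g0 = 0.01 mol m⁻² s⁻¹ and g1 = 9.
The raw linear form drops below g0 for negative A, so A is clamped at
zero in the conductance — the conventional night-time fix. Boundary
layer conductance is omitted (Cs = Ca, hs = air relative humidity).
The coupled system is closed by the diffusion equation
`Ci = Ca − 1.6·A/gs` and solved by bisection on Ci between just above
Γ* and `Ca + 1.6·Rd/g0` (the dark solution lies above ambient), to a
bracket width of 1e-6 µmol mol⁻¹. Bisection was chosen over fixed-point
iteration for guaranteed convergence; the test suite cross-checks it
against a 10⁵-point brute-force scan of the residual.

Leaf-level rates (µmol m⁻² s⁻¹) convert to plant-level daily fluxes as
`A × daylight seconds × leaf area × 12e-6 g C µmol⁻¹`, with daylight
length a configuration constant (12 h). The generator's PAR is a
midday-equivalent value applied over the whole photoperiod, so
"assimilation" in the ledger is the leaf's daily net carbon export; on
dark days the negative flux is booked as leaf dark respiration paid
from the pool, then from the leaf's own store. Known limitations: no
peaked (high-temperature deactivating) Arrhenius variant, no mesophyll
conductance, no C4 pathway, no energy-balance leaf temperature (leaf =
air + configurable offset).

## Nitrogen uptake

Root nitrate uptake combines a saturating high-affinity system
(Vmax = 0.02 g N g⁻¹ root d⁻¹, Km = 0.05 mol m⁻³) and a linear
low-affinity system (k = 0.002 g N g⁻¹ root d⁻¹ per mol m⁻³, optional
activation threshold, default none — the linear form already vanishes
at low concentration). Regulation by root carbon status uses a bounded
saturating factor `f_C = f_min + (1−f_min)·c/(K+c)` of the root labile-C
concentration (K = 0.05 g C g⁻¹, f_min = 0.1); setting f_min = 1
disables it. Soil nitrate is an exogenous driver and is never depleted
by uptake — soil N is treated as non-limiting by assumption. Units are
per gram of root structural mass.

## Respiration

Maintenance respiration is `R_maintenance = R_basal + D·C_defense` per
organ and day, with `R_basal = m_base·mass·Q10^((T−25)/10)`. The
defense term makes the energetic cost of defense activation explicit
instead of hiding it in a catch-all maintenance coefficient; C_defense
(0.0055 g C g⁻¹ d⁻¹ at D = 1) is interpreted per unit organ mass so
that both defense cost channels scale the same way as the defense sink
(D × mass). Basal coefficients are 0.015 g C g⁻¹ d⁻¹ for active leaves,
0.010 for roots, 0.008 for grain, 0.004 for the senescent leaf; Q10 = 2.
Growth respiration is tied to the growth yield Yg = 0.75 g DM per g
C-substrate: building Δm grams costs `c_per_g·Δm/Yg` g C of which
`c_per_g·Δm(1−Yg)/Yg` is respired. An itemized "process-sum" accounting
mode (Σ activity × metabolic cost) is available as a diagnostic
alternative; the historical photosynthesis-proportional formulation is
deliberately not the default since the model's own maintenance law is
the basal + defense form.

## Stress signals and defense dynamics

Stress enters as per-day, per-organ intensities in [0,1] from
trapezoidal events (linear ramp up over `ramp_days` from `start_day`,
plateau through `end_day`, linear ramp down after). Within a stress
class, overlapping stressors combine by maximum; the biotic and abiotic
class signals then combine by a configurable rule: capped addition, a
nonlinear response surface `min(s_a+s_b+γ·s_a·s_b, 1)` (γ > 0
synergistic, γ < 0 antagonistic), or dominance (`max`). When proxy
observations are used instead (hormone levels, transcriptional markers,
NIRS-type indicators, all normalized to [0,1]), S₀ is their
weight-normalized mean.

The defense coefficient tracks a Hill dose–response target
`d_max·s₀^h/(s50^h+s₀^h)` (d_max = 0.8, s50 = 0.4, h = 2 — sigmoidal,
saturating at high stress) through first-order dynamics
`D' = D + (1−e^(−k))·(target−D)` with induction rate 0.5 d⁻¹ and slower
relaxation 0.2 d⁻¹. The asymmetry yields hysteresis (the decay branch of
a symmetric stress pulse lies above the time-mirrored rise) and a
priming-like behaviour (residual D after a first pulse accelerates the
response to a second). A categorical mode snaps the continuous response
to {0, d_max/2, d_max} by terciles, as a calibration convenience.
D is bounded by 1 so it can multiply capacity-type constants. Genotypes
are represented purely by re-parameterization of this chain. A grid
search utility recovers (s50, k_induction) from a noisy D time series;
with observation noise σ = 0.02 both are recovered within 10 %.

## Allocation

The integration unit aggregates organ signals into a plant status
(mass-weighted mean and max of S₀) and directives: stage-dependent base
priorities (vegetative: emerging/growing leaves and roots high, grain
zero; reproductive: grain dominant) modulated per organ by
`base × (1 + β·s₀)` with β = 0.5, so stressed organs attract resources;
photosynthesis and uptake are downregulated by `σ_max·s₀` (σ_max = 0.3)
of the source organ's own stress.

Pool sharing treats C and N independently: if the pool covers total
demand every organ receives its demand; otherwise organ i receives
`min(demand_i, pool·w_i·demand_i/Σw_j·demand_j)` in a single pass —
leftovers legitimately persist in the pool, which also keeps the rule
order-independent. Organs with zero effective priority are excluded
even in surplus (a pre-anthesis grain receives nothing). Unused pool
resources persist indefinitely.

Within an organ the partition is hierarchical: maintenance is funded
first, from the delivery and then from the organ's internal labile
store; if both fall short, a deficit is logged and defense and growth
receive nothing that day (deficits never kill organs — mortality is out
of scope). A fraction φ = D of post-maintenance carbon is offered to
defense synthesis — using the already-dynamic D avoids introducing a
second free response function — capped by the defense demand
`D × mass × s_def_rate` (s_def_rate = 0.016 g compound g⁻¹ d⁻¹).
Defense compounds are a two-class mix: 70 % phenolic-like, costed at
2.5 g glucose-equivalents (1.0 g C) per g, and 30 % protein-like at
0.53 g C and 0.151 g N per g (protein C:N 3.5). The remainder is offered
to growth, realized at fixed tissue stoichiometry: one gram of new
structure costs `c_per_g/Yg` g C and `c_per_g/tissue_cn` g N, with
c_per_g = 0.45 (0.44 grain) and tissue C:N 12.5 for leaves, 25 for
roots, 20 for grain. Growth takes the minimum of the C-limited,
N-limited and potential masses; the surplus of the non-limiting element
is returned. Returned resources first top the organ's labile store up
to a target concentration (a small buffer that keeps root carbon status
meaningful and lets organs ride out short shortfalls), then flow back
to the pool. Every step conserves each element exactly:
maintenance + defense + growth + returned = delivered.

Sink strengths follow normalized beta functions of organ age,
`x^(a−1)(1−x)^(b−1)` scaled to peak 1 over an organ-specific window.
Leaf classes and grain have *absolute* potential rates (growing leaf
0.10 g d⁻¹ over 90 d, emerging leaf 0.05 g d⁻¹ over 70 d, grain
0.20 g d⁻¹ over 50 d from anthesis) because an organ size class has a
finite expansion potential; the root sink is *relative*
(0.09 d⁻¹ × root mass) over the vegetative window (85 d). This split is
a deliberate design choice: an early all-relative parameterization let
leaf growth feed back into leaf area and produced unbounded exponential
growth, while all-absolute sinks made mid-season growth demand-limited
so that stress had no biomass effect. With a mass-proportional root
sink the root system absorbs assimilate surplus, mid-season growth
stays source-limited, and stress treatments translate into biomass
differences. A consequence is a root-heavy final allocation; the root
compartment should be read as the whole non-leaf structural sink
(including tillers and stem, which are not separate compartments).

Organ identities are fixed: leaves do not progress between the
emerging/growing/mature/senescent classes, and the senescent leaf only
exports fractions of its labile stores (r_C = 0.03, r_N = 0.05 per day,
accelerated by `1 + a_sen·S_plant`); its structural mass never changes.

## Phenology

A single configured anthesis day (default 80) switches the plant from
vegetative to reproductive stage and the priority table with it. No
thermal-time development is modeled.

## Synthetic environment

The weather generator produces midday-equivalent PAR and air temperature
as seasonal sinusoids (period 365 d, phase set so a 150-day run spans a
cool spring start of ~6 °C to ~21 °C) with seeded Gaussian noise
(sd 1.5 °C, 150 µmol m⁻² s⁻¹), AR(1) relative humidity (mean 0.65,
persistence 0.7), constant CO₂ (420 µmol mol⁻¹) and constant soil
nitrate (2 mol m⁻³, optional linear depletion). Leaf temperature equals
air temperature by default. What it does *not* emulate: weather
autocorrelation beyond humidity, sub-daily light dynamics, rainfall or
soil water, within-canopy gradients, or correlated stress/weather
(heat waves are scheduled as stress events, not emergent from the
temperature series). Tests passing under this generator therefore show
internal consistency and qualitative stress physiology, not predictive
skill on field data.

## Scenario experiments and calibration

The default scenario set compares control, a heat event (days 55–85,
peak 0.2, all organs), a pathogen event (days 60–80, peak 0.2, mature
and growing leaves) and their combination, all sharing one seed and
hence identical weather. The non-additivity index
`NAI = [Δ_combined − (Δ_a + Δ_b)]/biomass_control` is ≈ 0 (|NAI| well
below the 0.02 tolerance) when the stress signals combine with γ = 0,
and positive (synergistic) at γ = 1. The mild peak intensities are
deliberate: they keep the single-stress responses in the near-linear
range of the damage response, where the additive reference is
meaningful; strong treatments drive the response into saturation and
make any combination sub-additive regardless of the interaction term.

Defense costs are calibrated so that, with D clamped to 1 on the mature
leaf during a sustained 20-day pathogen challenge (the standard
challenge scenario, days 90–109), the defense respiration term plus
synthesis substrate consume 11–12 % of the leaf's assimilated carbon —
inside the 10–15 % physiological range for pathogen-challenged tissue —
stable to within ±0.4 percentage points across weather seeds.

## Numerical choices and degenerate inputs

* Bisection tolerance 1e-6 µmol mol⁻¹ on Ci; a missing sign change
  raises an error reporting the bracket.
* Daily C and N ledgers close to ≤ 1e-9 relative (observed ~1e-14);
  the audit recomputes closure from recorded totals and fluxes alone,
  so it also works on an exported trajectory CSV.
* Capped-proportional pool shares are rescaled if rounding pushes their
  sum one ulp above the pool; within-organ consumption is computed as a
  sequential remainder chain so stocks cannot go negative by rounding.
* Zero-mass organs demand, respire and take up nothing; a zero-mass
  plant is rejected at status integration. Horizon 0 yields a
  trajectory containing only the initial snapshot.
* θ = 0 in the light response falls back to the rectangular hyperbola;
  beta exponents a = b = 1 give a flat sink strength.
* All stochasticity flows from the single scenario seed through
  `numpy.random.default_rng`; runs are bit-reproducible.

## Known limitations

No organ mortality or mechanistic senescence; no soil water or soil N
dynamics (both non-limiting by assumption); no explicit hormone state
variables (SA/JA/ABA are abstracted into S₀ and D); no 3D architecture,
light interception geometry or canopy feedback; no sub-daily dynamics.
Unused pool resources accumulate without cost late in the season once
sink windows close. Priority weights are free parameters with no direct
measurement; they were chosen to express the usual vegetative/
reproductive sink hierarchy, not fitted to data.
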