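# Methods

`canopyopt` implements an eco-evolutionary optimality (EEO) model of daily
stand-level gross primary production (GPP) and canopy transpiration (E_c)
for boreal conifer forest under joint nitrogen and water limitation. Two
plastic traits of a top-of-canopy needle — stomatal conductance g_s
(adjusted twice per day) and mass-based leaf N concentration N_mf (adjusted
weekly) — are chosen to maximize a fitness proxy balancing carbon gain,
hydraulic embolism risk, and the carbon costs of building and supplying
photosynthetic capacity.

## Leaf photosynthesis

Assimilation follows the electron-transport-limited Farquhar rate under the
coordination (co-limitation) hypothesis,

    A = (J/4) (c_i − Γ*) / (c_i + 2Γ*),

balanced against Fick-law CO₂ supply A = g (c_a − c_i)/P with the lumped
stomatal-plus-mesophyll conductance g = 0.42 g_s. The balance is a quadratic
in c_i; the greater root is physical (c_i → c_a as demand vanishes). Both
quadratics in the module (the c_i balance and the non-rectangular hyperbola
for J) are solved with the cancellation-safe `q = −(b + sign(b)√disc)/2`
formulation.

Temperature responses: Γ* follows an Arrhenius curve anchored at
Γ*_ref = 4.17 Pa for T_ref = 298 K (kept at the printed 298, not 298.15;
public interfaces use °C and convert internally); J_max carries a peaked
activation/deactivation multiplier f_Jmax(T) with E_A = 47.4 kJ mol⁻¹,
E_D = 200 kJ mol⁻¹ and optimum 305 K, equal to 1 at the optimum.

Seasonal acclimation: a delayed temperature S_t follows first-order dynamics
S_t = (1 − 1/τ) S_{t−1} + T_t/τ with S_0 = T_0 and τ = 14.87 days; the
activation factor X_t ramps linearly from 0 at S_min to 1 at S_min + ΔS
(ΔS = 18.29 °C), with closed interval ends (S_t ≤ S_min → 0,
S_t ≥ S_min + ΔS → 1). S_min is not constrained by the published parameter
tables; it defaults to 0 °C and is exposed in the config. Both the quantum
yield (α = X_t α_season, α_season = 0.19) and the capacity
J_max = X_t a_Jmax N_mf f_Jmax(T) scale with X_t; a_Jmax = 0.02
mol m⁻² s⁻¹ per kg N kg⁻¹ links capacity linearly to leaf N.

## Hydraulics

Leaf-area transpiration is E = 1.6 g_s VPD / P. Soil water potential comes
from the Brooks–Corey retention curve ψ_s = ψ_a S_e^(−1/λ),
S_e = (θ − θ_r)/(θ_s − θ_r) (ψ_a = −0.098 MPa, λ = 1, θ_s = 0.41,
θ_r = 0.006). Printed site tables truncate ψ_s toward zero at two decimals
(e.g. θ = 9.9 % → ψ_s = −0.4257, printed −0.42); the tests encode that
convention. The pre-dawn canopy potential subtracts the gravitational head,
ψ_c,pd = ψ_s − Hρg·10⁻⁶ with ρ = 997 kg m⁻³ and g = 9.82 m s⁻² exactly as
published.

The soil–canopy conductance declines along the vulnerability curve
P(ψ) = (1/2)^((ψ/ψ50)^b) (ψ50 = −2.7 MPa, b = 2.15), and the effective
conductance over the traversed interval is its Simpson-rule mean,
k_sc = k_sc,max · mean(P; ψ_c, ψ_c,pd). Darcy's law closes the system:
ψ_c = ψ_c,pd − E/k_sc. The solver iterates
k⁽ⁿ⁺¹⁾ = k_sc,max · mean_Simpson(P; ψ_c(k⁽ⁿ⁾), ψ_c,pd) from the zero-flux
initial guess k⁽⁰⁾ = k_sc,max P(ψ_c,pd) (exact in the E → 0 limit). Because
the supply curve E_sup(ψ_c) = k_sc,max ∫ P dψ is strictly monotone with a
finite asymptote, the solution is unique whenever demand is below the
asymptotic supply; the iteration is then monotone decreasing in k and a 0.5
damping step (applied on detected oscillation) is a safeguard rather than a
necessity. Numerical settings: 50 Simpson panels (20 in calibration loops),
relative tolerance 10⁻⁹, 200 iterations maximum, then a no-solution
("runaway embolism") error. Panel counts were chosen so that the solved ψ_c
agrees with an adaptive-quadrature + bisection reference to better than
10⁻⁵ MPa across the tested driver space.

The hydraulic-risk discount is linear in conductance,
k_cost = (k_sc − k_crit)/(k_sc,max − k_crit) with k_crit = 0.12 k_sc,max
(the commonly observed lethal 88 % conductivity loss). The critical
stomatal conductance g_s,crit — where P(ψ_c) = 0.12 — is computed in closed
form: invert the vulnerability curve for ψ_crit, take
E_crit = k_sc(ψ_crit) (ψ_c,pd − ψ_crit) from Darcy, and divide by
1.6 VPD / P. This is algebraically the same condition as a root search on
g_s and is verified against a dense grid scan in the tests.

## Trait optimization

The instantaneous fitness proxy is G = A·k_cost − (N_r + N_u) J_max, with
N_r = 0.0056 (dark-respiration-to-J_max ratio) and N_u the treatment-
specific N-uptake cost (0.0 fertilized, 0.012 control in the published
estimates). Daily fitness uses a two-segment daily model (SDM-2): daylight
is split at solar noon into two equal segments represented by their
midpoint drivers. Within a day, radiation follows a half-sine integrating
to the daily total I₀; temperature follows a sine from T_min at sunrise
peaking at T_max at 0.75 Δt_g (clipped to [T_min, T_max]); VPD is rebuilt
per instant from the Magnus saturation pressure minus a constant daily
actual vapor pressure e_a = e_sat(T_mean) − VPD_mean (clamped at 0); CO₂
and soil moisture are constant within a day. The exact segment placement
and weights of the original segmented-day scheme are not fully specified in
the main published text; this symmetric midpoint variant is isolated behind
the `DiurnalSegment` builder so it can be swapped.

The two-step weekly routine: step 1 maximizes the block integral of G over
(N_mf, g_s,am, g_s,pm) on the week-average day (arithmetic driver means;
block-mean activation factor), step 2 fixes N_mf and re-optimizes each
day's pair from the step-1 starting point. Bounds are
0.007 ≤ N_mf ≤ 0.05 and 0.001 ≤ g_s ≤ g_s,crit per segment. The optimizer
is bounded L-BFGS-B from three deterministic starts (bounds midpoint, a
low-g_s start, a high-N start); it is seedless and deterministic, and its
step-1 optimum is checked against a 40³ grid oracle (evaluated exactly but
cheaply via the morning/afternoon separability of the objective). The
weekly integral covers daylight only — G contains the assimilation term, so
night-time is excluded by construction; a configurable
`include_night_cost` flag records the alternative reading. Trailing partial
weeks (< 7 days) are optimized as their own block. Blocks where even the
stomatal floor violates the hydraulic threshold fall back to the floor and
are flagged, never fatal.

A `fast` fidelity mode (single multistart, step-1 stomatal pair applied to
every day, 20 Simpson panels) exists for calibration loops where the trait
optimization is re-run thousands of times inside a global optimizer.
Synthetic-data recovery experiments generate observations at the same
fidelity used for refitting, so the estimation exercise is internally
consistent.

## Upscaling

J_max and g_s are assumed to acclimate proportionally to irradiance down
the canopy, collapsing the vertical integral of any leaf rate to the
top-leaf rate times (1 − e^(−k·LAI))/k, k = 0.52. Top-leaf incident
irradiance is taken as k I₀(t)/(1 − m) with leaf transmittance m = 0.05
(Beer-law interception per unit leaf area at the canopy top); the constant
factor of this choice is absorbed by a_Jmax under calibration. Canopy
conductance is g_C = 1.6 g_s,top (1 − e^(−k·LAI))/k and E_c = g_C VPD/P,
boundary-layer conductance neglected. Carbon converts at 12.011 g mol⁻¹,
water at 18.015 g mol⁻¹ (1 kg m⁻² = 1 mm). Ecosystem GPP adds the
understory through GPP_e = ζ·GPP_c with ζ = 1.2 (fertilized) and 1.13
(control) as configuration inputs — the understory-LAI derivation behind
those numbers is not reproduced.

## Calibration

Observation errors are Laplace with prediction-linear scale a + b·M; the
log-likelihood Σ w_i [−log 2(a+bM) − |y−M|/(a+bM)] is maximized (log form
for numerics; identical argmax). Weights: GPP 1.5, E_c and N_mf 1.0. Error
scales default to the published values (GPP a=0.41, b=0.08; E_c
0.069/0.15 fertilized and 0.043/0.18 control; N_mf a=0.0023, b=0). Leaf N
enters as a per-treatment seasonal mean compared to the mean modeled N_mf.
In the default sharing scheme N_u and k_sc,max are estimated per treatment
and all other free parameters are shared. The global optimizer is seeded
differential evolution (scipy) with Sobol initialization; default free-
parameter bounds (N_u ∈ [0, 0.05], α_season ∈ [0.05, 0.5],
a_Jmax ∈ [0.005, 0.1], ΔS ∈ [1, 30] °C, τ ∈ [2, 40] d,
k_sc,max ∈ [10⁻⁴, 5·10⁻³]) are package choices, documented and
configurable, as the source reports none.

Validation uses repeated random holdout: by default round(0.2·n) points per
repeat (588 → 118; an absolute-count switch reproduces a 119-point split),
disjoint train/validation, independent sub-seeds per repeat. Metrics are
RMSE, MAPE (percent, zero observations excluded and counted) and R².
Ablations: static leaf N (frozen at the baseline season median), pooled
leaf N across treatments, a single shared N_u, and static soil moisture
(series replaced by its mean), each reported as paired R² changes and mean
predicted N_mf per treatment.

## Synthetic weather

The generator emulates the study site's growth-season forcing at
64.17° N: temperature is a seasonal cosine (mean 11 °C, half-range 8 °C,
peak near day-of-year 200) plus AR(1) noise (φ = 0.65, σ = 2.2 °C);
radiation is a clear-sky envelope tied to squared relative day length
(peak 58 mol m⁻² d⁻¹) times an AR(1) cloudiness fraction; VPD comes from
Magnus saturation pressure and AR(1) relative humidity coupled to
cloudiness, so bright days are drier; soil moisture is a persistent AR(1)
regime (mean 0.18, φ = 0.92) with an optional scheduled drought dip; CO₂
ramps linearly from 40.5 to 39.0 Pa; day length uses the CBM formula with
daylength coefficient p = 0 (sun-center), which reproduces the site's
printed upper range (~20.3–20.5 h at midsummer). Every series is clipped to
the site-observed driver bounds. The generator reproduces realistic ranges,
seasonality and the radiation–VPD cross-correlation, but not precipitation
physics, multi-scale soil-moisture memory, or observed spatial coherence
between drivers — so tests passing on synthetic seasons demonstrate
correct model mechanics and directional responses, not site-level
predictive skill.

## Problem sizes in the test suite

The shipped tests run the heavy experiments at desk scale as the package's
own study conditions: oracle cross-checks use 500 random hydraulic draws
and 5 synthetic weeks; the parameter-recovery experiment uses two 42-day
spring-containing seasons per treatment with published noise scales and a
reduced differential-evolution budget; the N-uptake-ordering experiment
repeats a two-parameter refit over 10 seeds. The trait–weather correlation
diagnostics use an 84–112 day synthetic season.

## Known limitations

No within-canopy N profile, energy balance, boundary-layer conductance, or
multi-layer radiative transfer; no hydraulic-damage accumulation or xylem
refilling (severe multi-week droughts are outside the model's trust
region); rooting depth is implicit in the soil-moisture forcing; the SDM-2
segment placement is a documented stand-in where the original scheme's
supplement-level detail was unavailable; understory GPP enters only through
the constant ζ factor.
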