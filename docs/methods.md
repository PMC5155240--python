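# Methods

## Scope and design

`nsatcn` is a point-scale annual-time-step reduction of a coupled
carbon–nitrogen terrestrial ecosystem model, built to isolate one mechanism:
the response of the carbon budget to nitrogen *saturation* — deposition in
excess of an ecosystem's empirical critical load. Everything that a full
land-surface model would resolve around that mechanism (sub-daily
photosynthesis, canopy radiative transfer, soil physics, vegetation
dynamics, fire) is deliberately replaced by smooth annual response functions,
so that the nitrogen-control pathway is exact and testable while the rest is
merely plausible. Results on the synthetic ensemble are therefore
*sign- and ratio-level* statements, not global magnitudes.

## Carbon core

Five carbon pools (leaf, wood, root, litter, SOC; g C m⁻²) evolve annually:

- Potential NPP: `NPP_pot = NPP_ref · f_T(T) · f_W(P) · f_C(CO₂)` with
  `f_T = exp(0.03 ΔT − 0.001 ΔT²)`, `f_W` a saturating
  precipitation response with half-saturation 400 mm yr⁻¹, and the β-factor
  form `f_C = 1 + 0.5 ln(CO₂/296 ppm)`. All factors are 1 at the biome's
  reference climate, so `NPP_ref` (per-biome, 150–1100 g C m⁻² yr⁻¹) is the
  biome's reference productivity.
- Realized NPP = K_P · NPP_pot. The scaling is deliberately linear so the K_P
  floor (0.824) maps *exactly* onto the parameterized maximum NPP reduction
  (17.6 %).
- Allocation fractions per biome (e.g. forest 0.30/0.40/0.30
  leaf/wood/root) are multiplied by `1 + s·(M_i − 1)` with
  `M = (1.10, 1.25, 0.65)` and renormalized; the saturation degree
  `s = clamp((N_M − N_MS)/(N_Mmax − N_MS), 0, 1)` ramps the published
  endpoint shifts in linearly, since only the endpoints are constrained by
  observation syntheses.
- Turnover: leaf 1.0, root 0.5, wood 0.02 yr⁻¹. Litter and SOC decompose
  first-order (base rates 0.5 and 0.02 yr⁻¹) times a temperature–moisture
  scalar (1 at reference climate) times K_M; 30 % of decomposed litter is
  humified into SOC, the rest plus all SOC decomposition is heterotrophic
  respiration. Because both rates scale linearly with K_M, Rh responds
  exactly proportionally to it (the 15 % floor → 15 % Rh reduction).
- Identities held to machine precision every step: NEP ≡ NPP − Rh and
  Δ(total C) ≡ NPP − Rh.

GPP is reported diagnostically as NPP/0.45.

## Nitrogen cycle

Three pools: soil mineral N (N_M), soil organic N, plant N. Fluxes per year:

- deposition (forcing) and a constant biological fixation input
  (0.4 g N m⁻² yr⁻¹, see below);
- gross mineralization = decomposed C × the *actual* N:C ratio of the
  combined litter+SOC pool. Using the dynamic pool ratio (rather than fixed
  tissue ratios) is what gives the soil organic N pool a well-defined
  equilibrium — with fixed ratios organic N drifts without bound;
- immobilization = K_1 × 0.2 × gross mineralization (returned to organic N);
- plant uptake = new-tissue demand (allocation fluxes divided by tissue C:N
  of 30/150/60 for leaf/wood/root), capped at 90 % of the mineral N
  available that year; if the cap binds, NPP and its allocation are scaled
  down proportionally;
- leaching = 0.2 yr⁻¹ × N_M (first-order);
- litterfall N follows the plant pool's actual N:C ratio (again so the plant
  N pool has a unique equilibrium rather than a neutral drift mode).

Absent clipping, total N changes by exactly
(deposition + fixation − leaching) per year; pools that would go negative
are clipped at zero and the deficit logged.

### Why constant fixation, and why 0.4

Biological N fixation is a real, roughly climate-stationary background input
(~0.1–2 g N m⁻² yr⁻¹ across biomes); the package treats it as a constant
boundary condition, not a dynamic process. It matters for two reasons.
First, realism: without any non-deposition N source, a pre-industrial
ecosystem forced with 0.05 g N m⁻² yr⁻¹ deposition equilibrates in a state
far more nitrogen-starved than any real biome. Second, stability: that
starved equilibrium sits on the steep rising limb of the modifier curves,
where the annual explicit step has a feedback gain large enough to produce a
persistent limit cycle. With fixation at 0.4 g N m⁻² yr⁻¹ the
pre-industrial mineral-N equilibrium ((0.05 + 0.4)/0.2 = 2.25 g N m⁻²) sits
just on the stable K = 1 plateau: mildly N-sufficient, as temperate
ecosystems were. A pleasing consequence of deriving N_MS with the same
boundary condition is that `N_MS = (CL + fixation)/leaching` at
equilibrium, so the *pool* crosses its saturation threshold exactly when
*deposition* crosses the critical load — the two definitions of saturation
coincide up to transient lag (~5 yr, the mineral-pool turnover time).

## Modifier curves

The three modifiers are continuous piecewise-linear functions of N_M,
bounded in (0, 1]:

- legacy mode: from 0.05 at N_M = 0 linearly to 1 at 2 g N m⁻², 1 beyond;
- saturation mode: the same rising limb to `min(2, N_MS)`, a plateau of 1
  through N_MS, linear decline to the floor at N_Mmax, constant beyond.

Floors: K_P 0.824, K_M 0.85, K_1 0.85. The K_1 floor is set equal to K_M's
because immobilization has no separately published saturation response; the
immobilization pathway is weak (immobilization is only 20 % of
mineralization), so this choice has little leverage. `N_Mmax = 2 × N_MS` per
site — the maximum available mineral N is unobserved, and the factor 2 makes
the decline's span scale with the site's own threshold. Both choices are
config-exposed (`ModelParams`). The two modes agree below
`min(2, N_MS)`; derived N_MS values under default parameters (6.5–9.5
g N m⁻²) always exceed the 2 g N m⁻² ceiling, so in practice the legacy and
saturation curves share the entire rising limb.

## Critical loads

The shipped table holds empirical loads for 15 vegetation types ×
{USA, China, Europe} plus a computed "Other" column: the mean of the row's
*positive* empirical cells, in exact decimal arithmetic with ties rounded
down (0.695 → 0.69). Zero-valued cells (desert, polar) mark "no tolerated
load" and are excluded from the average — including them cannot reproduce
the published Other values, excluding them reproduces every one.
Classification is strict: deposition exactly at the load is not saturation.

## Synthetic forcing

Monthly climate per site: sinusoidal seasonal cycle around a biome-template
mean, AR(1) interannual anomalies (φ = 0.3, σ = 0.6 °C), +0.02 °C yr⁻¹
trend after 1970, mean-one lognormal precipitation noise (σ = 0.25), and
bounded Gaussian cloud/wind/wet-day/humidity fields. CO₂ is flat at 296 ppm
to 1900 then rises quadratically to 387 ppm in 2009. Deposition
trajectories: a logistic US plateau (to 1.8 g N m⁻² yr⁻¹), a Gaussian
European hump (peak 1985, width 15 yr), an accelerating Chinese/Indian rise
built from non-negative noisy increments (hence monotone for *every* seed),
and flat background. Determinism: every stream is keyed by (seed, site id,
variable name), so adding sites never perturbs existing ones.

What the generator does *not* emulate: spatial correlation between sites,
observed drought/heat extremes, monthly deposition seasonality, or any real
geography. Passing tests therefore demonstrate the mechanism's internal
correctness and sign structure, not agreement with observations.

## Protocol and scenarios

Spin-up runs the climatological year (first 30 years' monthly means, CO₂ at
its first-year value, deposition 0.05 g N m⁻² yr⁻¹) to equilibrium —
relative pool change < 10⁻⁶ yr⁻¹, cap 5000 years, typically ~700 — then the
pre-1901 years are reported at that equilibrium. 1901–1969 uses transient
climate and CO₂ with deposition held at its 1970 value; 1970–2009 is fully
dynamic. Frozen-driver scenarios repeat the single 1970 value/monthly cycle
from 1970 onward. The no-saturation scenario (NNS) pins all three modifiers
to 1 only in site-years where deposition exceeds the critical load; because
spin-ups are shared and the pinning rule is local, NNS is bit-identical to
the reference at never-saturated sites.

Attribution: driver contribution = reference run − frozen-driver run
(saturation: NNS − NCC), reported as mean ± interannual SD over 1970–2009,
absolute and as a percentage of the reference mean, area-weighted across
sites.

## Problem sizes

The shipped study uses 8 sites × 159 years × 6 scenarios (plus one
equilibrium derivation per site), which completes in a few seconds on one
CPU; the property suite adds 2 × 10⁴ randomized conservation checks. These
sizes give every qualitative result headroom while keeping the full test
suite fast.

## Known limitations

- On the saturation-weighted four-archetype ensemble the *net* deposition
  effect (NCC − NNC) is negative: the saturation penalty outweighs
  fertilization because the ensemble deliberately over-samples saturated
  regions. A globally representative ensemble, dominated by N-limited sites,
  would flip this sign; the per-driver saturation and CO₂ signs do not
  depend on the ensemble composition.
- Annual explicit time stepping: the modifier feedback is stable only
  because the pre-industrial equilibrium sits on the K = 1 plateau; runs
  with fixation + deposition below ~0.4 g N m⁻² yr⁻¹ can oscillate.
- No nitrification/denitrification split, no gaseous N loss, no dynamic
  fixation, no phenology or disturbance; mineral-N magnitudes (2–25 g N m⁻²)
  are internally consistent but higher than field values, since the pool
  absorbs fluxes a finer model would route through fast sub-annual sinks.
- GPP is a fixed ratio of NPP and carries no independent information.
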