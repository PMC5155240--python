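# nsatcn

Nitrogen saturation in a coupled carbon–nitrogen ecosystem model: a
point-scale simulator plus analysis pipeline for asking how chronic nitrogen
deposition in excess of ecosystem critical loads alters net primary
productivity (NPP) and net ecosystem productivity (NEP), and for attributing
the productivity response to individual global-change drivers (CO₂,
temperature, precipitation, N deposition, N saturation).

It is written for ecosystem/biogeochemistry modellers who want a small,
fully-tested testbed of the saturation mechanism without running a full
dynamic global vegetation model.

## The model

Carbon and nitrogen are coupled through three multiplicative modifiers of the
soil mineral nitrogen pool *N*_M (g N m⁻²):

- **K_P** scales plant biomass construction (realized NPP = K_P · NPP_pot),
- **K_1** scales soil N immobilization,
- **K_M** scales soil organic matter mineralization (and hence heterotrophic
  respiration Rh).

In *legacy* mode the modifiers only encode N deficit: they rise from a small
positive value at *N*_M = 0 and are fixed at 1 once *N*_M ≥ 2 g N m⁻².
In *saturation* mode they additionally penalize N excess: each modifier holds
1 up to the saturation onset *N*_MS, then declines linearly to a floor at the
maximum available mineral N *N*_Mmax and stays there. The floors encode mean
observed saturation responses: K_P → 0.824 (−17.6 % NPP), K_M → 0.85 (−15 %
SOC decomposition), K_1 mirroring K_M. Under saturation, carbon allocation
also shifts: −35 % to roots, +10 % to leaves, +25 % to wood (before
renormalization), ramping linearly in *N*_M between *N*_MS and *N*_Mmax.

*N*_MS is not a free parameter. Each site's empirical N critical load (CL,
g N m⁻² yr⁻¹; shipped for 15 vegetation types × USA/China/Europe/Other) is
converted to a pool threshold by running the model to equilibrium with
deposition pinned at the CL and all modifiers held at 1; the equilibrium
mineral N is *N*_MS. A site-year is *classified* N-saturated when deposition
strictly exceeds the CL.

Around this core sit: a seeded synthetic-forcing generator (monthly climate
with seasonal cycle + AR(1) anomalies, a smooth CO₂ ramp 296→387 ppm, and
region-typed deposition trajectories — persistent US plateau, European
1980s hump, accelerating Chinese/Indian rise, low background); a three-stage
protocol (spin-up to carbon equilibrium at 0.05 g N m⁻² yr⁻¹ deposition,
1901–1969 transient with deposition at its 1970 level, fully dynamic
1970–2009); and six factorial scenarios (NCC all-dynamic; NNC/CNC/TNC/PNC
freeze one driver at 1970; NNS pins the modifiers to 1 in saturated
site-years).

## Worked example

```python
from nsatcn import diff_scenarios, run_study

study = run_study(seed=42, n_sites=8)          # 6 scenarios, 1851-2009
d = diff_scenarios(study.runs["NNS"], study.runs["NCC"], "npp",
                   weights=study.ensemble.areas)
print(f"saturation cost: {d.mean:.1f} ± {d.sd:.1f} g C m-2 yr-1 "
      f"({d.pct:.1f}% of NPP)")
print({k: round(v, 2) for k, v in study.nms.items()})
```

prints

```
saturation cost: 24.6 ± 8.2 g C m-2 yr-1 (3.7% of NPP)
{'US-TF-00': 6.5, 'EU-TF-00': 9.5, 'CN-GR-00': 8.25, 'BO-BG-00': 7.1,
 'US-TF-01': 6.5, 'EU-TF-01': 9.5, 'CN-GR-01': 8.25, 'BO-BG-01': 7.1}
```

i.e. on this eight-site ensemble the saturation response depresses
area-weighted NPP by ~25 g C m⁻² yr⁻¹ (the no-saturation run NNS minus the
reference NCC is positive in every saturated site-year), and the derived
saturation thresholds *N*_MS track each site's critical load
(*N*_MS ≈ (CL + fixation)/leaching-rate at equilibrium).

The numbered scripts under `analysis/` run the same pipeline stepwise and
write tables under `results/`: site ensemble and forcing
(`01`), per-site *N*_MS (`02`), the six scenario runs (`03`), driver
attribution and biome aggregation (`04`), and the modifier response curves
(`05`). For example `04` reports that rising CO₂ raises NPP (+5.8 % on this
ensemble) while drawing soil mineral N down by ~2.2 g N m⁻² by the 2000s
relative to frozen CO₂ — increased biomass growth slows the nitrogen
turnover.

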