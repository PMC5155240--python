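"""Model parameters and per-biome defaults.

All fluxes are annual (g C m⁻² yr⁻¹ or g N m⁻² yr⁻¹), pools are g C m⁻² or
g N m⁻², temperatures °C, precipitation mm yr⁻¹ (annual) / mm month⁻¹
(monthly), CO₂ ppm, nitrogen deposition g N m⁻² yr⁻¹.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import TYPE_CHECKING

if TYPE_CHECKING:  # pragma: no cover
    from .critical_loads import SiteSpec

#: Reference (potential) NPP by aggregation biome, g C m⁻² yr⁻¹, attained at
#: the biome's reference climate and reference CO₂.
NPP_REF_BY_BIOME: dict[str, float] = {
    "tropical forest": 1100.0,
    "temperate forest": 800.0,
    "boreal forest": 420.0,
    "grassland": 500.0,
    "shrubland": 300.0,
    "savanna": 700.0,
    "cropland": 600.0,
    "tundra/other": 150.0,
}

#: Base carbon allocation fractions (leaf, wood, root) by biome. They sum to 1.
ALLOC_BY_BIOME: dict[str, tuple[float, float, float]] = {
    "tropical forest": (0.30, 0.40, 0.30),
    "temperate forest": (0.30, 0.40, 0.30),
    "boreal forest": (0.25, 0.45, 0.30),
    "grassland": (0.45, 0.05, 0.50),
    "shrubland": (0.35, 0.25, 0.40),
    "savanna": (0.35, 0.25, 0.40),
    "cropland": (0.45, 0.05, 0.50),
    "tundra/other": (0.40, 0.10, 0.50),
}


@dataclass(frozen=True, slots=True)
class ModelParams:
    """Scalar parameters of the coupled point-scale C–N model.

    The defaults describe a temperate forest; :meth:`for_site` rebinds the
    biome-dependent entries (reference NPP, allocation fractions, reference
    climate) for a given site.
    """

    # --- potential productivity ---
    npp_ref: float = 800.0          # g C m⁻² yr⁻¹ at reference climate & CO₂
    t_ref: float = 10.0             # °C, reference mean annual temperature
    p_ref: float = 900.0            # mm yr⁻¹, reference annual precipitation
    p_half: float = 400.0           # mm yr⁻¹, half-saturation of moisture response
    t_sens: float = 0.03            # °C⁻¹, linear log-response to warming
    t_curv: float = 0.001           # °C⁻², curvature (high-T penalty)
    co2_ref: float = 296.0          # ppm, pre-industrial reference
    beta_co2: float = 0.5           # β-factor of the logarithmic CO₂ response
    npp_gpp_ratio: float = 0.45     # NPP:GPP, diagnostics only

    # --- allocation ---
    alloc_fractions: tuple[float, float, float] = (0.30, 0.40, 0.30)
    sat_multipliers: tuple[float, float, float] = (1.10, 1.25, 0.65)

    # --- turnover and decomposition ---
    turnover_leaf: float = 1.0      # yr⁻¹
    turnover_wood: float = 0.02     # yr⁻¹
    turnover_root: float = 0.5      # yr⁻¹
    k_litter: float = 0.5           # yr⁻¹ base litter decomposition rate
    k_soc: float = 0.02             # yr⁻¹ base SOC decomposition rate
    humification: float = 0.3       # fraction of decomposed litter C -> SOC
    decomp_t_sens: float = 0.035    # °C⁻¹ temperature sensitivity of decay

    # --- stoichiometry, g C (g N)⁻¹ ---
    cn_leaf: float = 30.0
    cn_wood: float = 150.0
    cn_root: float = 60.0
    cn_soc: float = 12.0
    cn_litter: float = 60.0

    # --- nitrogen cycle ---
    imm_frac: float = 0.2           # gross immobilization / gross mineralization
    leach_rate: float = 0.2         # yr⁻¹ first-order loss from mineral N
    uptake_frac: float = 0.9        # max share of available mineral N plants take
    n_fixation: float = 0.4         # g N m⁻² yr⁻¹ constant biological fixation

    # --- saturation modifiers ---
    kp_floor: float = 0.824         # K_P at N_Mmax: 17.6 % NPP reduction
    km_floor: float = 0.85          # K_M at N_Mmax: 15 % decomposition decline
    k1_floor: float = 0.85          # K_1 at N_Mmax (mirrors K_M)
    legacy_ceiling: float = 2.0     # g N m⁻²: legacy modifiers reach 1 here
    modifier_origin: float = 0.05   # modifier value at N_M = 0
    nmmax_ratio: float = 2.0        # N_Mmax = ratio × N_MS
    n_ms_min: float = 0.05          # g N m⁻² floor for derived N_MS

    # --- protocol ---
    spinup_tol: float = 1e-6        # per-year relative pool change at equilibrium
    spinup_max_years: int = 5000
    spinup_ndep: float = 0.05       # g N m⁻² yr⁻¹ pre-industrial deposition
    freeze_year: int = 1970
    climatology_years: int = 30     # window used for the spin-up climatology

    def for_site(self, site: "SiteSpec") -> "ModelParams":
        """Return a copy with biome-dependent entries resolved for *site*."""
        from .forcing import CLIMATE_TEMPLATES  # local import, no cycle at module load

        biome = site.biome_label
        tmpl = CLIMATE_TEMPLATES[biome]
        return dataclasses.replace(
            self,
            npp_ref=NPP_REF_BY_BIOME[biome],
            alloc_fractions=ALLOC_BY_BIOME[biome],
            t_ref=tmpl.t_mean,
            p_ref=tmpl.p_annual,
        )
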