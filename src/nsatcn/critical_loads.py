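"""Empirical nitrogen critical loads, saturation classification and N_MS.

The package ships the literature compilation of empirical N critical loads
(g N m⁻² yr⁻¹) for the 15 modelled vegetation types in three well-studied
regions (USA, China, Europe). For the rest of the world ("Other") each type's
load is the arithmetic mean of its positive empirical regional values, rounded
to two decimals — a printed load of 0 marks an ecosystem with no tolerated
input rather than an observation that should enter the average.

Deposition above the critical load classifies a site-year as N-saturated
(strict inequality: deposition exactly at the load is not saturation). The
saturation threshold that actually drives the model's modifier curves is a
*pool* quantity, N_MS: the equilibrium soil mineral N reached when deposition
is pinned at the site's critical load with all three C–N modifiers held at 1
(:func:`derive_nms`).
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from .errors import ConfigurationError, InputError
from .params import ModelParams

REGIONS = ("USA", "China", "Europe", "Other")

_REGION_COL = {"USA": "usa", "China": "china", "Europe": "europe", "Other": "other"}

BIOME_LABELS = (
    "tropical forest", "temperate forest", "boreal forest", "grassland",
    "shrubland", "savanna", "cropland", "tundra/other",
)


@dataclass(frozen=True, slots=True)
class SiteSpec:
    """One simulated site: identity, vegetation class, region, biome."""

    site_id: str
    vegetation_type: int          # table row index, 1–15
    region: str                   # USA / China / Europe / Other
    biome_label: str              # aggregation class used in reporting

    def __post_init__(self):
        if not 1 <= int(self.vegetation_type) <= 15:
            raise InputError(f"vegetation_type must be 1–15, got {self.vegetation_type}")
        if self.region not in REGIONS:
            raise InputError(f"region must be one of {REGIONS}, got {self.region!r}")
        if self.biome_label not in BIOME_LABELS:
            raise InputError(f"unknown biome_label {self.biome_label!r}")


class CriticalLoadTable:
    """Vegetation-type × region critical loads with per-entry provenance."""

    def __init__(self, frame: pd.DataFrame, provenance: pd.DataFrame | None = None):
        self.frame = frame.set_index("index") if "index" in frame.columns else frame
        if provenance is None:
            provenance = self.frame[list(_REGION_COL.values())].notna().map(
                lambda filled: "empirical" if filled else "missing")
        self.provenance = provenance

    @property
    def filled(self) -> bool:
        return not self.frame["other"].isna().any()

    def row(self, vegetation_type: int | str) -> pd.Series:
        if isinstance(vegetation_type, str):
            match = self.frame[self.frame["vegetation_type"].str.lower()
                               == vegetation_type.lower()]
            if match.empty:
                raise InputError(f"unknown vegetation type {vegetation_type!r}")
            return match.iloc[0]
        if vegetation_type not in self.frame.index:
            raise InputError(f"unknown vegetation type index {vegetation_type}")
        return self.frame.loc[vegetation_type]


def load_raw_table() -> CriticalLoadTable:
    """The empirical cells only; the Other column is left missing."""
    with resources.files("nsatcn.data").joinpath("critical_loads.csv").open() as fh:
        frame = pd.read_csv(fh)
    frame = frame.drop(columns=["other"]).assign(other=np.nan)
    return CriticalLoadTable(frame)


def load_printed_table() -> CriticalLoadTable:
    """The table exactly as published, including the printed Other column."""
    with resources.files("nsatcn.data").joinpath("critical_loads.csv").open() as fh:
        frame = pd.read_csv(fh)
    return CriticalLoadTable(frame)


def fill_other_region(raw: CriticalLoadTable) -> CriticalLoadTable:
    """Fill the Other column from the empirical regional cells.

    Other = mean of the row's positive, non-missing USA/China/Europe loads,
    rounded to two decimals in exact decimal arithmetic with ties rounded
    down (the convention of the published table: (0.47 + 0.92)/2 = 0.695
    rounds to 0.69). Empirical cells are untouched. A row with no usable
    empirical cell raises :class:`ConfigurationError`.
    """
    from decimal import ROUND_HALF_DOWN, Decimal

    frame = raw.frame.copy()
    prov = raw.provenance.copy()
    others = []
    for idx, row in frame.iterrows():
        vals = [Decimal(repr(row[c])) for c in ("usa", "china", "europe")
                if pd.notna(row[c]) and row[c] > 0]
        if not vals:
            raise ConfigurationError(
                f"row {idx} ({row['vegetation_type']}) has no positive empirical load")
        mean = sum(vals) / len(vals)
        others.append(float(mean.quantize(Decimal("0.01"), rounding=ROUND_HALF_DOWN)))
    frame["other"] = others
    prov["other"] = "filled"
    return CriticalLoadTable(frame, prov)


def load_table() -> CriticalLoadTable:
    """The canonical filled table used throughout the package."""
    return fill_other_region(load_raw_table())


def lookup_cl(table: CriticalLoadTable, vegetation_type: int | str,
              region: str) -> float:
    """Critical load (g N m⁻² yr⁻¹) for a vegetation type and region."""
    if region not in REGIONS:
        raise InputError(f"unknown region {region!r}")
    if region == "Other" and not table.filled:
        raise InputError("table must be filled before looking up the Other region")
    value = table.row(vegetation_type)[_REGION_COL[region]]
    if pd.isna(value):
        raise InputError(
            f"no empirical critical load for ({vegetation_type!r}, {region})")
    return float(value)


def classify_saturation(n_deposition_series, cl: float) -> np.ndarray:
    """Boolean per-year saturation flags: deposition strictly above the load."""
    if cl < 0:
        raise InputError("critical load must be non-negative")
    return np.asarray(n_deposition_series, dtype=float) > cl


def derive_nms(site_spec: SiteSpec, table: CriticalLoadTable, params: ModelParams,
               climatology) -> float:
    """Soil mineral N at saturation onset (N_MS, g N m⁻²) for one site.

    Runs the coupled C–N model to equilibrium under the site's climatology
    with N deposition pinned at the critical load and all three modifiers held
    at 1, and returns the equilibrium soil mineral N pool (floored at
    ``params.n_ms_min`` so a zero-load site still yields a usable modifier
    curve). Deterministic given its inputs.
    """
    from .carbon import annualize, default_initial_state, spin_to_equilibrium
    from .nitrogen import ModifierCurve

    cl = lookup_cl(table, int(site_spec.vegetation_type), site_spec.region)
    site_params = params.for_site(site_spec)
    fy = annualize(climatology)[0]
    fy = fy.replace(n_deposition=cl)
    # Curve parameters are irrelevant while the modifiers are pinned at 1.
    dummy = ModifierCurve(n_ms=max(params.legacy_ceiling, 1.0),
                          n_mmax=2 * max(params.legacy_ceiling, 1.0))
    state, _info = spin_to_equilibrium(default_initial_state(), fy, site_params,
                                       dummy, mode="saturation", pinned=True)
    return max(float(state.nitrogen.soil_mineral_n), params.n_ms_min)
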