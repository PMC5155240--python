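"""Soil mineral-N dynamics and the three C–N coupling modifiers.

Three multiplicative modifiers couple nitrogen availability to the carbon
cycle: K_P scales plant biomass construction (NPP), K_1 soil N immobilization
and K_M soil organic matter mineralization. Two functional modes exist:

legacy
    N-deficit response only — each modifier rises with soil mineral N (N_M)
    from a small positive origin and is fixed at 1 once N_M reaches the
    2 g N m⁻² ceiling.
saturation
    additionally penalizes N excess — the modifier holds 1 up to N_MS (the
    mineral-N level at saturation onset), then declines linearly to a
    parameterized floor at N_Mmax (the maximum available soil mineral N) and
    stays there. The floors encode the observed mean saturation responses:
    K_P → 0.824 (a 17.6 % NPP reduction), K_M → 0.85 (a 15 % decline in SOC
    decomposition), with K_1 mirroring K_M.

Both modes agree below min(ceiling, N_MS), are continuous everywhere and
bounded in (0, 1].
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np

from .errors import InputError

log = logging.getLogger(__name__)

MODES = ("legacy", "saturation")


@dataclass(frozen=True, slots=True)
class ModifierCurve:
    """Parameters defining the K_P/K_1/K_M response shapes for one site."""

    n_ms: float                    # g N m⁻², soil mineral N at saturation onset
    n_mmax: float                  # g N m⁻², maximum available soil mineral N
    kp_floor: float = 0.824
    km_floor: float = 0.85
    k1_floor: float = 0.85
    legacy_ceiling: float = 2.0    # g N m⁻², legacy modifiers reach 1 here
    origin: float = 0.05           # modifier value at N_M = 0

    def __post_init__(self):
        for name in ("kp_floor", "km_floor", "k1_floor"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise InputError(f"{name} must be in (0, 1], got {v}")
        if not 0 < self.n_ms < self.n_mmax:
            raise InputError("require 0 < n_ms < n_mmax, got "
                             f"n_ms={self.n_ms}, n_mmax={self.n_mmax}")
        if self.legacy_ceiling <= 0:
            raise InputError("legacy_ceiling must be positive")
        if not 0 < self.origin <= 1:
            raise InputError("origin must be in (0, 1]")


def _evaluate(n_m, curve: ModifierCurve, mode: str, floor: float):
    n_arr = np.asarray(n_m, dtype=float)
    if (n_arr < 0).any():
        raise InputError("soil mineral N must be non-negative")
    if mode == "legacy":
        xp = [0.0, curve.legacy_ceiling]
        fp = [curve.origin, 1.0]
    elif mode == "saturation":
        rise_end = min(curve.legacy_ceiling, curve.n_ms)
        xp = [0.0, rise_end, curve.n_ms, curve.n_mmax]
        fp = [curve.origin, 1.0, 1.0, floor]
    else:
        raise InputError(f"unknown modifier mode {mode!r}")
    out = np.interp(n_arr, xp, fp)
    return float(out) if np.isscalar(n_m) else out


def modifier_kp(n_m, curve: ModifierCurve, mode: str = "saturation"):
    """Plant biomass construction modifier K_P ∈ (0, 1]."""
    return _evaluate(n_m, curve, mode, curve.kp_floor)


def modifier_k1(n_m, curve: ModifierCurve, mode: str = "saturation"):
    """Soil N immobilization modifier K_1 ∈ (0, 1]."""
    return _evaluate(n_m, curve, mode, curve.k1_floor)


def modifier_km(n_m, curve: ModifierCurve, mode: str = "saturation"):
    """Soil organic matter mineralization modifier K_M ∈ (0, 1]."""
    return _evaluate(n_m, curve, mode, curve.km_floor)


def saturation_degree(n_m: float, curve: ModifierCurve) -> float:
    """Linear ramp in N_M from 0 at N_MS to 1 at N_Mmax (clamped)."""
    if n_m < 0:
        raise InputError("soil mineral N must be non-negative")
    return float(np.clip((n_m - curve.n_ms) / (curve.n_mmax - curve.n_ms), 0.0, 1.0))


def curves_frame(curve: ModifierCurve, n_grid=None):
    """Fig-6-style diagnostic table of all three modifiers in both modes."""
    import pandas as pd

    if n_grid is None:
        n_grid = np.linspace(0.0, 1.5 * curve.n_mmax, 301)
    n_grid = np.asarray(n_grid, dtype=float)
    return pd.DataFrame({
        "n_m": n_grid,
        "kp_legacy": modifier_kp(n_grid, curve, "legacy"),
        "k1_legacy": modifier_k1(n_grid, curve, "legacy"),
        "km_legacy": modifier_km(n_grid, curve, "legacy"),
        "kp_saturation": modifier_kp(n_grid, curve, "saturation"),
        "k1_saturation": modifier_k1(n_grid, curve, "saturation"),
        "km_saturation": modifier_km(n_grid, curve, "saturation"),
    })


# ---------------------------------------------------------------------------
# nitrogen pools


@dataclass(frozen=True, slots=True)
class NPoolState:
    """Nitrogen pools, g N m⁻²."""

    soil_mineral_n: float
    soil_organic_n: float
    plant_n: float

    def replace(self, **kw) -> "NPoolState":
        return replace(self, **kw)


@dataclass(frozen=True, slots=True)
class NFluxRecord:
    """Annual nitrogen fluxes, g N m⁻² yr⁻¹ (all non-negative)."""

    deposition: float
    mineralization: float
    immobilization: float
    plant_uptake: float
    leaching: float

    def __post_init__(self):
        for name in ("deposition", "mineralization", "immobilization",
                     "plant_uptake", "leaching"):
            if getattr(self, name) < 0:
                raise InputError(f"{name} must be non-negative")


def step_n_pools(state: NPoolState, fluxes: NFluxRecord, dt: float = 1.0,
                 plant_litter_n: float = 0.0) -> NPoolState:
    """Advance the N pools by ``dt`` years under the given fluxes.

    Mineral N receives deposition and net mineralization and loses plant
    uptake and leaching; plant N gains uptake and sheds litter N, which joins
    soil organic N together with immobilized N. Absent clipping the total N
    change is exactly (deposition − leaching)·dt; pools that would go negative
    are clipped at zero and the deficit logged.
    """
    if dt <= 0:
        raise InputError("dt must be positive")
    mineral = state.soil_mineral_n + dt * (
        fluxes.deposition + fluxes.mineralization - fluxes.immobilization
        - fluxes.plant_uptake - fluxes.leaching)
    plant = state.plant_n + dt * (fluxes.plant_uptake - plant_litter_n)
    organic = state.soil_organic_n + dt * (
        fluxes.immobilization - fluxes.mineralization + plant_litter_n)
    clipped = {}
    if mineral < 0:
        clipped["soil_mineral_n"] = mineral
        mineral = 0.0
    if plant < 0:
        clipped["plant_n"] = plant
        plant = 0.0
    if organic < 0:
        clipped["soil_organic_n"] = organic
        organic = 0.0
    if clipped:
        log.debug("N pool clipping: %s", clipped)
    return NPoolState(mineral, organic, plant)
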