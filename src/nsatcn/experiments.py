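"""Three-stage simulation protocol, factorial scenarios and attribution.

The protocol has three stages: a pre-industrial spin-up under repeating
climatology with deposition at 0.05 g N m⁻² yr⁻¹ run to carbon equilibrium
(reported as 1851–1900), a transient stage 1901–1969 with dynamic climate and
CO₂ but deposition held at its 1970 value, and the fully dynamic analysis
stage 1970–2009.

Six factorial scenarios attribute the NPP/NEP response to individual drivers.
``NCC`` is the all-dynamic reference; ``NNC``/``CNC``/``TNC``/``PNC`` each
freeze one driver (N deposition, CO₂, temperature, precipitation) at its 1970
values; ``NNS`` removes the saturation effect by pinning the three C–N
modifiers to 1 in exactly those site-years where deposition exceeds the
critical load.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .carbon import (EcosystemState, annualize, default_initial_state,
                     spin_to_equilibrium, step_year)
from .critical_loads import (CriticalLoadTable, derive_nms, load_table, lookup_cl)
from .errors import InputError
from .forcing import ForcingSeries, freeze_driver, spinup_climatology
from .nitrogen import ModifierCurve
from .params import ModelParams
from .sites import SiteEnsemble, generate_ensemble_forcing, make_ensemble


@dataclass(frozen=True, slots=True)
class ScenarioConfig:
    name: str
    full_name: str
    frozen_driver: str | None = None     # temperature/precipitation/co2/n_deposition
    freeze_year: int = 1970
    saturation_active: bool = True


SCENARIOS: dict[str, ScenarioConfig] = {
    "NCC": ScenarioConfig("NCC", "Nitrogen CO2 Climate"),
    "NNC": ScenarioConfig("NNC", "No Nitrogen Change", frozen_driver="n_deposition"),
    "CNC": ScenarioConfig("CNC", "CO2 No Change", frozen_driver="co2"),
    "TNC": ScenarioConfig("TNC", "Temperate No Change", frozen_driver="temperature"),
    "PNC": ScenarioConfig("PNC", "Precipitation No Change",
                          frozen_driver="precipitation"),
    "NNS": ScenarioConfig("NNS", "No N Saturation effect", saturation_active=False),
}

_DRIVER_COLS = ("temperature", "precipitation", "co2", "n_deposition")


def scenario_table() -> pd.DataFrame:
    """The scenario design matrix ('Change' vs frozen-at-1970 per driver)."""
    rows = []
    for cfg in SCENARIOS.values():
        row = {"experiment": cfg.name, "full_name": cfg.full_name}
        for d in _DRIVER_COLS:
            row[d] = str(cfg.freeze_year) if cfg.frozen_driver == d else "Change"
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass(slots=True)
class RunResult:
    """Per-site, per-year states and fluxes for one scenario run."""

    scenario: str
    data: pd.DataFrame
    nms: dict[str, float]
    meta: dict = field(default_factory=dict)


class ProtocolRunner:
    """Runs the three-stage protocol; caches the work shared by scenarios.

    Per-site N_MS values and the stage-1 equilibrium states depend only on
    the site and (for the equilibrium) on whether the spin-up is pinned, so
    they are computed once and reused across the six scenarios — which also
    guarantees that scenarios are bitwise identical wherever their forcing
    and pinning rules coincide.
    """

    def __init__(self, ensemble: SiteEnsemble, forcing: dict[str, ForcingSeries],
                 params: ModelParams | None = None,
                 table: CriticalLoadTable | None = None,
                 nms: dict[str, float] | None = None):
        self.ensemble = ensemble
        self.forcing = forcing
        self.params = params or ModelParams()
        self.table = table or load_table()
        self._climatology: dict[str, ForcingSeries] = {}
        self._eq_cache: dict[tuple[str, bool], EcosystemState] = {}
        self.nms = dict(nms) if nms else {}
        self.spinup_info: dict = {}

    def climatology(self, site_id: str) -> ForcingSeries:
        if site_id not in self._climatology:
            f = self.forcing[site_id]
            y0 = int(f.years[0])
            window = (y0, y0 + self.params.climatology_years - 1)
            self._climatology[site_id] = spinup_climatology(f, window=window)
        return self._climatology[site_id]

    def site_nms(self, site) -> float:
        if site.site_id not in self.nms:
            self.nms[site.site_id] = derive_nms(site, self.table, self.params,
                                                self.climatology(site.site_id))
        return self.nms[site.site_id]

    def curve(self, site) -> ModifierCurve:
        p = self.params
        n_ms = self.site_nms(site)
        return ModifierCurve(n_ms=n_ms, n_mmax=p.nmmax_ratio * n_ms,
                             kp_floor=p.kp_floor, km_floor=p.km_floor,
                             k1_floor=p.k1_floor, legacy_ceiling=p.legacy_ceiling,
                             origin=p.modifier_origin)

    def _stage1_equilibrium(self, site, fy_spin, site_params, curve, pinned):
        key = (site.site_id, pinned)
        if key not in self._eq_cache:
            state, info = spin_to_equilibrium(default_initial_state(), fy_spin,
                                              site_params, curve,
                                              mode="saturation", pinned=pinned)
            self._eq_cache[key] = state
            self.spinup_info[key] = info
        return self._eq_cache[key]

    def run(self, scenario: ScenarioConfig | str, seed: int | None = None) -> RunResult:
        """Run one scenario over all sites. The model itself is deterministic;
        ``seed`` is recorded in the result metadata only."""
        if isinstance(scenario, str):
            if scenario not in SCENARIOS:
                raise InputError(f"unknown scenario {scenario!r}")
            scenario = SCENARIOS[scenario]
        rows = []
        for site in self.ensemble:
            rows.extend(self._run_site(site, scenario))
        data = pd.DataFrame(rows)
        return RunResult(scenario.name, data, dict(self.nms),
                         meta={"seed": seed, "scenario": scenario})

    def _run_site(self, site, scenario: ScenarioConfig):
        p = self.params
        site_params = p.for_site(site)
        cl = lookup_cl(self.table, int(site.vegetation_type), site.region)
        curve = self.curve(site)

        forcing = self.forcing[site.site_id]
        if scenario.frozen_driver is not None:
            forcing = freeze_driver(forcing, scenario.frozen_driver,
                                    scenario.freeze_year)
        annual = annualize(forcing)
        years = forcing.years
        fy_clim = annualize(self.climatology(site.site_id))[0]
        fy_spin = fy_clim.replace(n_deposition=p.spinup_ndep)

        sat_spin = fy_spin.n_deposition > cl
        pinned_spin = (not scenario.saturation_active) and sat_spin
        state = self._stage1_equilibrium(site, fy_spin, site_params, curve,
                                         pinned_spin)
        i1970 = forcing.year_index(scenario.freeze_year)
        dep_1970 = annual[i1970].n_deposition

        rows = []
        for i, year in enumerate(years):
            if year <= 1900:
                fy, stage = fy_spin, "spinup"
            elif year < scenario.freeze_year:
                fy, stage = annual[i].replace(n_deposition=dep_1970), "historical"
            else:
                fy, stage = annual[i], "analysis"
            saturated = fy.n_deposition > cl
            pinned = (not scenario.saturation_active) and saturated
            state, cflux, nflux = step_year(state, fy, site_params, curve,
                                            mode="saturation", pinned=pinned)
            c, n = state.carbon, state.nitrogen
            rows.append({
                "site_id": site.site_id, "year": int(year), "stage": stage,
                "npp": cflux.npp, "gpp": cflux.gpp, "rh": cflux.rh,
                "nep": cflux.nep,
                "leaf_c": c.leaf_c, "wood_c": c.wood_c, "root_c": c.root_c,
                "litter_c": c.litter_c, "soc": c.soc,
                "soil_mineral_n": n.soil_mineral_n,
                "soil_organic_n": n.soil_organic_n, "plant_n": n.plant_n,
                "n_deposition": fy.n_deposition, "co2": fy.co2,
                "plant_uptake": nflux.plant_uptake, "leaching": nflux.leaching,
                "saturated": bool(saturated), "pinned": bool(pinned),
            })
        return rows


def run_protocol(sites: SiteEnsemble, forcing: dict[str, ForcingSeries],
                 scenario: ScenarioConfig | str,
                 params: ModelParams | None = None,
                 table: CriticalLoadTable | None = None,
                 seed: int | None = None) -> RunResult:
    """Run the three-stage protocol for one scenario (convenience wrapper)."""
    return ProtocolRunner(sites, forcing, params, table).run(scenario, seed=seed)


def run_all_scenarios(sites: SiteEnsemble, forcing: dict[str, ForcingSeries],
                      params: ModelParams | None = None,
                      table: CriticalLoadTable | None = None,
                      scenarios=None, seed: int | None = None,
                      ) -> dict[str, RunResult]:
    """Run the factorial experiment, sharing spin-ups across scenarios."""
    runner = ProtocolRunner(sites, forcing, params, table)
    names = list(scenarios) if scenarios else list(SCENARIOS)
    return {name: runner.run(name, seed=seed) for name in names}


# ---------------------------------------------------------------------------
# scenario differencing and aggregation


@dataclass(slots=True)
class ScenarioDiff:
    variable: str
    per_site: pd.DataFrame      # site_id, year, diff
    series: pd.Series           # per-year (weighted) mean diff, analysis window
    mean: float
    sd: float                   # interannual SD of the per-year series
    pct: float                  # 100 × mean / (baseline mean)


def _weighted_site_mean(frame: pd.DataFrame, column: str,
                        weights: dict[str, float] | None) -> pd.Series:
    """Area-weighted across-site mean of `column`, per year."""
    if weights is None:
        return frame.groupby("year")[column].mean()
    w = frame["site_id"].map(weights)
    num = (frame[column] * w).groupby(frame["year"]).sum()
    den = w.groupby(frame["year"]).sum()
    return num / den


def diff_scenarios(a: RunResult, b: RunResult, variable: str,
                   weights: dict[str, float] | None = None,
                   years: tuple[int, int] = (1970, 2009)) -> ScenarioDiff:
    """Elementwise a − b for one variable, with analysis-window summaries.

    The summary is the mean and interannual SD of the per-year across-site
    (optionally area-weighted) mean difference over ``years``, plus the mean
    as a percentage of b's own mean over the same window.
    """
    key = ["site_id", "year"]
    fa = a.data[key + [variable]].set_index(key).sort_index()
    fb = b.data[key + [variable]].set_index(key).sort_index()
    if not fa.index.equals(fb.index):
        raise InputError("runs cover different sites or years")
    per_site = (fa[variable] - fb[variable]).reset_index().rename(
        columns={variable: "diff"})
    window = per_site[(per_site["year"] >= years[0]) & (per_site["year"] <= years[1])]
    series = _weighted_site_mean(window.rename(columns={"diff": variable}),
                                 variable, weights)
    bwin = b.data[(b.data["year"] >= years[0]) & (b.data["year"] <= years[1])]
    base = _weighted_site_mean(bwin, variable, weights).mean()
    mean = float(series.mean())
    sd = float(series.std(ddof=1))
    pct = float(100.0 * mean / base) if base != 0 else float("nan")
    return ScenarioDiff(variable, per_site, series, mean, sd, pct)


def aggregate_by_biome(result: RunResult, sites: SiteEnsemble,
                       weights: dict[str, float] | None = None,
                       variable: str = "npp",
                       years: tuple[int, int] = (1970, 2009)) -> pd.DataFrame:
    """Area-weighted biome totals (flux × area, g yr⁻¹) and percentage shares."""
    areas = weights or sites.areas
    for sid, w in areas.items():
        if w <= 0:
            raise InputError(f"non-positive area weight for site {sid}")
    biome_of = {s.site_id: s.biome_label for s in sites}
    win = result.data[(result.data["year"] >= years[0])
                      & (result.data["year"] <= years[1])]
    unknown = set(win["site_id"]) - set(biome_of)
    if unknown:
        raise InputError(f"sites without biome labels: {sorted(unknown)}")
    per_site = win.groupby("site_id")[variable].mean()
    mass = per_site * pd.Series(areas)
    totals = mass.groupby(pd.Series(biome_of)).sum()
    out = pd.DataFrame({"total": totals,
                        "share_pct": 100.0 * totals / totals.sum()})
    out.index.name = "biome_label"
    return out


_ATTRIBUTION_PAIRS = {
    "co2": ("NCC", "CNC"),
    "temperature": ("NCC", "TNC"),
    "precipitation": ("NCC", "PNC"),
    "n_deposition": ("NCC", "NNC"),
    "n_saturation": ("NNS", "NCC"),
}


def attribution_summary(runs: dict[str, RunResult],
                        weights: dict[str, float] | None = None,
                        variables: tuple[str, ...] = ("npp", "nep"),
                        years: tuple[int, int] = (1970, 2009)) -> pd.DataFrame:
    """Driver-contribution table over the analysis window.

    Each driver's contribution is the all-dynamic run minus the run with that
    driver frozen (for saturation: the no-saturation run minus the reference,
    i.e. the productivity lost to saturation). Percentages are relative to the
    reference-run (NCC) mean.
    """
    missing = {s for pair in _ATTRIBUTION_PAIRS.values() for s in pair} - set(runs)
    if missing:
        raise InputError(f"missing scenarios: {sorted(missing)}")
    rows = []
    for driver, (hi, lo) in _ATTRIBUTION_PAIRS.items():
        for var in variables:
            d = diff_scenarios(runs[hi], runs[lo], var, weights=weights, years=years)
            ncc = _weighted_site_mean(
                runs["NCC"].data[(runs["NCC"].data["year"] >= years[0])
                                 & (runs["NCC"].data["year"] <= years[1])],
                var, weights).mean()
            rows.append({"driver": driver, "variable": var,
                         "mean": d.mean, "sd": d.sd,
                         "pct_of_ncc": 100.0 * d.mean / ncc if ncc != 0 else np.nan})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# one-call study


@dataclass(slots=True)
class StudyResult:
    ensemble: SiteEnsemble
    forcing: dict[str, ForcingSeries]
    table: CriticalLoadTable
    nms: dict[str, float]
    runs: dict[str, RunResult]


def run_study(seed: int, n_sites: int = 8, years: tuple[int, int] = (1851, 2009),
              params: ModelParams | None = None, scenarios=None,
              template: str = "paperlike") -> StudyResult:
    """Generate a seeded ensemble plus forcing and run the factorial design."""
    ensemble = make_ensemble(n_sites=n_sites, seed=seed, template=template)
    forcing = generate_ensemble_forcing(ensemble, years, seed)
    table = load_table()
    runner = ProtocolRunner(ensemble, forcing, params, table)
    names = list(scenarios) if scenarios else list(SCENARIOS)
    runs = {name: runner.run(name, seed=seed) for name in names}
    return StudyResult(ensemble, forcing, table, runner.nms, runs)
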