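"""Protocol stages, scenario fidelity, differencing and attribution."""

import numpy as np
import pandas as pd
import pytest

from nsatcn import (InputError, ModelParams, NdepProfile, SiteSpec,
                    aggregate_by_biome, attribution_summary, diff_scenarios,
                    generate_forcing, run_all_scenarios, scenario_table)
from nsatcn.experiments import SCENARIOS, ProtocolRunner, RunResult
from nsatcn.sites import SiteEnsemble


def test_scenario_table_matches_design_matrix():
    expected = pd.DataFrame([
        ("NCC", "Nitrogen CO2 Climate", "Change", "Change", "Change", "Change"),
        ("NNC", "No Nitrogen Change", "Change", "Change", "Change", "1970"),
        ("CNC", "CO2 No Change", "Change", "Change", "1970", "Change"),
        ("TNC", "Temperate No Change", "1970", "Change", "Change", "Change"),
        ("PNC", "Precipitation No Change", "Change", "1970", "Change", "Change"),
        ("NNS", "No N Saturation effect", "Change", "Change", "Change", "Change"),
    ], columns=["experiment", "full_name", "temperature", "precipitation",
                "co2", "n_deposition"])
    got = scenario_table().set_index("experiment")
    assert got.equals(expected.set_index("experiment"))
    assert SCENARIOS["NCC"].frozen_driver is None
    assert SCENARIOS["NCC"].saturation_active
    assert not SCENARIOS["NNS"].saturation_active


def test_spinup_stage_ends_in_equilibrium(study):
    ncc = study.runs["NCC"].data
    end = ncc[ncc.year == 1900]
    assert (end.nep.abs() < 0.1).all()
    assert (ncc[ncc.year <= 1900].stage == "spinup").all()


def test_nnc_deposition_constant_at_1970_value(study):
    nnc = study.runs["NNC"].data
    for sid, grp in nnc[nnc.year >= 1901].groupby("site_id"):
        dep1970 = grp.loc[grp.year == 1970, "n_deposition"].iloc[0]
        assert np.allclose(grp.n_deposition, dep1970)


def test_stage_coverage_is_complete(study):
    for run in study.runs.values():
        for sid, grp in run.data.groupby("site_id"):
            analysis = grp[grp.stage == "analysis"]
            assert sorted(analysis.year) == list(range(1970, 2010))


def test_ncc_and_nns_bitwise_identical_at_unsaturated_sites(study):
    ncc, nns = study.runs["NCC"].data, study.runs["NNS"].data
    never_sat = [sid for sid, g in ncc.groupby("site_id") if not g.saturated.any()]
    assert never_sat  # the paperlike ensemble guarantees such sites
    a = ncc[ncc.site_id.isin(never_sat)].reset_index(drop=True)
    b = nns[nns.site_id.isin(never_sat)].reset_index(drop=True)
    assert a.equals(b)


def test_removing_saturation_never_reduces_npp_when_saturated(study):
    ncc, nns = study.runs["NCC"].data, study.runs["NNS"].data
    m = ncc.merge(nns, on=["site_id", "year"], suffixes=("_ncc", "_nns"))
    sat = m[(m.year >= 1970) & m.saturated_ncc]
    assert len(sat) > 0
    assert (sat.npp_nns - sat.npp_ncc).min() >= 0.0


def test_soil_mineral_n_lower_under_rising_co2(study):
    ncc, cnc = study.runs["NCC"].data, study.runs["CNC"].data
    end_ncc = ncc[ncc.year >= 2000].groupby("site_id").soil_mineral_n.mean()
    end_cnc = cnc[cnc.year >= 2000].groupby("site_id").soil_mineral_n.mean()
    assert end_ncc.mean() < end_cnc.mean()


def test_co2_contribution_to_npp_positive(study):
    d = diff_scenarios(study.runs["NCC"], study.runs["CNC"], "npp",
                       weights=study.ensemble.areas)
    assert d.mean > 0


def test_diff_of_run_with_itself_is_zero(study):
    d = diff_scenarios(study.runs["NCC"], study.runs["NCC"], "npp")
    assert (d.per_site["diff"] == 0).all()
    assert d.mean == 0 and d.pct == 0


def test_diff_summary_matches_naive_recomputation(study):
    a, b = study.runs["NNS"], study.runs["NCC"]
    d = diff_scenarios(a, b, "npp")
    # brute-force oracle: plain loops over the raw frames
    diffs = {}
    for year in range(1970, 2010):
        vals = []
        for sid in a.data.site_id.unique():
            va = a.data[(a.data.site_id == sid) & (a.data.year == year)].npp.iloc[0]
            vb = b.data[(b.data.site_id == sid) & (b.data.year == year)].npp.iloc[0]
            vals.append(va - vb)
        diffs[year] = sum(vals) / len(vals)
    series = pd.Series(diffs)
    assert d.mean == pytest.approx(series.mean())
    assert d.sd == pytest.approx(series.std(ddof=1))


def test_diff_rejects_mismatched_runs(study):
    a = study.runs["NCC"]
    b = RunResult("X", a.data[a.data.site_id != a.data.site_id.iloc[0]],
                  a.nms)
    with pytest.raises(InputError):
        diff_scenarios(a, b, "npp")


# --- aggregation ----------------------------------------------------------


def _toy_run(fluxes: dict[str, float]) -> RunResult:
    rows = [{"site_id": sid, "year": y, "npp": v}
            for sid, v in fluxes.items() for y in range(1970, 2010)]
    return RunResult("toy", pd.DataFrame(rows), {})


def _toy_sites(biomes: dict[str, str]) -> SiteEnsemble:
    veg = {"temperate forest": 5, "grassland": 10, "boreal forest": 6}
    sites = [SiteSpec(sid, veg[b], "Other", b) for sid, b in biomes.items()]
    return SiteEnsemble(sites, {sid: 1.0 for sid in biomes},
                        {sid: NdepProfile("background") for sid in biomes})


def test_single_biome_share_is_100pct():
    out = aggregate_by_biome(_toy_run({"a": 500.0, "b": 700.0}),
                             _toy_sites({"a": "grassland", "b": "grassland"}))
    assert out.share_pct.iloc[0] == pytest.approx(100.0)


def test_two_equal_sites_split_50_50():
    out = aggregate_by_biome(
        _toy_run({"a": 600.0, "b": 600.0}),
        _toy_sites({"a": "grassland", "b": "temperate forest"}))
    assert np.allclose(out.share_pct, [50.0, 50.0])


def test_biome_shares_match_naive_groupby(study):
    ncc = study.runs["NCC"]
    out = aggregate_by_biome(ncc, study.ensemble, variable="npp")
    assert out.share_pct.sum() == pytest.approx(100.0, abs=1e-9)
    # naive loop oracle
    totals = {}
    for site in study.ensemble:
        sub = ncc.data[(ncc.data.site_id == site.site_id)
                       & (ncc.data.year >= 1970) & (ncc.data.year <= 2009)]
        totals.setdefault(site.biome_label, 0.0)
        totals[site.biome_label] += sub.npp.mean() * study.ensemble.areas[site.site_id]
    for biome, total in totals.items():
        assert out.loc[biome, "total"] == pytest.approx(total, rel=1e-12)


def test_aggregate_rejects_bad_weights(study):
    with pytest.raises(InputError):
        aggregate_by_biome(study.runs["NCC"], study.ensemble,
                           weights={sid: 0.0 for sid in study.ensemble.site_ids})


# --- attribution ----------------------------------------------------------


def test_attribution_table_matches_hand_assembly(study):
    out = attribution_summary(study.runs, weights=study.ensemble.areas)
    assert set(out.driver) == {"co2", "temperature", "precipitation",
                               "n_deposition", "n_saturation"}
    for _, row in out.iterrows():
        hi, lo = {"co2": ("NCC", "CNC"), "temperature": ("NCC", "TNC"),
                  "precipitation": ("NCC", "PNC"),
                  "n_deposition": ("NCC", "NNC"),
                  "n_saturation": ("NNS", "NCC")}[row.driver]
        d = diff_scenarios(study.runs[hi], study.runs[lo], row.variable,
                           weights=study.ensemble.areas)
        assert row["mean"] == pytest.approx(d.mean)
        assert row["sd"] == pytest.approx(d.sd)


def test_identical_runs_have_zero_contribution(study):
    d = diff_scenarios(study.runs["NNC"], study.runs["NNC"], "nep")
    assert d.mean == 0.0


def test_attribution_requires_all_scenarios(study):
    partial = {k: v for k, v in study.runs.items() if k != "TNC"}
    with pytest.raises(InputError):
        attribution_summary(partial)


# --- determinism and monotone harm ---------------------------------------


def _single_site_runs(start_level, table):
    site = SiteSpec("X-00", 5, "USA", "temperate forest")
    profile = NdepProfile("background", start_level=start_level, noise_sigma=0.0)
    ens = SiteEnsemble([site], {"X-00": 1.0}, {"X-00": profile})
    forcing = {"X-00": generate_forcing(site, (1851, 2009), profile, seed=0)}
    return run_all_scenarios(ens, forcing, table=table, scenarios=["NCC", "NNS"])


def test_repeated_invocation_is_bitwise_identical(table):
    a = _single_site_runs(2.0, table)["NCC"]
    b = _single_site_runs(2.0, table)["NCC"]
    assert a.data.equals(b.data)


def test_deeper_saturation_never_helps_ncc_relative_to_nns(table):
    """Raising deposition beyond the critical load only widens the NPP gap
    between the saturation run and the modifiers-off run."""
    gaps = []
    for level in (2.0, 3.0):  # both above the 0.9 critical load
        runs = _single_site_runs(level, table)
        d = diff_scenarios(runs["NCC"], runs["NNS"], "npp")
        gaps.append(d.mean)  # <= 0: saturation harms
    assert gaps[0] <= 0
    assert gaps[1] <= gaps[0]
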