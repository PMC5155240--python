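"""Carbon core: productivity responses, allocation, decomposition, coupling."""

import math

import numpy as np
import pytest

from nsatcn import (AllocationParams, CPoolState, EcosystemState, InputError,
                    ModelParams, ModifierCurve, NPoolState, NumericalError,
                    YearForcing, allocate, decompose, default_initial_state,
                    npp_potential, realized_npp, spin_to_equilibrium, step_year)
from nsatcn.carbon import decomp_climate_scalar

P = ModelParams()
REF = YearForcing(P.t_ref, P.p_ref, P.co2_ref, 0.5)
CURVE = ModifierCurve(n_ms=6.0, n_mmax=12.0)


def _rich_state(n_m=6.0):
    """A well-stocked state whose N supply comfortably meets plant demand."""
    return EcosystemState(
        CPoolState(leaf_c=300.0, wood_c=16000.0, root_c=600.0,
                   litter_c=1600.0, soc=12000.0),
        NPoolState(soil_mineral_n=n_m, soil_organic_n=320.0, plant_n=250.0))


# --- potential NPP --------------------------------------------------------


def test_reference_climate_returns_npp_ref():
    assert npp_potential(REF, P.co2_ref, P) == pytest.approx(P.npp_ref)


def test_co2_response_is_beta_logarithmic():
    expected = P.npp_ref * (1.0 + P.beta_co2 * math.log(2.0))
    assert npp_potential(REF, 2 * P.co2_ref, P) == pytest.approx(expected)


def test_npp_increasesing_with_co2_over_sweep():
    vals = [npp_potential(REF, c, P) for c in np.linspace(280, 800, 100)]
    assert (np.diff(vals) > 0).all()


def test_npp_positive_and_co2_validated():
    assert npp_potential(YearForcing(-20.0, 100.0, 300.0, 0), 300.0, P) > 0
    with pytest.raises(InputError):
        npp_potential(REF, 0.0, P)


# --- K_P scaling ----------------------------------------------------------


@pytest.mark.parametrize("kp,expected", [(1.0, 1000.0), (0.824, 824.0),
                                         (0.5, 500.0)])
def test_realized_npp_scales_linearly(kp, expected):
    assert realized_npp(1000.0, kp) == pytest.approx(expected)


def test_realized_npp_rejects_bad_kp():
    with pytest.raises(InputError):
        realized_npp(100.0, 0.0)
    with pytest.raises(InputError):
        realized_npp(100.0, 1.2)


# --- allocation -----------------------------------------------------------


def test_allocation_identity_at_zero_saturation():
    alloc = AllocationParams((0.3, 0.4, 0.3))
    out = allocate(900.0, alloc, 0.0)
    assert out == pytest.approx([270.0, 360.0, 270.0])


def test_allocation_full_saturation_hand_computation():
    # equal base thirds, multipliers (1.10, 1.25, 0.65) average exactly to 1
    alloc = AllocationParams((1 / 3, 1 / 3, 1 / 3))
    out = allocate(1.0, alloc, 1.0)
    assert out == pytest.approx([1.10 / 3, 1.25 / 3, 0.65 / 3])
    assert out.sum() == pytest.approx(1.0, abs=1e-12)


def test_root_share_drops_35pct_before_renormalization():
    alloc = AllocationParams((0.3, 0.4, 0.3))
    raw_root = 0.3 * (1 + 1.0 * (0.65 - 1))
    assert raw_root == pytest.approx(0.3 * 0.65)
    assert (0.3 - raw_root) / 0.3 == pytest.approx(0.35)


def test_allocation_sums_to_npp_exactly():
    alloc = AllocationParams((0.25, 0.45, 0.30))
    for s in (0.0, 0.3, 0.7, 1.0):
        assert allocate(777.0, alloc, s).sum() == pytest.approx(777.0, abs=1e-9)


def test_allocation_validation():
    with pytest.raises(InputError):
        allocate(-1.0, AllocationParams((0.3, 0.4, 0.3)), 0.0)
    with pytest.raises(InputError):
        AllocationParams((0.5, 0.6, 0.3))


# --- decomposition --------------------------------------------------------


def test_rh_responds_exactly_proportionally_to_km():
    state = _rich_state().carbon
    a = decompose(state, 1.0, 1.0, 1.0, P)
    b = decompose(state, 0.85, 1.0, 1.0, P)
    assert b.rh / a.rh == pytest.approx(0.85, abs=1e-12)


def test_empty_pools_give_zero_fluxes():
    empty = CPoolState(0, 0, 0, 0, 0)
    out = decompose(empty, 1.0, 1.0, 1.0, P)
    assert out.rh == 0 and out.mineralized_n == 0 and out.immobilized_n == 0


def test_closed_system_conserves_carbon_over_century():
    state = CPoolState(0, 0, 0, 1000.0, 8000.0)
    initial = state.litter_c + state.soc
    emitted = 0.0
    for _ in range(100):
        d = decompose(state, 0.9, 1.0, 1.1, P)
        state = CPoolState(0, 0, 0,
                           state.litter_c - d.litter_decomp,
                           state.soc + d.humified_c - d.soc_decomp)
        emitted += d.rh
    assert emitted + state.litter_c + state.soc == pytest.approx(initial,
                                                                 abs=1e-8)


def test_decompose_validates_modifiers():
    with pytest.raises(InputError):
        decompose(_rich_state().carbon, 0.0, 1.0, 1.0, P)


def test_climate_scalar_is_one_at_reference():
    assert decomp_climate_scalar(P.t_ref, P.p_ref, P) == pytest.approx(1.0)


# --- coupled annual step --------------------------------------------------


def test_zero_forcing_zero_pools_is_inert():
    state = EcosystemState(CPoolState(0, 0, 0, 0, 0), NPoolState(0, 0, 0))
    params = ModelParams(n_fixation=0.0)
    fy = YearForcing(params.t_ref, 0.0, params.co2_ref, 0.0)
    out, cflux, nflux = step_year(state, fy, params, CURVE)
    assert cflux.npp == 0 and cflux.rh == 0 and cflux.nep == 0
    assert np.allclose(out.as_vector(), 0.0)


def test_carbon_mass_balance_over_random_steps():
    rng = np.random.default_rng(7)
    for _ in range(1000):
        state = EcosystemState(
            CPoolState(*rng.uniform(0, 5000, 5)),
            NPoolState(*rng.uniform(0, 50, 3)))
        fy = YearForcing(rng.uniform(-10, 30), rng.uniform(100, 2500),
                         rng.uniform(280, 500), rng.uniform(0, 5))
        out, cflux, _ = step_year(state, fy, P, CURVE)
        dc = out.carbon.total() - state.carbon.total()
        assert abs(dc - (cflux.npp - cflux.rh)) < 1e-8
        assert cflux.nep == cflux.npp - cflux.rh  # identity, exact


def test_saturation_floor_cuts_npp_by_exactly_17_6pct():
    state = _rich_state(n_m=CURVE.n_mmax)
    fy = YearForcing(P.t_ref, P.p_ref, 380.0, 2.0)
    _, sat, _ = step_year(state, fy, P, CURVE, mode="saturation")
    _, ref, _ = step_year(state, fy, P, CURVE, pinned=True)
    assert 100.0 * (1.0 - sat.npp / ref.npp) == pytest.approx(17.6, abs=1e-9)


def test_non_finite_state_raises():
    bad = EcosystemState(CPoolState(float("nan"), 0, 0, 0, 0),
                         NPoolState(0, 0, 0))
    with pytest.raises(NumericalError):
        step_year(bad, REF, P, CURVE)


def test_spinup_reaches_same_fixed_point_from_many_starts():
    rng = np.random.default_rng(99)
    fy = YearForcing(P.t_ref, P.p_ref, P.co2_ref, 0.05)
    reference = None
    for _ in range(50):
        start = EcosystemState(
            CPoolState(*rng.uniform(0.0, 3000.0, 5)),
            NPoolState(*rng.uniform(0.0, 100.0, 3)))
        state, info = spin_to_equilibrium(start, fy, P, CURVE)
        assert abs(info["cflux"].nep) < 0.1
        vec = state.as_vector()
        if reference is None:
            reference = vec
        else:
            assert np.allclose(vec, reference, rtol=1e-3)
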