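import dataclasses

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from cosmopharm import (
    Component,
    CosmoSac2002,
    CosmoSac2010,
    FloryHuggins,
    HansenRecord,
    ModelParameters2002,
    ModelParameters2010,
    SigmaProfile,
    fh_chi,
    hansen_from_groups,
    hansen_lookup,
    segment_gammas,
    staverman_guggenheim,
)
from cosmopharm.activity import exchange_energy_2002, exchange_energy_2010

from . import oracles

T_ROOM = 298.15


# ---------------------------------------------------------------------------
# Staverman-Guggenheim combinatorial
# ---------------------------------------------------------------------------

def test_sg_pure_component_is_zero():
    assert staverman_guggenheim([1.0], [2.3], [1.9])[0] == pytest.approx(0.0, abs=1e-14)


@given(st.floats(0.05, 0.95))
def test_sg_identical_molecules_are_ideal(x1):
    lng = staverman_guggenheim([x1, 1 - x1], [2.0, 2.0], [1.5, 1.5])
    np.testing.assert_allclose(lng, 0.0, atol=1e-13)


def test_sg_matches_naive_evaluation():
    x, r, q = [0.5, 0.5], [2.0, 1.0], [2.0, 1.0]
    got = staverman_guggenheim(x, r, q, z=10.0)
    want = oracles.naive_staverman_guggenheim(x, r, q, z=10.0)
    np.testing.assert_allclose(got, want, rtol=1e-12)


def test_sg_infinite_dilution_is_finite_limit():
    r, q = [3.1, 1.2], [2.7, 1.1]
    at_zero = staverman_guggenheim([0.0, 1.0], r, q)
    near_zero = staverman_guggenheim([1e-9, 1.0 - 1e-9], r, q)
    assert at_zero[0] == pytest.approx(near_zero[0], abs=1e-6)
    assert np.isfinite(at_zero).all()


# ---------------------------------------------------------------------------
# exchange energies
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "sm,sn,expected",
    [
        (0.0, 0.0, 0.0),
        (0.005, -0.005, 0.0),  # misfit cancels, |sigma| below the hb cutoff
        (0.01, 0.01, 16466.72 * 0.0004 / 2.0),
    ],
)
def test_exchange_energy_2002_closed_forms(sm, sn, expected):
    p = ModelParameters2002()
    assert exchange_energy_2002(sm, sn, p) == pytest.approx(expected, rel=1e-12)


@given(st.floats(-0.025, 0.025), st.floats(-0.025, 0.025))
def test_exchange_energy_2002_symmetric(sm, sn):
    p = ModelParameters2002()
    assert exchange_energy_2002(sm, sn, p) == pytest.approx(
        exchange_energy_2002(sn, sm, p), rel=1e-12
    )


def test_exchange_energy_2002_hb_term_activates_beyond_cutoff():
    p = ModelParameters2002()
    w = exchange_energy_2002(0.012, -0.012, p)
    # misfit cancels; hb term = c_hb*(0.012-0.0084)*(-0.012+0.0084)
    assert w == pytest.approx(85580.0 * 0.0036 * -0.0036, rel=1e-10)
    assert w < 0


def test_exchange_energy_2010_closed_forms():
    p = ModelParameters2010()
    assert exchange_energy_2010(0.0, "OH", 0.0, "OT", T_ROOM, p) == 0.0
    # NHB pairs never hydrogen-bond: pure electrostatics
    es = (p.a_es + p.b_es / T_ROOM**2) * (0.01 - 0.01) ** 2
    assert exchange_energy_2010(0.01, "NHB", -0.01, "NHB", T_ROOM, p) == pytest.approx(es)
    # OH pair with opposite signs: electrostatics vanish, attractive hb stays
    w = exchange_energy_2010(0.01, "OH", -0.01, "OH", T_ROOM, p)
    assert w == pytest.approx(-4013.78 * 0.02**2, rel=1e-12)
    with pytest.raises(ValueError, match="class"):
        exchange_energy_2010(0.0, "XX", 0.0, "OH", T_ROOM, p)


def test_exchange_energy_2010_same_sign_pair_has_no_hb():
    p = ModelParameters2010()
    w = exchange_energy_2010(0.01, "OH", 0.02, "OH", T_ROOM, p)
    assert w == pytest.approx((p.a_es + p.b_es / T_ROOM**2) * 0.03**2, rel=1e-12)


# ---------------------------------------------------------------------------
# segment activity coefficients
# ---------------------------------------------------------------------------

def test_segment_gammas_unity_for_zero_exchange_energy():
    p = np.full(51, 1 / 51)
    gam = segment_gammas(p, np.zeros((51, 51)), T_ROOM, 0.001987)
    np.testing.assert_allclose(gam, 1.0, atol=1e-12)


def test_segment_gammas_match_brute_force_two_bin_system():
    R = 0.001987
    w = R * T_ROOM  # exchange energy equal to RT
    p = [0.5, 0.5]
    dw = [[0.0, w], [w, 0.0]]
    brute = oracles.naive_segment_fixed_point(p, dw, T_ROOM, R)
    got = segment_gammas(np.array(p), np.array(dw), T_ROOM, R, tol=1e-12)
    np.testing.assert_allclose(got, brute, rtol=1e-9)


def test_segment_gammas_satisfy_fixed_point_residual(hb_component):
    from cosmopharm.activity import _dw_matrix_2002

    params = ModelParameters2002()
    dw = _dw_matrix_2002(params)
    p = hb_component.profile.p
    gam = segment_gammas(p, dw, T_ROOM, params.R)
    rhs = 1.0 / (np.exp(-dw / (params.R * T_ROOM)) @ (p * gam))
    assert np.max(np.abs(rhs - gam) / gam) < 1e-8


# ---------------------------------------------------------------------------
# full COSMO-SAC models
# ---------------------------------------------------------------------------

def test_cosmosac2002_pure_component_is_ideal(binary_components):
    model = CosmoSac2002(binary_components)
    lng = model.ln_gamma([1.0, 0.0], T_ROOM)
    assert lng[0] == pytest.approx(0.0, abs=1e-12)


def test_cosmosac2002_identical_components_are_ideal(apolar_component):
    model = CosmoSac2002([apolar_component, apolar_component])
    lng = model.ln_gamma([0.3, 0.7], T_ROOM)
    np.testing.assert_allclose(lng, 0.0, atol=1e-12)


def test_cosmosac2002_matches_independent_oracle(binary_components):
    model = CosmoSac2002(binary_components)
    got = model.ln_gamma([0.5, 0.5], T_ROOM)
    want = oracles.naive_cosmosac2002(
        [c.profile.p.tolist() for c in binary_components],
        [c.area for c in binary_components],
        [c.volume for c in binary_components],
        [0.5, 0.5],
        T_ROOM,
    )
    np.testing.assert_allclose(got, want, atol=1e-9)


def test_cosmosac2002_infinite_dilution_is_finite(binary_components):
    model = CosmoSac2002(binary_components)
    lng = model.ln_gamma([0.0, 1.0], T_ROOM)
    assert np.isfinite(lng).all()
    near = model.ln_gamma([1e-10, 1.0 - 1e-10], T_ROOM)
    assert lng[0] == pytest.approx(near[0], abs=1e-6)


def test_cosmosac2010_pure_component_is_ideal(binary_components):
    model = CosmoSac2010(binary_components)
    assert model.ln_gamma([0.0, 1.0], T_ROOM)[1] == pytest.approx(0.0, abs=1e-12)


def test_cosmosac2010_reduces_to_2002_without_hb_surface(
    apolar_component, second_apolar_component
):
    """With A_ES = alpha'/2, B_ES = 0 and no OH/OT area the revision
    degenerates to the original model."""
    comps = [apolar_component, second_apolar_component]
    geom = ModelParameters2002()
    params10 = ModelParameters2010(a_es=geom.alpha_prime / 2.0, b_es=0.0)
    m2002 = CosmoSac2002(comps, geom)
    m2010 = CosmoSac2010(comps, params10, geom)
    x = [0.4, 0.6]
    np.testing.assert_allclose(
        m2010.ln_gamma(x, T_ROOM), m2002.ln_gamma(x, T_ROOM), atol=1e-9
    )


def test_cosmosac2010_matches_independent_oracle(binary_components):
    model = CosmoSac2010(binary_components)
    got = model.ln_gamma([0.5, 0.5], T_ROOM)
    split_profiles = [
        {"NHB": c.split.nhb.tolist(), "OH": c.split.oh.tolist(), "OT": c.split.ot.tolist()}
        for c in binary_components
    ]
    want = oracles.naive_cosmosac2010(
        split_profiles,
        [c.area for c in binary_components],
        [c.volume for c in binary_components],
        [0.5, 0.5],
        T_ROOM,
    )
    np.testing.assert_allclose(got, want, atol=1e-9)


def test_cosmosac2010_requires_split_profiles(apolar_molecule):
    comp = Component.from_molecule(apolar_molecule, with_split=False)
    with pytest.raises(ValueError, match="split"):
        CosmoSac2010([comp, comp])


def test_residual_invariant_under_global_charge_mirror(binary_components):
    """Flipping every charge density and mirroring the profiles leaves the
    exchange energies, hence ln gamma, unchanged."""
    mirrored = [
        Component(
            c.name,
            c.area,
            c.volume,
            SigmaProfile(c.profile.p[::-1].copy(), c.profile.total_area),
        )
        for c in binary_components
    ]
    m = CosmoSac2002(binary_components)
    m_flip = CosmoSac2002(mirrored)
    x = [0.35, 0.65]
    np.testing.assert_allclose(
        m.ln_gamma(x, T_ROOM), m_flip.ln_gamma(x, T_ROOM), atol=1e-10
    )


@pytest.mark.parametrize("x1", [0.999, 0.9999])
def test_gamma_approaches_one_toward_pure_limit(binary_components, x1):
    model = CosmoSac2002(binary_components)
    lng = model.ln_gamma([x1, 1 - x1], T_ROOM)
    assert abs(lng[0]) < abs(model.ln_gamma([0.9, 0.1], T_ROOM)[0])
    assert abs(lng[0]) < 5e-3


# ---------------------------------------------------------------------------
# Flory-Huggins
# ---------------------------------------------------------------------------

def _toy_records():
    return [
        HansenRecord("a", 18.0, 6.0, 8.0, volume=90.0),
        HansenRecord("b", 16.0, 10.0, 20.0, volume=40.0),
        HansenRecord("c", 15.0, 2.0, 3.0, volume=130.0),
    ]


def test_fh_chi_self_interaction_is_zero():
    rec = hansen_lookup("Ethanol")
    assert fh_chi(rec, rec, T_ROOM) == 0.0


def test_fh_chi_acetaminophen_water_hand_value():
    chi = fh_chi(hansen_lookup("Acetaminophen"), hansen_lookup("Water"), T_ROOM)
    assert chi == pytest.approx(11.376, abs=5e-3)


def test_fh_chi_asymmetry_scales_with_volume_ratio():
    a, w = hansen_lookup("Acetaminophen"), hansen_lookup("Water")
    assert fh_chi(w, a, T_ROOM) == pytest.approx(
        fh_chi(a, w, T_ROOM) * w.volume / a.volume, rel=1e-12
    )


@pytest.mark.parametrize("convention", FloryHuggins.CONVENTIONS)
def test_fh_pure_component_is_ideal(convention):
    model = FloryHuggins(_toy_records(), convention=convention)
    lng = model.ln_gamma([1.0, 0.0, 0.0], T_ROOM)
    assert lng[0] == pytest.approx(0.0, abs=1e-13)


@pytest.mark.parametrize("convention", FloryHuggins.CONVENTIONS)
def test_fh_identical_substances_are_ideal(convention):
    rec = _toy_records()[0]
    twin = HansenRecord("a2", rec.delta_d, rec.delta_p, rec.delta_h, volume=rec.volume)
    model = FloryHuggins([rec, twin], convention=convention)
    np.testing.assert_allclose(model.ln_gamma([0.25, 0.75], T_ROOM), 0.0, atol=1e-13)


@pytest.mark.parametrize("convention", FloryHuggins.CONVENTIONS)
def test_fh_matches_independent_oracle(convention):
    recs = _toy_records()
    model = FloryHuggins(recs, convention=convention)
    x = [0.2, 0.5, 0.3]
    got = model.ln_gamma(x, T_ROOM)
    want = oracles.naive_flory_huggins(
        [(r.delta_d, r.delta_p, r.delta_h, r.volume) for r in recs],
        x,
        T_ROOM,
        convention=convention,
    )
    np.testing.assert_allclose(got, want, atol=1e-9)


def _gibbs_duhem_residual(model, T, x1=0.35, h=1e-5):
    def lng(x):
        return model.ln_gamma([x, 1.0 - x], T)

    d = (np.asarray(lng(x1 + h)) - np.asarray(lng(x1 - h))) / (2 * h)
    return abs(x1 * d[0] + (1 - x1) * d[1])


def test_fh_regular_convention_satisfies_gibbs_duhem():
    model = FloryHuggins(_toy_records()[:2], convention="regular")
    assert _gibbs_duhem_residual(model, T_ROOM) < 1e-6


def test_fh_literal_expression_violates_gibbs_duhem():
    """The published activity expression is thermodynamically inconsistent;
    this pins the known defect of the literal form."""
    model = FloryHuggins(_toy_records()[:2], convention="per-volume")
    assert _gibbs_duhem_residual(model, T_ROOM) > 1e-2


# ---------------------------------------------------------------------------
# group contributions
# ---------------------------------------------------------------------------

def test_hansen_from_single_group_closed_form():
    rec = hansen_from_groups([(420.0, 300.0, 2000.0, 50.0)])
    assert rec.delta_d == pytest.approx(420.0 / 50.0)
    assert rec.delta_p == pytest.approx(300.0 / 50.0)
    assert rec.delta_h == pytest.approx(np.sqrt(2000.0) / 50.0)
    assert rec.delta_t == pytest.approx(rec.delta_t_from_parts())


def test_hansen_from_groups_rejects_empty_list():
    with pytest.raises(ValueError, match="group"):
        hansen_from_groups([])


@pytest.mark.parametrize(
    "name,expected",
    [("Acetylsalicylic acid", 29.06), ("Water", 47.8)],
)
def test_total_parameter_from_components_matches_printed(name, expected):
    rec = hansen_lookup(name)
    assert rec.delta_t_from_parts() == pytest.approx(expected, abs=0.05)
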