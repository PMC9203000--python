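"""Homogeneous inversion: slope fits, algebraic inverses, unmixing, pipeline."""
import copy

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import bilayerdos as bd
from bilayerdos.forward import _k_squared
from bilayerdos.inversion import cw_slope_model, fd_slope_model
from conftest import random_homogeneous_medium

OMEGA_FD = 2 * np.pi * 140.625e6
RHOS = (25.0, 35.0)


# ---------------------------------------------------------------------------
# slope fits
# ---------------------------------------------------------------------------

def test_cw_fit_round_trip_recovers_mueff():
    mua, musp = 0.02, 0.8
    mueff = np.sqrt(3 * mua * (mua + musp))
    vals = np.array([bd.homogeneous_reflectance(mua, musp, r) for r in RHOS])
    k = bd.fit_effective_attenuation(vals, RHOS, cw_slope_model(musp, 1.4))
    assert abs(k - mueff) / mueff < 1e-6


def test_fd_fit_round_trip_recovers_optical_properties():
    mua, musp = 0.01, 1.0
    vals = np.array([bd.homogeneous_reflectance(mua, musp, r, 1.4, OMEGA_FD)
                     for r in RHOS])
    k = bd.fit_effective_attenuation(vals, RHOS, fd_slope_model(OMEGA_FD, 1.4))
    mua_rec, musp_rec = bd.fd_optical_properties(k, OMEGA_FD, 1.4)
    assert abs(mua_rec - mua) / mua < 1e-6
    assert abs(musp_rec - musp) / musp < 1e-6


def test_fit_invariant_under_distance_order_swap():
    mua, musp = 0.02, 0.8
    vals = np.array([bd.homogeneous_reflectance(mua, musp, r) for r in RHOS])
    model = cw_slope_model(musp, 1.4)
    k1 = bd.fit_effective_attenuation(vals, RHOS, model)
    k2 = bd.fit_effective_attenuation(vals[::-1], RHOS[::-1], model)
    assert np.isclose(k1, k2, rtol=1e-12)


def test_fit_rejects_equal_distances():
    with pytest.raises(ValueError, match="distances"):
        bd.fit_effective_attenuation(np.array([1.0, 0.5]), (25.0, 25.0),
                                     cw_slope_model(0.5, 1.4))


def test_two_layer_cw_mueff_lies_between_layer_values(baseline, table):
    """The effective attenuation of a layered medium at 830 nm is bracketed
    by the two layers' homogeneous values (computed as brute-force bounds)."""
    basis = bd.build_extinction_matrix([830.0], table)
    bounds = []
    for lay in (baseline.top, baseline.bottom):
        mua = bd.absorption_spectrum(lay.chromophores, basis)[0]
        musp = bd.reduced_scattering_spectrum(lay.scattering, [830.0])[0]
        bounds.append(np.sqrt(3 * mua * (mua + musp)))
    musp_mid = 0.45
    vals = np.array([bd.two_layer_reflectance(baseline, 830.0, r, 0.0, table)
                     for r in RHOS])
    k = bd.fit_effective_attenuation(vals, RHOS, cw_slope_model(musp_mid, 1.4))
    assert min(bounds) < k < max(bounds)


# ---------------------------------------------------------------------------
# algebraic stages
# ---------------------------------------------------------------------------

def test_fd_property_equations_invert_complex_attenuation_exactly():
    """The mut'/mua expressions are the exact algebraic inverse of the
    complex attenuation definition (to 1e-9)."""
    for mua, musp in [(0.005, 0.3), (0.01, 1.0), (0.04, 1.8)]:
        k = np.sqrt(_k_squared(mua, musp, 1.4, OMEGA_FD))
        mua_rec, musp_rec = bd.fd_optical_properties(complex(k), OMEGA_FD, 1.4)
        assert abs(mua_rec - mua) <= 1e-9 * mua
        assert abs(musp_rec - musp) <= 1e-9 * musp


def test_fd_properties_reject_degenerate_and_conjugated_input():
    from bilayerdos.inversion import NonphysicalRecoveryError

    with pytest.raises(ValueError, match="FD information"):
        bd.fd_optical_properties(0.25 + 0.0j, OMEGA_FD, 1.4)
    k = np.sqrt(_k_squared(0.01, 1.0, 1.4, OMEGA_FD))
    with pytest.raises(NonphysicalRecoveryError):
        bd.fd_optical_properties(complex(np.conj(k)), OMEGA_FD, 1.4)


def test_broadband_absorption_inverts_effective_attenuation():
    mua, musp = 0.02, 0.5
    mueff = np.sqrt(3 * mua * (mua + musp))
    out = bd.broadband_absorption(np.array([mueff]), np.array([musp]))[0]
    assert abs(out - mua) < 1e-12
    assert bd.broadband_absorption(np.zeros(3), np.full(3, 0.5)).max() == 0.0
    # the output satisfies mueff^2 = 3 mua (mua + musp) by construction
    grid = np.linspace(0.01, 0.5, 20)
    mua_out = bd.broadband_absorption(grid, np.full_like(grid, 0.7))
    np.testing.assert_allclose(3 * mua_out * (mua_out + 0.7), grid**2, rtol=1e-10)


def test_scattering_extrapolation_published_example_and_identities():
    b, spectrum = bd.scattering_extrapolation(0.50, 0.42, [690.0, 830.0])
    assert round(b, 1) == 0.9
    assert abs(spectrum[0] - 0.50) < 1e-12  # evaluating back at 690 nm
    assert spectrum[1] == 0.42
    b0, flat = bd.scattering_extrapolation(0.45, 0.45, np.linspace(650, 1024, 5))
    assert b0 == 0.0
    np.testing.assert_array_equal(flat, 0.45)
    with pytest.raises(ValueError):
        bd.scattering_extrapolation(-0.1, 0.4, [700.0])


@settings(max_examples=25, deadline=None, derandomize=True)
@given(
    t=st.floats(0.0, 150.0), s=st.floats(0.0, 1.0),
    w=st.floats(0.0, 1.0), l=st.floats(0.0, 1.0),
)
def test_unmix_mix_identity(t, s, w, l):
    """Unmixing a spectrum synthesized from known concentrations with the
    same basis returns them to machine precision."""
    table = bd.load_default_extinction()
    basis = bd.build_extinction_matrix(np.linspace(650, 1024, 150), table)
    c = bd.ChromophoreConcentrations(t, s, w, l)
    rec = bd.unmix_chromophores(bd.absorption_spectrum(c, basis), basis)
    np.testing.assert_allclose(rec.as_vector(), c.as_vector(), rtol=1e-8, atol=1e-9)


def test_unmix_zero_spectrum_reports_missing_saturation(table):
    basis = bd.build_extinction_matrix(np.linspace(650, 1024, 60), table)
    rec = bd.unmix_chromophores(np.zeros(60), basis)
    assert rec.thb_uM == pytest.approx(0.0, abs=1e-12)
    assert np.isnan(rec.so2)


def test_unmix_rejects_rank_deficient_basis():
    basis = np.ones((30, 4))
    with pytest.raises(ValueError, match="rank"):
        bd.unmix_chromophores(np.ones(30), basis)


# ---------------------------------------------------------------------------
# end-to-end pipeline
# ---------------------------------------------------------------------------

def test_homogeneous_media_recovered_exactly(instrument, table):
    """Matched forward/inverse models: 10 random homogeneous media recover
    (T, W, L, mus') within 2%, S within 1 point, b within 0.05."""
    rng = np.random.default_rng(7)
    for _ in range(10):
        med = random_homogeneous_medium(rng)
        rec = bd.recover_all(bd.simulate_instrument(med, instrument, table),
                             instrument, table)
        actual = med.bottom.chromophores
        assert rec.chromophores.thb_uM == pytest.approx(actual.thb_uM, rel=0.02)
        assert abs(rec.chromophores.so2 - actual.so2) < 0.01
        assert rec.chromophores.water == pytest.approx(actual.water, rel=0.02)
        assert rec.chromophores.lipid == pytest.approx(actual.lipid, rel=0.02)
        i830 = int(np.argmin(np.abs(rec.fd_wavelengths - 830.0)))
        assert rec.musp_fd[i830] == pytest.approx(med.bottom.scattering.musp830, rel=0.02)
        assert abs(rec.b_rec - med.bottom.scattering.power) < 0.05


def test_fd_data_used_only_for_scattering(baseline_data, instrument, table):
    """Perturbing the CW data leaves musp_fd and b_rec untouched."""
    rec0 = bd.recover_all(baseline_data, instrument, table)
    perturbed = copy.deepcopy(baseline_data)
    perturbed.cw *= np.exp(0.03 * np.random.default_rng(0).standard_normal(perturbed.cw.shape))
    rec1 = bd.recover_all(perturbed, instrument, table)
    np.testing.assert_array_equal(rec1.musp_fd, rec0.musp_fd)
    assert rec1.b_rec == rec0.b_rec
    assert not np.allclose(rec1.mua_cw, rec0.mua_cw)


def test_water_only_medium_recovers_water_fraction(instrument, table):
    layer = bd.Layer(bd.ChromophoreConcentrations(0.0, 0.0, 0.5, 0.0),
                     bd.ScatteringLaw(0.5, 1.0))
    med = bd.TwoLayerMedium(layer, layer, 5.0)
    rec = bd.recover_all(bd.simulate_instrument(med, instrument, table),
                         instrument, table)
    assert abs(rec.chromophores.thb_uM) < 0.5
    assert rec.chromophores.water == pytest.approx(0.5, abs=0.01)


def test_recovered_musp_spectrum_follows_power_law(baseline_rec):
    i830 = int(np.argmin(np.abs(baseline_rec.fd_wavelengths - 830.0)))
    expected = baseline_rec.musp_fd[i830] * (
        baseline_rec.cw_wavelengths / 830.0) ** (-baseline_rec.b_rec)
    np.testing.assert_allclose(baseline_rec.musp_cw, expected, rtol=1e-12)
    # and mueff/mua satisfy the CW diffusion relation on output
    np.testing.assert_allclose(
        baseline_rec.mueff_cw**2,
        3 * baseline_rec.mua_cw * (baseline_rec.mua_cw + baseline_rec.musp_cw),
        rtol=1e-9,
    )


def test_two_layer_mueff_bracketed_by_layer_bounds(baseline, baseline_rec, table):
    """The recovered CW effective attenuation lies between the two layers'
    homogeneous values at every wavelength (brute-force bounds)."""
    grid = baseline_rec.cw_wavelengths
    basis = bd.build_extinction_matrix(grid, table)
    lo = np.full(len(grid), np.inf)
    hi = np.full(len(grid), -np.inf)
    for lay in (baseline.top, baseline.bottom):
        mua = bd.absorption_spectrum(lay.chromophores, basis)
        musp = bd.reduced_scattering_spectrum(lay.scattering, grid)
        mueff = np.sqrt(3 * mua * (mua + musp))
        lo = np.minimum(lo, mueff)
        hi = np.maximum(hi, mueff)
    assert np.all(baseline_rec.mueff_cw > lo) and np.all(baseline_rec.mueff_cw < hi)
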