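"""Analytic depth dose, lateral spread and beamlet superposition."""
import math

import numpy as np
import pytest
from scipy.integrate import quad
from scipy.signal import find_peaks

from minibeams.errors import ConfigError, DomainError
from minibeams.dose import (GridSpec, bragg_depth_dose, compute_dose,
                            lateral_sigma, scattering_power)
from minibeams.geometry import SpotGrid, make_scenario
from minibeams.optics import build_field_table, reference_landing_x
from minibeams.physics import WATER_RADIATION_LENGTH_MM
from minibeams.synth import single_slit_scenario


def test_bragg_curve_shape(rm_tab):
    z = np.arange(0.0, 250.0, 0.1)
    d = bragg_depth_dose(150.0, z, range_model=rm_tab)
    r = rm_tab.range_mm(150.0)
    assert abs(z[np.argmax(d)] - r) <= 1.0          # peak at the range
    assert d[0] < d.max()                           # entrance below peak
    assert bragg_depth_dose(150.0, r + 40.0, range_model=rm_tab) == 0.0
    assert np.all(d >= 0.0)


def test_bragg_curve_broadens_with_energy_spread(rm_tab):
    z = np.arange(140.0, 180.0, 0.05)
    d0 = bragg_depth_dose(150.0, z, range_model=rm_tab)
    d1 = bragg_depth_dose(150.0, z, range_model=rm_tab,
                          energy_spread_sigma_mev=2.0)
    width = lambda d: np.ptp(z[d >= 0.5 * d.max()])
    assert width(d1) > width(d0)


def test_lateral_sigma_source_limit_and_monotonicity(rm_tab):
    assert lateral_sigma(150.0, 0.0, sigma0=0.2, range_model=rm_tab) == \
        pytest.approx(0.2, abs=1e-12)
    z = np.linspace(0.0, rm_tab.range_mm(150.0), 100)
    s = lateral_sigma(150.0, z, sigma0=0.2, range_model=rm_tab)
    assert np.all(np.diff(s) >= 0.0)


def test_lateral_sigma_matches_quadrature_oracle(rm_tab):
    """Fermi-Eyges variance vs direct adaptive quadrature at 70 mm depth."""
    r = rm_tab.range_mm(150.0)
    z = 70.0
    var_ref, _ = quad(lambda u: (z - u) ** 2 * scattering_power(
        rm_tab.energy_from_range_mm(max(r - u, 0.05))), 0.0, z, limit=200)
    got = lateral_sigma(150.0, z, sigma0=0.0, range_model=rm_tab)
    assert got == pytest.approx(math.sqrt(var_ref), rel=0.01)


def test_lateral_sigma_beyond_range_rejected(rm_tab):
    with pytest.raises(DomainError):
        lateral_sigma(150.0, rm_tab.range_mm(150.0) + 5.0, range_model=rm_tab)


def test_grid_specs_match_reference_lattice():
    assert GridSpec.full().shape == (1000, 50, 300)
    assert GridSpec.coarse().shape == (500, 10, 150)


def test_config1_ridges_land_on_straight_drift_positions(grid_config1_150,
                                                         config1, rm_tab):
    """15 dose ridges whose Bragg-peak x positions follow the straight-drift
    landing equation per slit."""
    x, prof = grid_config1_150.transverse_profile(rm_tab.range_mm(150.0) / 2)
    idx, _ = find_peaks(prof, prominence=0.05 * prof.max())
    assert idx.size == 15
    zq = grid_config1_150.z_coords()[
        np.argmin(np.abs(grid_config1_150.z_coords() - rm_tab.range_mm(150.0) / 2))]
    expected = sorted(
        x1 + (config1.collimator.thickness + config1.air_gap + zq)
        * math.tan(t) for x1, t in config1.collimator.slit_positions())
    np.testing.assert_allclose(x[idx], expected, atol=0.25)


def test_zero_spot_weight_gives_zero_grid(config1, rm_tab):
    sg = SpotGrid(dx=4.0, energy=150.0, weight=0.0)
    g = compute_dose(config1, spot_grid=sg, grid="coarse", range_model=rm_tab)
    assert np.all(g.values == 0.0)


def test_dose_nonnegative_and_mirror_symmetric(grid_config1_150):
    v = grid_config1_150.values
    assert np.all(v >= 0.0)
    flipped = v[::-1]
    denom = np.maximum(v, 1e-12 * v.max())
    assert np.max(np.abs(flipped - v) / denom) < 0.01


def test_beamlet_transverse_integral_tracks_depth_dose(rm_tab):
    """The x-integral at fixed depth scales exactly with the depth-dose
    curve (flux normalization is depth independent)."""
    scn = single_slit_scenario()
    g = compute_dose(scn, energy=150.0, grid="coarse", range_model=rm_tab)
    z = g.z_coords()
    iy = np.argmin(np.abs(g.y_coords()))
    i1, i2 = np.argmin(np.abs(z - 50.0)), np.argmin(np.abs(z - 120.0))
    integ1 = g.values[:, iy, i1].sum() * g.voxel[0]
    integ2 = g.values[:, iy, i2].sum() * g.voxel[0]
    from minibeams.dose import MACHINE_ENERGY_SPREAD_SIGMA_MEV
    d1 = bragg_depth_dose(150.0, z[i1], range_model=rm_tab,
                          energy_spread_sigma_mev=MACHINE_ENERGY_SPREAD_SIGMA_MEV)
    d2 = bragg_depth_dose(150.0, z[i2], range_model=rm_tab,
                          energy_spread_sigma_mev=MACHINE_ENERGY_SPREAD_SIGMA_MEV)
    assert integ1 / integ2 == pytest.approx(d1 / d2, rel=1e-3)


def test_single_slit_scenario_yields_one_ridge(rm_tab):
    g = compute_dose(single_slit_scenario(), energy=150.0, grid="coarse",
                     range_model=rm_tab)
    x, prof = g.transverse_profile(70.0)
    idx, _ = find_peaks(prof, prominence=0.05 * prof.max())
    assert idx.size == 1 and abs(x[idx[0]]) < 0.3


def _central_fwhm(grid, z):
    x, p = grid.transverse_profile(z)
    m = np.abs(x) < 2.9
    xm, pm = x[m], p[m]
    half = pm.max() / 2.0
    i0 = int(np.argmax(pm))
    il = np.where(pm[:i0] < half)[0][-1]
    xl = np.interp(half, [pm[il], pm[il + 1]], [xm[il], xm[il + 1]])
    ir = i0 + np.where(pm[i0:] < half)[0][0]
    xr = np.interp(half, [pm[ir], pm[ir - 1]], [xm[ir], xm[ir - 1]])
    return xr - xl


@pytest.fixture(scope="module")
def dipole_grids(rm_tab):
    grids = {}
    for name in ("config2", "config2p"):
        scn = make_scenario(name)
        ft = build_field_table(scn, [150.0], range_model=rm_tab)
        grids[name] = compute_dose(scn, energy=150.0, field_table=ft,
                                   grid="coarse", range_model=rm_tab)
    return grids


def test_static_collimator_broadening(dipole_grids, grid_config1_150, rm_tab):
    """Non-optimized deflection of neighbor-spot flux broadens the static
    multislit minibeams; the dynamic aperture is immune."""
    z_mid = rm_tab.range_mm(150.0) / 2.0
    w2 = _central_fwhm(dipole_grids["config2"], z_mid)
    w2p = _central_fwhm(dipole_grids["config2p"], z_mid)
    w1 = _central_fwhm(grid_config1_150, z_mid)
    assert w2 > w2p
    assert abs(w1 / w2p - 1.0) < 0.10
    # the effect is already visible at the phantom entrance
    assert _central_fwhm(dipole_grids["config2"], 1.0) > \
        _central_fwhm(dipole_grids["config2p"], 1.0)


def test_field_region_requires_field_table(rm_tab):
    with pytest.raises(ConfigError):
        compute_dose(make_scenario("config3"), energy=150.0, grid="coarse",
                     range_model=rm_tab)
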