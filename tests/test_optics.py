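"""Trajectories, dipole kicks and field optimization."""
import math

import numpy as np
import pytest

from minibeams.errors import DomainError, InfeasibleFieldError
from minibeams.geometry import make_scenario
from minibeams.optics import (build_field_table, dipole_exit_angle,
                              dipole_landing_x, integrate_trajectory,
                              phantom_entry_x, phantom_landing_x,
                              reference_landing_x, solve_dipole_field,
                              solve_phantom_field)
from minibeams.physics import magnetic_rigidity


def test_reference_landing_on_axis_is_zero(config1, rm_tab):
    for e in (100.0, 150.0, 200.0):
        assert reference_landing_x(0.0, e, config1, range_model=rm_tab) == 0.0


def test_reference_landing_examples(config1, rm_tab):
    # direct evaluation of the straight-drift equation with R from the model
    assert reference_landing_x(4.0, 100.0, config1, range_model=rm_tab) == \
        pytest.approx(4.37, abs=0.005)
    assert reference_landing_x(28.0, 100.0, config1, range_model=rm_tab) == \
        pytest.approx(30.59, abs=0.005)


def test_dipole_exit_angle_zero_field_identity():
    assert dipole_exit_angle(0.01, 0.0, 100.0, 50.0) == 0.01


def test_dipole_exit_angle_closed_form():
    theta = 0.002
    phi = dipole_exit_angle(theta, 1.0, 100.0, 50.0)
    expected = theta - math.asin(0.050 / magnetic_rigidity(100.0))
    assert phi == pytest.approx(expected, abs=1e-12)


def test_dipole_exit_angle_infeasible_when_radius_too_small():
    with pytest.raises(InfeasibleFieldError):
        dipole_exit_angle(0.0, 50.0, 100.0, 50.0)


@pytest.mark.parametrize("energy, b", [(100.0, 1.0), (150.0, 0.5), (200.0, 1.4)])
def test_dipole_kick_matches_vacuum_rk4(energy, b, rm_tab):
    """Closed-form kick vs in-dipole RK4 tracking, r >= 20 * dz_dip."""
    assert 1000.0 * magnetic_rigidity(energy) / b >= 20 * 50.0
    theta = 0.01
    phi = dipole_exit_angle(theta, b, energy, 50.0)
    tr = integrate_trajectory(0.0, theta, b, energy, range_model=rm_tab,
                              medium="vacuum", track_length=60.0, ds=0.02)
    phi_rk = np.interp(50.0, tr.z, tr.angle)
    assert abs((theta - phi_rk) / (theta - phi) - 1.0) < 1e-3


def test_dipole_landing_zero_field_reduces_to_straight_drift(rm_tab):
    scn = make_scenario("config2")
    for x1 in (6.0, 18.0, 42.0):
        ref = reference_landing_x(x1, 150.0, scn, range_model=rm_tab)
        assert dipole_landing_x(x1, 0.0, 150.0, scn, range_model=rm_tab) == \
            pytest.approx(ref, abs=1e-12)


def test_dipole_landing_monotone_in_field(rm_tab):
    scn = make_scenario("config2")
    bs = np.linspace(0.0, 3.0, 30)
    x2 = [dipole_landing_x(6.0, b, 100.0, scn, range_model=rm_tab) for b in bs]
    assert np.all(np.diff(x2) < 0)


def test_dipole_solver_round_trip_within_micron(rm_tab, config1):
    scn = make_scenario("config2")
    target = reference_landing_x(4.0, 100.0, config1, range_model=rm_tab)
    b = solve_dipole_field(6.0, 100.0, target, scn, range_model=rm_tab)
    landed = dipole_landing_x(6.0, b, 100.0, scn, range_model=rm_tab)
    assert abs(landed - target) < 1e-3


def test_unknown_drift_convention_rejected(rm_tab):
    scn = make_scenario("config2")
    with pytest.raises(DomainError):
        dipole_landing_x(6.0, 0.5, 100.0, scn, range_model=rm_tab,
                         drift_convention="teleport")


def test_integrate_zero_field_is_straight(rm_tab):
    theta = math.radians(0.3)
    tr = integrate_trajectory(5.0, theta, 0.0, 150.0, range_model=rm_tab)
    r = rm_tab.range_mm(150.0)
    assert tr.path_length == pytest.approx(r, abs=1e-9)
    assert tr.end_depth == pytest.approx(r * math.cos(theta), abs=1e-6)
    assert tr.landing_x == pytest.approx(5.0 + tr.end_depth * math.tan(theta),
                                         abs=1e-6)
    assert np.all(np.diff(tr.z) > 0)


def test_integrate_lateral_deflection_example(config3p, rm_tab):
    """~2.1 mm deflection for the first off-axis slit at 100 MeV, 0.883 T."""
    x_e = phantom_entry_x(6.0, config3p)
    theta = math.radians(0.15)
    tr = integrate_trajectory(x_e, theta, 0.883, 100.0, range_model=rm_tab)
    straight = x_e + rm_tab.range_mm(100.0) * math.tan(theta)
    assert straight - tr.landing_x == pytest.approx(2.1, abs=0.1)


def test_integrate_step_halving_converged(rm_tab):
    land = [integrate_trajectory(44.47, math.radians(1.05), 6.6, 100.0,
                                 range_model=rm_tab, ds=ds).landing_x
            for ds in (0.1, 0.05)]
    assert abs(land[0] - land[1]) < 1e-4   # < 0.1 um


def test_phantom_solver_zero_target_gives_zero_field(config3p, rm_tab):
    free = phantom_landing_x(6.0, 0.0, 100.0, config3p, range_model=rm_tab)
    b = solve_phantom_field(6.0, 100.0, free, config3p, range_model=rm_tab)
    assert b == pytest.approx(0.0, abs=1e-6)


@pytest.mark.parametrize("x1_ref, x1, energy, table1", [
    (4.0, 6.0, 100.0, 0.883),
    (28.0, 42.0, 100.0, 6.181),
])
def test_phantom_solver_near_reported_fields(x1_ref, x1, energy, table1,
                                             config1, config3p, rm_tab):
    target = reference_landing_x(x1_ref, energy, config1, range_model=rm_tab)
    b = solve_phantom_field(x1, energy, target, config3p, range_model=rm_tab)
    assert b == pytest.approx(table1, rel=0.10)


def test_phantom_solver_mirror_symmetry(config1, config3p, rm_tab):
    target = reference_landing_x(4.0, 100.0, config1, range_model=rm_tab)
    b_pos = solve_phantom_field(6.0, 100.0, target, config3p, range_model=rm_tab)
    b_neg = solve_phantom_field(-6.0, 100.0, -target, config3p, range_model=rm_tab)
    assert b_neg == pytest.approx(b_pos, abs=1e-9)


def test_phantom_solver_infeasible_target_reports_achievable(config3p, rm_tab):
    free = phantom_landing_x(6.0, 0.0, 100.0, config3p, range_model=rm_tab)
    with pytest.raises(InfeasibleFieldError) as exc:
        solve_phantom_field(6.0, 100.0, free + 5.0, config3p, range_model=rm_tab)
    assert exc.value.achievable is not None


def test_build_field_table_shape_and_monotonicity(config3p, rm_tab):
    table = build_field_table(config3p, [100.0, 150.0, 200.0], range_model=rm_tab)
    assert len(table) == 21
    assert not table.attrs["errors"]
    for e, sub in table.groupby("energy_MeV"):
        b = sub.sort_values("slit_offset_mm")["field_T"].to_numpy()
        assert np.all(np.diff(b) > 0)            # grows with off-axis distance
    for off, sub in table.groupby("slit_offset_mm"):
        b = sub.sort_values("energy_MeV")["field_T"].to_numpy()
        assert np.all(np.diff(b) < 0)            # falls with energy


def test_field_ratio_doubles_with_offset(field_table_3p_150):
    sub = field_table_3p_150.sort_values("slit_offset_mm")
    b = sub["field_T"].to_numpy()
    assert b[1] / b[0] == pytest.approx(2.0, rel=0.01)


def test_field_table_closed_loop(config1, config3p, rm_tab, field_table_3p_150):
    """Re-simulating each optimized row lands back on its target within 1 um."""
    for _, row in field_table_3p_150.iterrows():
        k = row.slit_offset_mm / config3p.collimator.ctc
        target = reference_landing_x(k * 4.0, row.energy_MeV, config1,
                                     range_model=rm_tab)
        landed = phantom_landing_x(row.slit_offset_mm, row.field_T,
                                   row.energy_MeV, config3p, range_model=rm_tab)
        assert abs(landed - target) < 1e-3


def test_empty_energy_list_gives_empty_table(config3p, rm_tab):
    table = build_field_table(config3p, [], range_model=rm_tab)
    assert table.empty and list(table.columns) == [
        "configuration", "slit_offset_mm", "energy_MeV", "field_T"]


def test_dipole_table_qualitative_table1_behavior(rm_tab):
    """Dipole-configuration fields keep the reported orderings (the
    absolute values are geometry-convention dependent)."""
    scn = make_scenario("config2")
    table = build_field_table(scn, [100.0, 150.0], range_model=rm_tab)
    assert not table.attrs["errors"]
    b100 = table[table.energy_MeV == 100.0].sort_values("slit_offset_mm")["field_T"].to_numpy()
    b150 = table[table.energy_MeV == 150.0].sort_values("slit_offset_mm")["field_T"].to_numpy()
    assert np.all(np.diff(b100) > 0) and np.all(b150 < b100)
    assert b100[1] / b100[0] == pytest.approx(2.0, rel=0.01)
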