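"""Minibeam central-axis trajectories in magnetic fields and per-slit,
per-energy field optimization.

The converging-pattern idea: a collimator with an enlarged center-to-center
distance (6 mm) is combined with a deflecting field so that every minibeam
lands, at its Bragg peak, exactly where the corresponding minibeam of the
4 mm-ctc no-field reference lands.  Two field placements are supported:

* a uniform dipole of finite thickness in the air gap (closed-form exit
  angle via the Larmor radius, then a straight drift), and
* a uniform field filling the water phantom (MRI-like), in which the proton
  slows down while bending; handled by Runge-Kutta integration of the
  curvature ODE with residual-range bookkeeping.

Sign conventions: a positive field strength always bends the beam toward
the axis; slits at -x1 require the same field magnitude with the opposite
bending sign (mirror symmetry).
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .errors import DomainError, InfeasibleFieldError, OutOfBoundsError
from .geometry import Scenario, reference_scenario
from .physics import RangeModel, DEFAULT_RANGE_MODEL, magnetic_rigidity

DRIFT_CONVENTIONS = ("remaining-air+range", "range-only", "dipole-center")


@dataclass
class Trajectory:
    """Sampled central-axis path of one minibeam.

    ``z`` (mm, increasing), ``x`` (mm) and ``angle`` (rad, atan(dx/dz)) are
    parallel arrays; ``s`` is the accumulated path length.  ``landing_x`` is
    the lateral position where integration stopped.
    """

    z: np.ndarray
    x: np.ndarray
    angle: np.ndarray
    s: np.ndarray
    entry_x: float
    landing_x: float
    exit_x: float | None = None

    @property
    def path_length(self) -> float:
        return float(self.s[-1])

    @property
    def end_depth(self) -> float:
        return float(self.z[-1])

    def x_at(self, z):
        """Lateral position interpolated at depth(s) z (mm)."""
        return np.interp(z, self.z, self.x)

    def s_at(self, z):
        """Accumulated path length interpolated at depth(s) z (mm)."""
        return np.interp(z, self.z, self.s)


def _tilt(scenario: Scenario, x1: float, tilt):
    return scenario.collimator.tilt_at(x1) if tilt is None else tilt


def reference_landing_x(x1: float, energy: float, scenario: Scenario,
                        range_model: RangeModel | None = None,
                        tilt: float | None = None) -> float:
    """Straight-drift landing position at the Bragg peak (no field).

    x2 = x1 + (dz_coll + dz_air + R(E)) * tan(theta), with theta the slit
    tilt at x1.
    """
    rm = range_model or DEFAULT_RANGE_MODEL
    theta = _tilt(scenario, x1, tilt)
    drift = scenario.collimator.thickness + scenario.air_gap + rm.range_mm(energy)
    return x1 + drift * math.tan(theta)


def dipole_exit_angle(theta: float, b_field: float, energy: float,
                      dipole_thickness: float) -> float:
    """Angle to the beamline axis at the dipole exit (rad).

    phi = theta - asin(dz_dip / r) with r the Larmor radius
    rigidity(E) / B.  B = 0 returns theta unchanged.  A positive field
    bends toward -x (converging for slits at +x1).
    """
    if b_field == 0.0:
        return theta
    r_mm = 1000.0 * magnetic_rigidity(energy) / abs(b_field)
    if r_mm <= dipole_thickness:
        raise InfeasibleFieldError(
            f"Larmor radius {r_mm:.1f} mm does not exceed the dipole "
            f"thickness {dipole_thickness} mm; the beam cannot traverse")
    kick = math.asin(dipole_thickness / r_mm)
    return theta - math.copysign(kick, b_field)


def dipole_landing_x(x1: float, b_field: float, energy: float,
                     scenario: Scenario,
                     range_model: RangeModel | None = None,
                     tilt: float | None = None,
                     drift_convention: str = "remaining-air+range") -> float:
    """Bragg-peak landing position for the dipole configuration.

    The proton drifts straight through the collimator, is kicked by the
    dipole (exit abscissa approximated by the straight-through value, since
    the Larmor radius is much larger than the dipole), then drifts straight
    to its Bragg peak.  ``drift_convention`` selects which longitudinal
    distances the pre-kick and post-kick drifts cover:

    ``remaining-air+range`` (default)
        pre-kick: collimator + dipole; post-kick: remaining air + R(E).
        Reduces exactly to the no-field straight-drift landing at B = 0.
    ``range-only``
        the literal thin-element reading: x2 = x1 + R(E) tan(phi).
    ``dipole-center``
        kick applied at the dipole mid-plane.
    """
    rm = range_model or DEFAULT_RANGE_MODEL
    if scenario.dipole_thickness is None:
        raise DomainError("scenario has no dipole")
    theta = _tilt(scenario, x1, tilt)
    phi = dipole_exit_angle(theta, b_field, energy, scenario.dipole_thickness)
    r_e = rm.range_mm(energy)
    dz_coll = scenario.collimator.thickness
    dz_dip = scenario.dipole_thickness
    dz_air = scenario.air_gap
    if drift_convention == "remaining-air+range":
        pre, post = dz_coll + dz_dip, (dz_air - dz_dip) + r_e
    elif drift_convention == "range-only":
        pre, post = 0.0, r_e
    elif drift_convention == "dipole-center":
        pre, post = dz_coll + dz_dip / 2.0, (dz_air - dz_dip / 2.0) + r_e
    else:
        raise DomainError(f"unknown drift convention {drift_convention!r}; "
                          f"choose one of {DRIFT_CONVENTIONS}")
    return x1 + pre * math.tan(theta) + post * math.tan(phi)


def _curvature_profile(energy: float, rm: RangeModel, ds: float,
                       medium: str):
    """Inverse rigidity 1/(B*rho) (1/(T*mm)) sampled on the RK4 s-grid
    (nodes and midpoints), plus the grid itself."""
    r_total = rm.range_mm(energy) if medium == "water" else None
    if medium == "vacuum":
        return None, None, None
    n = max(2, int(math.ceil(r_total / ds)))
    nodes = np.linspace(0.0, r_total, n + 1)
    mids = 0.5 * (nodes[:-1] + nodes[1:])
    # residual range floor keeps the (integrable) end-of-range curvature
    # singularity finite on the last step
    floor = 1e-3
    def inv_brho(s):
        res = np.maximum(r_total - s, floor)
        e = rm.energy_from_range_mm(res)
        return 1.0 / (1000.0 * magnetic_rigidity(np.maximum(e, 1e-6)))
    return nodes, inv_brho(nodes), inv_brho(mids)


def integrate_trajectory(entry_x: float, entry_angle: float, b_field: float,
                         energy: float, *,
                         range_model: RangeModel | None = None,
                         stop: str = "at-range", depth: float | None = None,
                         ds: float = 0.1, medium: str = "water",
                         x_bounds: tuple = (-50.0, 50.0),
                         track_length: float | None = None) -> Trajectory:
    """RK4 integration of a proton central axis in a uniform +y field.

    The ODE system, parameterized by arc length s, is

        dx/ds = sin(alpha),  dz/ds = cos(alpha),
        dalpha/ds = -B / (B*rho)(E(s)),

    where in water the energy follows the residual range R(E0) - s
    (continuous slowing down) and in vacuum it is constant.  A positive
    ``b_field`` bends toward -x.  Integration stops when the path length
    reaches the CSDA range (``stop='at-range'``), or at the requested
    ``depth`` (``stop='at-depth'``).

    Raises :class:`OutOfBoundsError` (with the partial trajectory attached)
    if the axis leaves ``x_bounds`` laterally.
    """
    rm = range_model or DEFAULT_RANGE_MODEL
    if b_field is None:
        raise DomainError("b_field must be a number (may be 0)")
    if medium not in ("water", "vacuum"):
        raise DomainError(f"unknown medium {medium!r}")
    if stop == "at-depth" and depth is None:
        raise DomainError("stop='at-depth' requires depth")
    if stop not in ("at-range", "at-depth"):
        raise DomainError(f"unknown stop condition {stop!r}")

    if medium == "water":
        s_total = rm.range_mm(energy)
        nodes, inv_nodes, inv_mids = _curvature_profile(energy, rm, ds, medium)
        n_steps = len(nodes) - 1
        h = nodes[1] - nodes[0]
    else:
        if track_length is None:
            raise DomainError("vacuum integration requires track_length")
        s_total = track_length
        n_steps = max(2, int(math.ceil(s_total / ds)))
        h = s_total / n_steps
        inv_const = 1.0 / (1000.0 * magnetic_rigidity(energy))
        inv_nodes = np.full(n_steps + 1, inv_const)
        inv_mids = np.full(n_steps, inv_const)

    x, z, alpha, s = float(entry_x), 0.0, float(entry_angle), 0.0
    xs, zs, als, ss = [x], [z], [alpha], [s]
    lo, hi = x_bounds
    done = False
    for i in range(n_steps):
        ka, kb = -b_field * inv_nodes[i], -b_field * inv_mids[i]
        kc = -b_field * inv_nodes[i + 1]
        # RK4 stages for y' = f(s, y); curvature depends on s only
        a1 = alpha
        a2 = alpha + 0.5 * h * ka
        a3 = alpha + 0.5 * h * kb
        a4 = alpha + h * kb
        dx = h / 6.0 * (math.sin(a1) + 2 * math.sin(a2) + 2 * math.sin(a3)
                        + math.sin(a4))
        dz = h / 6.0 * (math.cos(a1) + 2 * math.cos(a2) + 2 * math.cos(a3)
                        + math.cos(a4))
        dalpha = h / 6.0 * (ka + 4 * kb + kc)
        if stop == "at-depth" and z + dz >= depth:
            frac = (depth - z) / dz
            x, z, alpha, s = (x + frac * dx, depth, alpha + frac * dalpha,
                              s + frac * h)
            done = True
        else:
            x, z, alpha, s = x + dx, z + dz, alpha + dalpha, s + h
        xs.append(x); zs.append(z); als.append(alpha); ss.append(s)
        if not lo < x < hi:
            traj = Trajectory(z=np.array(zs), x=np.array(xs),
                              angle=np.array(als), s=np.array(ss),
                              entry_x=float(entry_x), landing_x=x)
            raise OutOfBoundsError(
                f"trajectory left the phantom laterally at x={x:.2f} mm, "
                f"z={z:.2f} mm", trajectory=traj)
        if done:
            break
    return Trajectory(z=np.array(zs), x=np.array(xs), angle=np.array(als),
                      s=np.array(ss), entry_x=float(entry_x), landing_x=x)


def phantom_entry_x(x1: float, scenario: Scenario,
                    tilt: float | None = None) -> float:
    """Lateral position of a minibeam at the phantom entrance (no field
    upstream of the phantom)."""
    theta = _tilt(scenario, x1, tilt)
    return x1 + (scenario.collimator.thickness + scenario.air_gap) * math.tan(theta)


def phantom_landing_x(x1: float, b_field: float, energy: float,
                      scenario: Scenario,
                      range_model: RangeModel | None = None,
                      tilt: float | None = None, ds: float = 0.1) -> float:
    """End-of-range landing position with a uniform in-phantom field."""
    theta = _tilt(scenario, x1, tilt)
    try:
        traj = integrate_trajectory(phantom_entry_x(x1, scenario, tilt=tilt),
                                    theta, b_field, energy,
                                    range_model=range_model, ds=ds)
    except OutOfBoundsError as exc:
        # overdriven field: report the exit abscissa so root bracketing
        # stays continuous and monotone
        return exc.trajectory.landing_x
    return traj.landing_x


def _solve_field(landing, target_x2: float, bracket=(0.0, 10.0),
                 xtol: float = 1e-7) -> float:
    f_lo, f_hi = landing(bracket[0]) - target_x2, landing(bracket[1]) - target_x2
    if f_lo == 0.0:
        return bracket[0]
    if f_lo * f_hi > 0:
        raise InfeasibleFieldError(
            f"target landing {target_x2:.3f} mm is outside the achievable "
            f"interval [{landing(bracket[1]):.3f}, {landing(bracket[0]):.3f}] mm "
            f"for fields in {bracket} T",
            achievable=(landing(bracket[1]), landing(bracket[0])))
    return brentq(lambda b: landing(b) - target_x2, *bracket, xtol=xtol)


def solve_dipole_field(x1: float, energy: float, target_x2: float,
                       scenario: Scenario,
                       range_model: RangeModel | None = None,
                       tilt: float | None = None,
                       drift_convention: str = "remaining-air+range",
                       bracket=(0.0, 10.0)) -> float:
    """Dipole field (T) landing the minibeam from slit x1 at ``target_x2``.

    Brent root of the closed-form landing position; mirror slits (x1 < 0)
    return the same magnitude.  Landing tolerance is ~1e-6 mm.
    """
    if x1 < 0:
        return solve_dipole_field(-x1, energy, -target_x2, scenario,
                                  range_model=range_model,
                                  tilt=None if tilt is None else -tilt,
                                  drift_convention=drift_convention,
                                  bracket=bracket)
    return _solve_field(
        lambda b: dipole_landing_x(x1, b, energy, scenario,
                                   range_model=range_model, tilt=tilt,
                                   drift_convention=drift_convention),
        target_x2, bracket=bracket)


def solve_phantom_field(x1: float, energy: float, target_x2: float,
                        scenario: Scenario,
                        range_model: RangeModel | None = None,
                        tilt: float | None = None, ds: float = 0.1,
                        bracket=(0.0, 10.0)) -> float:
    """Uniform in-phantom field (T) landing the minibeam at ``target_x2``.

    Root solve over RK4 slowing-down trajectories.  Mirror slits return the
    same magnitude.
    """
    if x1 < 0:
        return solve_phantom_field(-x1, energy, -target_x2, scenario,
                                   range_model=range_model,
                                   tilt=None if tilt is None else -tilt,
                                   ds=ds, bracket=bracket)
    return _solve_field(
        lambda b: phantom_landing_x(x1, b, energy, scenario,
                                    range_model=range_model, tilt=tilt, ds=ds),
        target_x2, bracket=bracket)


def build_field_table(scenario: Scenario, energies,
                      range_model: RangeModel | None = None,
                      drift_convention: str = "remaining-air+range",
                      ds: float = 0.1) -> pd.DataFrame:
    """Optimized field strength per (positive off-axis slit, energy).

    Each slit of the enlarged-ctc collimator is matched index-to-index to
    the corresponding slit of the 4 mm-ctc no-field reference: the field is
    solved so both land at the same Bragg-peak abscissa.  Returns a tidy
    DataFrame with columns ``configuration, slit_offset_mm, energy_MeV,
    field_T``; rows whose solve fails carry NaN and the error is collected
    in ``df.attrs['errors']``.
    """
    rm = range_model or DEFAULT_RANGE_MODEL
    if scenario.field_region == "none":
        raise DomainError("scenario has no field region to optimize")
    ref = reference_scenario(scenario)
    half = (scenario.collimator.n_slits - 1) // 2
    rows, errors = [], []
    for energy in energies:
        for k in range(1, half + 1):
            x1 = k * scenario.collimator.ctc
            x1_ref = k * ref.collimator.ctc
            target = reference_landing_x(x1_ref, energy, ref, range_model=rm)
            try:
                if scenario.field_region == "dipole":
                    b = solve_dipole_field(x1, energy, target, scenario,
                                           range_model=rm,
                                           drift_convention=drift_convention)
                else:
                    b = solve_phantom_field(x1, energy, target, scenario,
                                            range_model=rm, ds=ds)
            except (InfeasibleFieldError, OutOfBoundsError) as exc:
                b = np.nan
                errors.append((x1, energy, str(exc)))
            rows.append({"configuration": scenario.name,
                         "slit_offset_mm": x1, "energy_MeV": float(energy),
                         "field_T": b})
    df = pd.DataFrame(rows, columns=["configuration", "slit_offset_mm",
                                     "energy_MeV", "field_T"])
    df.attrs["errors"] = errors
    return df


@dataclass
class FieldAssignment:
    """Field strengths keyed by (slit off-axis distance, energy), with the
    spot-x correlation used at delivery time (the field follows the spot)."""

    region: str
    table: pd.DataFrame
    direction: str = "+y"

    def strength(self, slit_offset: float, energy: float) -> float:
        """Field magnitude for a slit/spot at |x| = slit_offset.

        Offsets beyond the outermost optimized slit are linearly
        extrapolated (the optimized field is linear in the offset to high
        accuracy); the on-axis field is zero.
        """
        off = abs(slit_offset)
        if off == 0.0:
            return 0.0
        sel = self.table[np.isclose(self.table["energy_MeV"], energy)]
        if sel.empty:
            raise DomainError(f"no field rows for energy {energy} MeV")
        sel = sel.sort_values("slit_offset_mm")
        offs = sel["slit_offset_mm"].to_numpy(float)
        vals = sel["field_T"].to_numpy(float)
        if np.any(np.isnan(vals)):
            raise DomainError("field table contains unsolved rows")
        if off <= offs[-1]:
            return float(np.interp(off, offs, vals))
        # linear extrapolation from the outermost pair
        slope = (vals[-1] - vals[-2]) / (offs[-1] - offs[-2])
        return float(vals[-1] + slope * (off - offs[-1]))
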