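"""Collimator, pencil-beam-scanning spot grid and the five named setups.

Coordinate frame: z runs along the beamline with z = 0 at the phantom
entrance; x is the scanning / bending direction; y is the slit-length
direction.  The deflecting field points along +y.  Slit tilts are stored in
radians internally; the tilt gradient is configured in degrees per mm of
off-axis distance, as quoted at the machine.

The five supported setups:

``config1``
    Reference: 15-slit multislit collimator, 4 mm center-to-center (ctc)
    distance, no magnetic field.
``config2`` / ``config2p``
    6 mm ctc collimator plus a 50 mm dipole directly after it; ``config2``
    uses the static multislit, ``config2p`` a dynamic (scanned) aperture.
``config3`` / ``config3p``
    6 mm ctc collimator with a uniform field inside the water phantom
    (MRI-like); static multislit and dynamic aperture respectively.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, replace, asdict

import numpy as np
from scipy.special import erf

from .errors import ConfigError

SCENARIO_NAMES = ("config1", "config2", "config2p", "config3", "config3p")


@dataclass(frozen=True)
class Collimator:
    """Multislit (or dynamic-aperture) collimator description.

    ``tilt_gradient`` is in degrees per mm of off-axis distance; slits
    diverge outward to follow the beam divergence, so the tilt of a slit at
    off-axis position x1 is ``tilt_gradient * |x1|`` pointing away from the
    axis.
    """

    n_slits: int = 15
    slit_width: float = 0.4
    slit_length: float = 45.0
    ctc: float = 4.0
    thickness: float = 65.0
    tilt_gradient: float = 0.025
    mode: str = "static-multislit"

    def __post_init__(self):
        if self.n_slits < 1 or self.n_slits % 2 == 0:
            raise ConfigError("n_slits must be odd (central slit on axis)")
        if not self.slit_width < self.ctc:
            raise ConfigError("slit_width must be smaller than ctc")
        if self.thickness <= 0:
            raise ConfigError("collimator thickness must be positive")
        if self.mode not in ("static-multislit", "dynamic-aperture"):
            raise ConfigError(f"unknown collimator mode {self.mode!r}")

    def tilt_at(self, x1: float) -> float:
        """Slit tilt (rad) at off-axis position x1 (mm), signed outward."""
        return math.radians(self.tilt_gradient * abs(x1)) * (
            0.0 if x1 == 0 else math.copysign(1.0, x1))

    def slit_positions(self):
        """Off-axis positions and tilts of all slits.

        Returns a list of ``(x1_mm, tilt_rad)`` ordered from the most
        negative slit to the most positive.  Positions are k*ctc for
        k = -(n-1)/2 ... +(n-1)/2; the central slit has zero tilt.
        """
        half = (self.n_slits - 1) // 2
        out = []
        for k in range(-half, half + 1):
            x1 = k * self.ctc
            out.append((x1, self.tilt_at(x1)))
        return out


def slit_positions(collimator: Collimator):
    """Functional wrapper over :meth:`Collimator.slit_positions`."""
    return collimator.slit_positions()


def slit_transmission_weights(spot_x: float, spot_sigma: float,
                              collimator: Collimator) -> np.ndarray:
    """Per-slit flux fractions for a pencil-beam spot centered at ``spot_x``.

    Static multislit mode: the weight of slit k is the integral of the
    spot's lateral Gaussian over that slit aperture (slit tilts are ignored
    at this stage; apertures are thin in x).  Dynamic-aperture mode: weight
    1 on the single aperture aligned with the spot (nearest slit position,
    within half a ctc), 0 elsewhere.
    """
    if spot_sigma <= 0:
        raise ConfigError("spot_sigma must be strictly positive")
    centers = np.array([x for x, _ in collimator.slit_positions()])
    if collimator.mode == "dynamic-aperture":
        w = np.zeros_like(centers)
        i = int(np.argmin(np.abs(centers - spot_x)))
        if abs(centers[i] - spot_x) <= collimator.ctc / 2.0:
            w[i] = 1.0
        return w
    a = (centers - collimator.slit_width / 2.0 - spot_x) / (math.sqrt(2) * spot_sigma)
    b = (centers + collimator.slit_width / 2.0 - spot_x) / (math.sqrt(2) * spot_sigma)
    return 0.5 * (erf(b) - erf(a))


@dataclass(frozen=True)
class SpotGrid:
    """Rectangular PBS spot grid.

    Horizontal spacing ``dx`` equals the collimator ctc; vertical spacing
    ``dy`` is 3 mm.  ``spot_sigma`` is the lateral Gaussian sigma of a
    pencil beam at the collimator plane.  Per-spot energies and weights are
    uniform unless overridden.
    """

    n_x: int = 31
    n_y: int = 17
    dx: float = 4.0
    dy: float = 3.0
    spot_sigma: float = 3.0
    energy: float | None = None
    weight: float = 1.0

    def __post_init__(self):
        if self.weight < 0:
            raise ConfigError("spot weights must be non-negative")

    def x_positions(self) -> np.ndarray:
        half = (self.n_x - 1) / 2.0
        return (np.arange(self.n_x) - half) * self.dx


@dataclass(frozen=True)
class Scenario:
    """One named beamline setup plus all geometry needed downstream.

    ``air_gap`` is the distance from the collimator rear surface to the
    phantom entrance.  ``dipole_thickness`` is set (50 mm) only when the
    field region is the dipole.  Phantom and scoring-voxel sizes follow the
    reference water-phantom geometry.
    """

    name: str
    collimator: Collimator
    air_gap: float = 70.0
    dipole_thickness: float | None = None
    field_region: str = "none"          # none | dipole | phantom
    phantom_size: tuple = (100.0, 100.0, 300.0)
    dose_voxels: tuple = (0.1, 2.0, 1.0)

    def __post_init__(self):
        if self.field_region not in ("none", "dipole", "phantom"):
            raise ConfigError(f"unknown field region {self.field_region!r}")
        if self.field_region == "dipole":
            if self.dipole_thickness is None or self.dipole_thickness <= 0:
                raise ConfigError("dipole field region requires a positive "
                                  "dipole_thickness")
            if self.dipole_thickness > self.air_gap:
                raise ConfigError("dipole does not fit in the air gap")

    def spot_grid(self, energy: float | None = None,
                  spot_sigma: float = 3.0) -> SpotGrid:
        """Default spot grid for this scenario (dx = collimator ctc)."""
        return SpotGrid(dx=self.collimator.ctc, spot_sigma=spot_sigma,
                        energy=energy)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["phantom_size"] = list(self.phantom_size)
        d["dose_voxels"] = list(self.dose_voxels)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "Scenario":
        d = dict(d)
        known = {"name", "collimator", "air_gap", "dipole_thickness",
                 "field_region", "phantom_size", "dose_voxels"}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown scenario keys: {sorted(unknown)}")
        coll = d.get("collimator")
        if isinstance(coll, dict):
            ck = {"n_slits", "slit_width", "slit_length", "ctc", "thickness",
                  "tilt_gradient", "mode"}
            unknown = set(coll) - ck
            if unknown:
                raise ConfigError(f"unknown collimator keys: {sorted(unknown)}")
            d["collimator"] = Collimator(**coll)
        for key in ("phantom_size", "dose_voxels"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


def make_scenario(name: str) -> Scenario:
    """Build one of the five named setups with its preset geometry."""
    if name not in SCENARIO_NAMES:
        raise ConfigError(
            f"unknown scenario {name!r}; valid names: {', '.join(SCENARIO_NAMES)}")
    if name == "config1":
        return Scenario(name=name, collimator=Collimator(ctc=4.0))
    mode = "dynamic-aperture" if name.endswith("p") else "static-multislit"
    coll = Collimator(ctc=6.0, mode=mode)
    if name.startswith("config2"):
        return Scenario(name=name, collimator=coll, dipole_thickness=50.0,
                        field_region="dipole")
    return Scenario(name=name, collimator=coll, field_region="phantom")


def reference_scenario(scenario: Scenario) -> Scenario:
    """The no-field reference whose Bragg-peak pattern a converging setup
    must reproduce (index-to-index slit correspondence, 4 mm ctc)."""
    ref = make_scenario("config1")
    return replace(ref, collimator=replace(
        ref.collimator, n_slits=scenario.collimator.n_slits))
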