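"""Synthetic fixtures with known analytic answers.

These generators build inputs whose metrics are known by construction:
cosine dose grids with exact PVDR, toy dose libraries with planted flat
weightings, and degenerate scenarios for edge testing.  They are used by
the test-suite and exposed through the ``fixtures`` CLI subcommand.
"""
from __future__ import annotations

from dataclasses import replace

import numpy as np

from .errors import ConfigError
from .dose import DoseGrid, GridSpec
from .geometry import Collimator, Scenario, make_scenario
from .sobp import DoseLibrary, SOBP_WINDOW


def cosine_minibeam_grid(ctc: float = 4.0, mean: float = 2.0,
                         amplitude: float = 1.0,
                         spec: GridSpec | None = None) -> DoseGrid:
    """Dose grid D(x) = mean + amplitude * cos(2 pi x / ctc), uniform in y
    and z.  PVDR = (mean + amplitude) / (mean - amplitude) by construction.
    """
    if not 0 <= amplitude < mean:
        raise ConfigError("need 0 <= amplitude < mean for positive dose")
    # default lattice has a voxel center exactly on the axis and on every
    # extremum of the cosine, so the constructed PVDR is exact
    spec = spec or GridSpec(phantom=(100.2, 100.0, 300.0), voxel=(0.2, 10.0, 2.0))
    grid = DoseGrid(values=np.zeros(spec.shape), voxel=spec.voxel,
                    phantom=spec.phantom)
    x = grid.x_coords()
    prof = mean + amplitude * np.cos(2.0 * np.pi * x / ctc)
    grid.values[:] = prof[:, None, None]
    return grid


def uniform_grid(dose: float = 1.0, spec: GridSpec | None = None) -> DoseGrid:
    """Spatially uniform dose grid (PVDR = 1 everywhere)."""
    spec = spec or GridSpec.coarse()
    return DoseGrid(values=np.full(spec.shape, float(dose)),
                    voxel=spec.voxel, phantom=spec.phantom)


def toy_two_layer_library(z_max: float = 100.0, dz: float = 0.5) -> DoseLibrary:
    """Two overlapping triangular 'Bragg' curves with a smooth analytic
    optimum over the window 40-60 mm; cheap enough for grid-search oracles.
    """
    z = np.arange(0.0, z_max + dz, dz)
    tri1 = np.clip(1.0 - np.abs(z - 45.0) / 20.0, 0.0, None)
    tri2 = np.clip(1.0 - np.abs(z - 60.0) / 20.0, 0.0, None)
    return DoseLibrary(z=z, energies=(1.0, 2.0), peak=np.stack([tri1, tri2]))


def planted_flat_library(seed: int = 0, n_layers: int = 5,
                         window=SOBP_WINDOW):
    """Library constructed so that known weights give an exactly flat SOBP.

    The first ``n_layers - 1`` curves are smooth random positive bumps; the
    last curve is defined as the residual that makes the planted weight
    vector yield a constant plateau over the window.  Returns
    ``(library, planted_weights)`` with weights normalized to the last
    layer.
    """
    rng = np.random.default_rng(seed)
    z = np.arange(0.0, 220.0, 0.5)
    lo, hi = window
    planted = np.sort(rng.uniform(0.1, 0.9, size=n_layers - 1))
    curves = []
    # narrow, well-separated bumps keep the layer curves far from
    # collinear, so the flat-plateau weighting is identifiable
    for i in range(n_layers - 1):
        center = lo + (hi - lo) * (i + 0.5) / n_layers
        width = rng.uniform(3.0, 4.5)
        curves.append(np.exp(-0.5 * ((z - center) / width) ** 2))
    stack = np.stack(curves)
    target = 2.0
    last = (target - planted @ stack)
    if np.any(last[(z >= lo) & (z <= hi)] <= 0):
        raise ConfigError("planted construction produced a negative curve")
    last = np.clip(last, 0.0, None)
    lib = DoseLibrary(z=z, energies=tuple(float(i + 1) for i in range(n_layers)),
                      peak=np.vstack([stack, last[None, :]]))
    weights = np.concatenate([planted, [1.0]])
    return lib, weights


def single_slit_scenario() -> Scenario:
    """Degenerate reference setup with a single on-axis slit."""
    base = make_scenario("config1")
    return replace(base, collimator=replace(base.collimator, n_slits=1))


def zero_tilt_scenario() -> Scenario:
    """Reference setup with no slit divergence (all tilts zero)."""
    base = make_scenario("config1")
    return replace(base, collimator=replace(base.collimator, tilt_gradient=0.0))


def make_fixtures(kind: str, seed: int = 0):
    """Dispatch used by the CLI: kind in {cosine, uniform, two-layer,
    planted-library, single-slit, zero-tilt}."""
    if kind == "cosine":
        return cosine_minibeam_grid()
    if kind == "uniform":
        return uniform_grid()
    if kind == "two-layer":
        return toy_two_layer_library()
    if kind == "planted-library":
        return planted_flat_library(seed=seed)
    if kind == "single-slit":
        return single_slit_scenario()
    if kind == "zero-tilt":
        return zero_tilt_scenario()
    raise ConfigError(f"unknown fixture kind {kind!r}")
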