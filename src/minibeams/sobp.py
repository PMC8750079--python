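"""Genetic-algorithm optimization of energy-layer weights for a flat SOBP.

The spread-out Bragg peak (SOBP) is a weighted sum of the central-minibeam
peak-dose depth curves of the individual energy layers,

    Dp(z) = sum_i w_i Dp_i(z),

and the fitness minimized by the GA is the maximum dose error within the
SOBP window,

    f = max(Dp) - min(Dp)  over the window,

reported also in relative form (f divided by the window mean, in percent).
Reported weights are normalized to the highest-energy (last) layer.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigError, DomainError
from .dose import bragg_depth_dose, compute_dose, DoseGrid
from .metrics import metrics_table
from .physics import RangeModel, DEFAULT_RANGE_MODEL

#: SOBP energy layers (MeV) and depth window (mm) of the clinical scenario.
SOBP_ENERGIES = (150.0, 154.0, 158.0, 162.0, 166.0)
SOBP_WINDOW = (157.0, 187.0)
#: Machine energy spread (sigma, MeV); shared with the dose engine.
from .dose import MACHINE_ENERGY_SPREAD_SIGMA_MEV as ENERGY_SPREAD_SIGMA_MEV


@dataclass
class DoseLibrary:
    """Per-energy central-minibeam peak (and optional valley) depth curves
    on a common z-grid."""

    z: np.ndarray
    energies: tuple
    peak: np.ndarray                 # (n_energies, n_z)
    valley: np.ndarray | None = None

    def __post_init__(self):
        if self.peak.shape != (len(self.energies), self.z.size):
            raise ConfigError("peak curves must be (n_energies, n_z)")
        if np.any(self.peak < 0):
            raise ConfigError("dose curves must be non-negative")


@dataclass
class SOBPPlan:
    """Optimized energy layers: weights normalized to the last layer."""

    energies: tuple
    weights: np.ndarray
    window: tuple = SOBP_WINDOW


@dataclass
class GAConfig:
    """GA hyperparameters; the seed is mandatory for reproducibility.

    Mutation acts on log-weights with a scale annealed geometrically to 1%
    of its initial value over the run.
    """

    rng_seed: int
    population_size: int = 60
    generations: int = 300
    crossover_rate: float = 0.9
    mutation_rate: float = 0.2
    mutation_scale: float = 0.1
    elite_count: int = 2
    tournament_size: int = 3

    def __post_init__(self):
        if self.population_size < 2:
            raise ConfigError("population_size must be at least 2")
        for r in (self.crossover_rate, self.mutation_rate):
            if not 0.0 <= r <= 1.0:
                raise ConfigError("rates must lie in [0, 1]")
        if self.rng_seed is None:
            raise ConfigError("rng_seed is mandatory")


def analytic_library(energies=SOBP_ENERGIES,
                     range_model: RangeModel | None = None,
                     energy_spread_sigma_mev: float = ENERGY_SPREAD_SIGMA_MEV,
                     z_max: float = 220.0, dz: float = 0.25) -> DoseLibrary:
    """Library of analytic Bragg depth-dose curves (no lateral transport)."""
    rm = range_model or DEFAULT_RANGE_MODEL
    z = np.arange(0.0, z_max + dz, dz)
    peak = np.stack([
        bragg_depth_dose(e, z, range_model=rm,
                         energy_spread_sigma_mev=energy_spread_sigma_mev)
        for e in energies])
    return DoseLibrary(z=z, energies=tuple(energies), peak=peak)


def engine_library(scenario, energies=SOBP_ENERGIES, field_tables=None,
                   grid: str = "coarse",
                   range_model: RangeModel | None = None,
                   energy_spread_sigma_mev: float = ENERGY_SPREAD_SIGMA_MEV,
                   **dose_kwargs) -> DoseLibrary:
    """Library built from beamlet-engine dose grids, one per energy layer.

    ``field_tables`` maps energy -> field table (or a single table covering
    all energies) for scenarios with a field region.
    """
    peaks, valleys, z = [], [], None
    for e in energies:
        ft = field_tables.get(e) if isinstance(field_tables, dict) else field_tables
        dg = compute_dose(scenario, energy=e, field_table=ft, grid=grid,
                          range_model=range_model,
                          energy_spread_sigma_mev=energy_spread_sigma_mev,
                          **dose_kwargs)
        t = metrics_table(dg)
        z = t["z_mm"].to_numpy()
        peaks.append(np.nan_to_num(t["peak_dose"].to_numpy()))
        valleys.append(np.nan_to_num(t["valley_dose"].to_numpy()))
    return DoseLibrary(z=z, energies=tuple(energies), peak=np.stack(peaks),
                       valley=np.stack(valleys))


def combined_peak_dose(weights, library: DoseLibrary) -> np.ndarray:
    """Weighted SOBP peak-dose curve Dp(z) = sum_i w_i Dp_i(z)."""
    w = np.asarray(weights, dtype=float)
    if w.size != len(library.energies):
        raise DomainError("one weight per energy layer is required")
    return w @ library.peak


def _window_mask(z: np.ndarray, window) -> np.ndarray:
    lo, hi = window
    m = (z >= lo) & (z <= hi)
    if not m.any():
        raise DomainError("SOBP window lies outside the z-grid")
    return m


def sobp_fitness(weights, library: DoseLibrary, window=SOBP_WINDOW,
                 relative: bool = False) -> float:
    """Maximum dose error over the SOBP window.

    Absolute form (default): max(Dp) - min(Dp) over the window.  Relative
    form: the same divided by the window mean, in percent.
    """
    dp = combined_peak_dose(weights, library)
    m = _window_mask(library.z, window)
    f = float(dp[m].max() - dp[m].min())
    if relative:
        mean = float(dp[m].mean())
        if mean == 0.0:
            raise DomainError("zero mean dose in the SOBP window")
        return 100.0 * f / mean
    return f


def ga_optimize(library: DoseLibrary, window=SOBP_WINDOW,
                ga_config: GAConfig | None = None,
                return_history: bool = False):
    """Tournament-selection GA with elitism over log-weight chromosomes.

    Returns the best :class:`SOBPPlan` (weights normalized to the last
    layer); with ``return_history`` also the best-so-far absolute fitness
    per generation (non-increasing by construction).
    """
    if len(library.energies) < 2:
        raise ConfigError("the library needs at least 2 energy layers")
    cfg = ga_config or GAConfig(rng_seed=0)
    rng = np.random.default_rng(cfg.rng_seed)
    n = len(library.energies)
    m = _window_mask(library.z, window)
    lib_w = library.peak[:, m]

    def fitness(logw):
        # evaluate in the reported parameterization (last layer weight 1);
        # the raw max-min error otherwise has a degenerate optimum at w -> 0
        w = np.exp(logw - logw[-1])
        dp = w @ lib_w
        return dp.max() - dp.min()

    pop = rng.uniform(-3.0, 0.5, size=(cfg.population_size, n))
    fit = np.array([fitness(c) for c in pop])
    history = []
    anneal = 0.01 ** (1.0 / max(cfg.generations, 1))
    scale = cfg.mutation_scale
    for _ in range(cfg.generations):
        order = np.argsort(fit)
        elites = pop[order[:cfg.elite_count]].copy()
        children = []
        while len(children) < cfg.population_size - cfg.elite_count:
            idx = rng.integers(0, cfg.population_size,
                               size=(2, cfg.tournament_size))
            pa = pop[idx[0][np.argmin(fit[idx[0]])]]
            pb = pop[idx[1][np.argmin(fit[idx[1]])]]
            if rng.random() < cfg.crossover_rate:
                u = rng.random(n)
                child = u * pa + (1.0 - u) * pb
            else:
                child = pa.copy()
            mask = rng.random(n) < cfg.mutation_rate
            child = child + mask * rng.normal(0.0, scale, size=n)
            children.append(child)
        pop = np.vstack([elites, children])
        fit = np.array([fitness(c) for c in pop])
        scale *= anneal
        history.append(float(fit.min()))
    best = np.exp(pop[np.argmin(fit)])
    weights = best / best[-1]
    plan = SOBPPlan(energies=library.energies, weights=weights, window=window)
    if return_history:
        return plan, np.array(history)
    return plan
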