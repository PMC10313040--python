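"""Population-level synthetic-data engine.

Simulates cohorts of cycling cells through repeated noisy interphases and
emulates the three experiment designs the analysis pipeline consumes:

* a synchronized-release timecourse (every cell starts at the same cycle age,
  sampled every 8 h from 0 to 88 h),
* an asynchronous control (initial ages uniform over each cell's first cycle),
* a time-lapse duration assay (n independent period draws, summarized as
  mean +/- SD).

Division is instantaneous re-initialization: when a cell's age exceeds its
current period, a fresh ``CycleParams`` is drawn for the next cycle.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import InvalidParameterError
from .interphase import (
    CycleParams,
    NoiseSpec,
    Phase,
    derive_cycle_params,
    dna_deterministic,
    phase_at,
    sample_cycle,
)

__all__ = [
    "SimulationConfig",
    "PopulationTimecourse",
    "DurationSample",
    "default_t_grid",
    "simulate_population",
    "emulate_synchronized_experiment",
    "emulate_asynchronous_experiment",
    "simulate_timelapse_durations",
]


def default_t_grid() -> np.ndarray:
    """The experiment's sampling grid: every 8 h from 0 to 88 h inclusive."""
    return np.arange(0.0, 89.0, 8.0)


@dataclass(frozen=True)
class SimulationConfig:
    """Full parameterization of one population simulation.

    Attributes
    ----------
    n_cells : int
        Cohort size (constant over time; no death or growth).
    t_grid : array of float
        Sampling times in hours, strictly increasing, starting at 0.
    noise : NoiseSpec
        Error-in-variables noise model for period and initial DNA.
    init_mode : str
        ``"synchronized"`` (all cells at the same initial age) or
        ``"asynchronous"`` (initial ages uniform on each cell's first period).
    base_dna0 : float
        Noise-free initial DNA content, a.u.
    fluorescence_scale : float
        Measured fluorescence per DNA unit (cosmetic; default maps
        dna0 = 1 to 50 a.u. so histograms resemble PI channel scales).
    seed : int
        Seed for the simulation's random stream.
    init_age_fraction : float
        Synchronized-mode starting age as a fraction of the first period
        (0 = start of G1; 0.5 = S entry, mimicking a thymidine block).
    measurement_cv : float
        Optional per-observation instrument noise, multiplicative CV.
    parent_corr : float
        Correlation between successive period deviations of the same lineage
        (normal family only; 0 = independent cycles).
    """

    n_cells: int = 1000
    t_grid: np.ndarray = field(default_factory=default_t_grid)
    noise: NoiseSpec = field(default_factory=NoiseSpec)
    init_mode: str = "synchronized"
    base_dna0: float = 1.0
    fluorescence_scale: float = 50.0
    seed: int = 0
    init_age_fraction: float = 0.0
    measurement_cv: float = 0.0
    parent_corr: float = 0.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "t_grid", np.asarray(self.t_grid, dtype=float))
        if self.n_cells < 1:
            raise InvalidParameterError(f"n_cells must be >= 1, got {self.n_cells}")
        if self.t_grid.ndim != 1 or len(self.t_grid) < 1:
            raise InvalidParameterError("t_grid must be a non-empty 1-D array")
        if self.t_grid[0] != 0.0:
            raise InvalidParameterError(f"t_grid must start at 0, got {self.t_grid[0]}")
        if len(self.t_grid) > 1 and not np.all(np.diff(self.t_grid) > 0):
            raise InvalidParameterError("t_grid must be strictly increasing")
        if self.init_mode not in ("synchronized", "asynchronous"):
            raise InvalidParameterError(
                f"init_mode must be 'synchronized' or 'asynchronous', got {self.init_mode!r}"
            )
        if not 0.0 <= self.init_age_fraction < 1.0:
            raise InvalidParameterError(
                f"init_age_fraction must lie in [0, 1), got {self.init_age_fraction}"
            )
        if self.measurement_cv < 0:
            raise InvalidParameterError(f"measurement_cv must be >= 0, got {self.measurement_cv}")
        if not -1.0 < self.parent_corr < 1.0:
            raise InvalidParameterError(f"parent_corr must lie in (-1, 1), got {self.parent_corr}")
        if not self.base_dna0 > 0:
            raise InvalidParameterError(f"base_dna0 must be positive, got {self.base_dna0}")
        if not self.fluorescence_scale > 0:
            raise InvalidParameterError(
                f"fluorescence_scale must be positive, got {self.fluorescence_scale}"
            )


@dataclass
class PopulationTimecourse:
    """Cells x timepoints fluorescence matrix with ground-truth labels.

    ``truth_phase`` and ``truth_cycle_index`` are ``None`` when the timecourse
    was read from a table lacking truth columns.
    """

    times: np.ndarray
    measurements: np.ndarray
    truth_phase: np.ndarray | None = None
    truth_cycle_index: np.ndarray | None = None
    config: SimulationConfig | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.measurements = np.asarray(self.measurements, dtype=float)
        if self.measurements.ndim != 2:
            raise InvalidParameterError("measurements must be a 2-D (cells x timepoints) matrix")
        if self.measurements.shape[1] != len(self.times):
            raise InvalidParameterError(
                f"measurements has {self.measurements.shape[1]} columns but "
                f"{len(self.times)} timepoints"
            )
        if np.any(self.measurements <= 0):
            raise InvalidParameterError("all measurements must be positive")
        for name, arr in (("truth_phase", self.truth_phase), ("truth_cycle_index", self.truth_cycle_index)):
            if arr is not None and np.asarray(arr).shape != self.measurements.shape:
                raise InvalidParameterError(f"{name} shape must match measurements")

    @property
    def n_cells(self) -> int:
        return self.measurements.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.measurements.shape[1]

    def column(self, j: int) -> np.ndarray:
        """All cells' measurements at timepoint index ``j``."""
        return self.measurements[:, j]


@dataclass(frozen=True)
class DurationSample:
    """Cycle-duration draws with their summary statistics."""

    durations: np.ndarray
    mean: float
    sd: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "durations", np.asarray(self.durations, dtype=float))


def _next_params(
    prev: CycleParams | None,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> CycleParams:
    """Draw the next cycle's parameters, optionally correlated with the last."""
    noise = config.noise
    if (
        prev is None
        or config.parent_corr == 0.0
        or noise.family_tau != "normal"
        or noise.sigma_tau == 0.0
    ):
        return sample_cycle(noise, config.base_dna0, rng)
    # AR(1) propagation of the period deviation keeps the stationary SD at sigma_tau.
    rho = config.parent_corr
    innovation_sd = noise.sigma_tau * np.sqrt(1.0 - rho * rho)
    tau = noise.mean_tau + rho * (prev.tau - noise.mean_tau) + rng.normal(0.0, innovation_sd)
    tau = max(tau, noise.tau_min)
    fresh = sample_cycle(replace(noise, sigma_tau=0.0), config.base_dna0, rng)
    return derive_cycle_params(tau, fresh.dna0)


def simulate_population(config: SimulationConfig) -> PopulationTimecourse:
    """Simulate a cohort of cycling cells sampled on ``config.t_grid``.

    Per cell: draw a noisy cycle; advance in absolute time; at each cycle wrap
    record a division and re-draw fresh parameters; the measured value at each
    grid time is ``fluorescence_scale`` times the deterministic DNA content at
    the cell's current age (plus optional per-observation instrument noise).
    """
    rng = np.random.default_rng(config.seed)
    t_grid = config.t_grid
    n_t = len(t_grid)
    measurements = np.empty((config.n_cells, n_t))
    truth_phase = np.empty((config.n_cells, n_t), dtype=object)
    truth_cycle = np.zeros((config.n_cells, n_t), dtype=int)

    for i in range(config.n_cells):
        params = _next_params(None, config, rng)
        if config.init_mode == "asynchronous":
            age0 = rng.uniform(0.0, params.tau)
        else:
            age0 = config.init_age_fraction * params.tau
        cycle_start = -age0  # absolute time at which the current cycle began
        cycle_index = 0
        for j, t in enumerate(t_grid):
            while t - cycle_start >= params.tau:
                cycle_start += params.tau
                cycle_index += 1
                params = _next_params(params, config, rng)
            age = t - cycle_start
            value = config.fluorescence_scale * dna_deterministic(age, params)
            if config.measurement_cv > 0:
                value *= 1.0 + config.measurement_cv * rng.normal()
                value = max(value, 1e-12)
            measurements[i, j] = value
            truth_phase[i, j] = phase_at(age, params.tau).value
            truth_cycle[i, j] = cycle_index

    return PopulationTimecourse(
        times=t_grid,
        measurements=measurements,
        truth_phase=truth_phase,
        truth_cycle_index=truth_cycle,
        config=config,
    )


def emulate_synchronized_experiment(
    noise: NoiseSpec, n_cells: int = 1000, seed: int = 0, **kwargs
) -> PopulationTimecourse:
    """Synchronized-release experiment: 0..88 h every 8 h, all cells at age 0."""
    config = SimulationConfig(
        n_cells=n_cells, noise=noise, init_mode="synchronized", seed=seed, **kwargs
    )
    return simulate_population(config)


def emulate_asynchronous_experiment(
    noise: NoiseSpec, n_cells: int = 1000, seed: int = 0, **kwargs
) -> PopulationTimecourse:
    """Asynchronous control: same grid, initial ages uniform over the period."""
    config = SimulationConfig(
        n_cells=n_cells, noise=noise, init_mode="asynchronous", seed=seed, **kwargs
    )
    return simulate_population(config)


def simulate_timelapse_durations(n: int, noise: NoiseSpec, seed: int = 0) -> DurationSample:
    """Draw ``n`` independent cycle durations and summarize mean and SD.

    Mirrors a time-lapse microscopy assay in which each tracked cell
    contributes one division-to-division interval.
    """
    if n < 1:
        raise InvalidParameterError(f"n must be >= 1, got {n}")
    rng = np.random.default_rng(seed)
    durations = np.array([sample_cycle(noise, 1.0, rng).tau for _ in range(n)])
    sd = float(durations.std(ddof=1)) if n > 1 else 0.0
    return DurationSample(durations=durations, mean=float(durations.mean()), sd=sd)
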