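"""Auto-similarity function (ASF) statistics.

The ASF between two timepoints of an evolving variable is the two-sample
Kuiper statistic between their empirical distributions::

    Sigma = max_x (F1(x) - F2(x))  +  max_x (F2(x) - F1(x))

with each maximum floored at 0.  It is 0 for indistinguishable distributions
(full asynchrony), 1 for fully separated ones (full synchrony), and is
invariant under strictly increasing transformations of the measurement scale,
which suits cyclic DNA-content data.

This module also provides the successive-pair ASF series and pairwise ASF
matrix of a population timecourse, initial-value normalization, logistic
decay-rate fitting, and grid-search inversion of the desynchronization curve
for the period-noise SD.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace as dc_replace

import numpy as np
from scipy.optimize import least_squares

from .errors import FitFailureError, InvalidInputError
from .population import PopulationTimecourse, SimulationConfig, simulate_population

__all__ = [
    "EmpiricalCDF",
    "ASFSeries",
    "LogisticFit",
    "SigmaTauEstimate",
    "ecdf",
    "kuiper_statistic",
    "asf_successive",
    "asf_matrix",
    "normalize_series",
    "fit_logistic_decay",
    "logistic_curve",
    "estimate_sigma_tau",
]


@dataclass(frozen=True)
class EmpiricalCDF:
    """Right-continuous empirical CDF as a step function.

    ``support`` holds the sorted distinct sample values; ``cum_frac[i]`` is
    the cumulative fraction of observations <= ``support[i]`` (ties accumulate
    mass at a single support point; the final value is exactly 1).
    """

    support: np.ndarray
    cum_frac: np.ndarray

    def __call__(self, x) -> np.ndarray:
        """Evaluate F(x) with at-or-below (<=) semantics."""
        idx = np.searchsorted(self.support, np.asarray(x, dtype=float), side="right")
        padded = np.concatenate([[0.0], self.cum_frac])
        return padded[idx]


def ecdf(sample) -> EmpiricalCDF:
    """Empirical CDF of a non-empty finite sample."""
    arr = np.asarray(sample, dtype=float).ravel()
    if arr.size == 0:
        raise InvalidInputError("sample must be non-empty")
    if not np.all(np.isfinite(arr)):
        raise InvalidInputError("sample must contain only finite values")
    support, counts = np.unique(arr, return_counts=True)
    return EmpiricalCDF(support=support, cum_frac=np.cumsum(counts) / arr.size)


def kuiper_statistic(x1, x2) -> float:
    """Two-sample Kuiper statistic in [0, 1].

    Both CDF differences are evaluated at every pooled sample point, which is
    sufficient for right-continuous step functions; each directional maximum
    is floored at 0 so that identical samples score exactly 0.
    """
    a = np.asarray(x1, dtype=float).ravel()
    b = np.asarray(x2, dtype=float).ravel()
    if a.size == 0 or b.size == 0:
        raise InvalidInputError("both samples must be non-empty")
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise InvalidInputError("samples must contain only finite values")
    pooled = np.union1d(a, b)
    f1 = np.searchsorted(np.sort(a), pooled, side="right") / a.size
    f2 = np.searchsorted(np.sort(b), pooled, side="right") / b.size
    d_plus = max(np.max(f1 - f2), 0.0)
    d_minus = max(np.max(f2 - f1), 0.0)
    return float(d_plus + d_minus)


@dataclass(frozen=True)
class ASFSeries:
    """Successive-pair ASF values over a timecourse.

    ``pair_labels[k] = (t_k, t_{k+1})``; ``times[k] = t_{k+1}``, the time at
    which the comparison becomes available, used as the fitting coordinate.
    """

    pair_labels: tuple
    values: np.ndarray
    normalized: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if len(self.pair_labels) != len(self.values):
            raise InvalidInputError("pair_labels and values must have equal length")
        if not self.normalized and (np.any(self.values < 0) or np.any(self.values > 1)):
            raise InvalidInputError("unnormalized ASF values must lie in [0, 1]")

    @property
    def times(self) -> np.ndarray:
        return np.array([pair[1] for pair in self.pair_labels], dtype=float)

    def __len__(self) -> int:
        return len(self.values)


def asf_successive(timecourse: PopulationTimecourse) -> ASFSeries:
    """ASF between each temporally successive pair of timepoint columns."""
    if timecourse.n_timepoints < 2:
        raise InvalidInputError("timecourse must have at least 2 timepoints")
    t = timecourse.times
    values = [
        kuiper_statistic(timecourse.column(j), timecourse.column(j + 1))
        for j in range(timecourse.n_timepoints - 1)
    ]
    labels = tuple((float(t[j]), float(t[j + 1])) for j in range(len(t) - 1))
    return ASFSeries(pair_labels=labels, values=np.array(values))


def asf_matrix(timecourse: PopulationTimecourse) -> np.ndarray:
    """Symmetric matrix of ASF values for every unordered timepoint pair."""
    if timecourse.n_timepoints < 2:
        raise InvalidInputError("timecourse must have at least 2 timepoints")
    n = timecourse.n_timepoints
    mat = np.zeros((n, n))
    for j in range(n):
        for k in range(j + 1, n):
            mat[j, k] = mat[k, j] = kuiper_statistic(timecourse.column(j), timecourse.column(k))
    return mat


def normalize_series(series: ASFSeries) -> ASFSeries:
    """Divide every value by the first value (first normalized value is 1)."""
    if series.values[0] == 0:
        raise InvalidInputError("cannot normalize a series whose first value is 0")
    return ASFSeries(
        pair_labels=series.pair_labels,
        values=series.values / series.values[0],
        normalized=True,
    )


def logistic_curve(t, upper: float, lower: float, rate: float, t_half: float):
    """Decaying logistic: ``lower + (upper - lower) / (1 + exp(rate*(t - t_half)))``."""
    t = np.asarray(t, dtype=float)
    return lower + (upper - lower) / (1.0 + np.exp(np.clip(rate * (t - t_half), -500, 500)))


@dataclass(frozen=True)
class LogisticFit:
    """Fitted logistic-decay parameters; ``rate`` summarizes desynchronization speed."""

    upper: float
    lower: float
    rate: float
    t_half: float
    rss: float

    def predict(self, t):
        return logistic_curve(t, self.upper, self.lower, self.rate, self.t_half)


def fit_logistic_decay(series: ASFSeries) -> LogisticFit:
    """Multi-start least-squares fit of a decaying logistic to an ASF series.

    Values are fitted against each pair's second time.  Starts combine
    data-driven heuristics (upper from the first value, lower from the last,
    t_half from the mid-range crossing) with a small grid of rates.  Bounds
    keep ``lower >= 0`` and, for unnormalized series, ``upper <= 1``.

    Raises
    ------
    FitFailureError
        If no start converges; carries the best attempt in ``best``.
    """
    if len(series) < 4:
        raise InvalidInputError("need at least 4 pairs to fit 4 parameters")
    t = series.times
    y = series.values
    upper_cap = 1.0 if not series.normalized else max(2.0, float(y.max()) * 1.05)
    upper0 = float(y[0])
    lower0 = float(y[-1])
    mid = (upper0 + lower0) / 2.0
    crossing = t[np.argmin(np.abs(y - mid))]
    t_half_starts = {float(crossing), float(np.median(t)), float(t[-1])}

    def residuals(p):
        return logistic_curve(t, *p) - y

    span = t[-1] - t[0]
    lo_bounds = [0.0, 0.0, 0.0, t[0] - span]
    hi_bounds = [upper_cap, upper_cap, 10.0, t[-1] + span]
    candidates: list[LogisticFit] = []
    for rate0 in (0.01, 0.05, 0.15, 0.5):
        for th0 in t_half_starts:
            p0 = np.clip(
                [max(upper0, 1e-6), max(lower0, 0.0), rate0, th0],
                lo_bounds,
                hi_bounds,
            )
            try:
                res = least_squares(residuals, p0, bounds=(lo_bounds, hi_bounds))
            except Exception:
                continue
            rss = float(np.sum(res.fun**2))
            upper, lower, rate, t_half = (float(v) for v in res.x)
            if lower > upper:  # canonical orientation: decay from upper to lower
                upper, lower = lower, upper
            candidates.append(
                LogisticFit(upper=upper, lower=lower, rate=rate, t_half=t_half, rss=rss)
            )
    if not candidates:
        raise FitFailureError("logistic fit failed from every start", best=None)
    # Parsimony tie-break among near-equivalent local optima: the 4-parameter
    # logistic degenerates into step functions on weakly decaying series, so
    # among fits within 20% relative RSS of the best (statistically
    # indistinguishable at this series length), prefer the least steep.
    best_rss = min(c.rss for c in candidates)
    admissible = [c for c in candidates if c.rss <= best_rss * 1.20 + 1e-12]
    return min(admissible, key=lambda c: c.rate)


@dataclass(frozen=True)
class SigmaTauEstimate:
    """Grid-search estimate of the period-noise SD with its discrepancy profile."""

    sigma_hat: float
    grid: np.ndarray
    discrepancy: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "grid", np.asarray(self.grid, dtype=float))
        object.__setattr__(self, "discrepancy", np.asarray(self.discrepancy, dtype=float))


def estimate_sigma_tau(
    observed: ASFSeries,
    grid,
    reps: int,
    base: SimulationConfig,
) -> SigmaTauEstimate:
    """Infer the period-noise SD from an observed desynchronization curve.

    For each candidate sigma, ``reps`` synchronized simulations (seeds derived
    from ``base.seed``) are run, their normalized successive-pair ASF series
    averaged, and the sum of squared differences to the normalized observed
    series computed; the arg-min candidate is returned with the full profile.
    Normalizing both sides makes the estimator insensitive to the absolute
    initial ASF value.
    """
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise InvalidInputError("candidate grid must be non-empty")
    if reps < 1:
        raise InvalidInputError("reps must be >= 1")
    obs_norm = observed if observed.normalized else normalize_series(observed)
    obs_times = obs_norm.times

    discrepancy = np.empty(grid.size)
    seed_seq = np.random.SeedSequence(base.seed)
    child_seeds = seed_seq.generate_state(grid.size * reps, dtype=np.uint32).reshape(
        grid.size, reps
    )
    for gi, sigma in enumerate(grid):
        acc = np.zeros(len(obs_norm))
        for ri in range(reps):
            config = dc_replace(
                base,
                noise=dc_replace(base.noise, sigma_tau=float(sigma)),
                init_mode="synchronized",
                seed=int(child_seeds[gi, ri]),
            )
            sim = simulate_population(config)
            if not np.array_equal(sim.times, np.concatenate([[base.t_grid[0]], obs_times])):
                raise InvalidInputError("observed series and simulation time grids differ")
            acc += normalize_series(asf_successive(sim)).values
        acc /= reps
        discrepancy[gi] = float(np.sum((acc - obs_norm.values) ** 2))
    return SigmaTauEstimate(
        sigma_hat=float(grid[int(np.argmin(discrepancy))]),
        grid=grid,
        discrepancy=discrepancy,
    )
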