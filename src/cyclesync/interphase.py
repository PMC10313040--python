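"""Single-cell interphase DNA-content model.

A cell's DNA content over one interphase is modeled as a logistic rise from
``dna0`` (G1 content) toward ``dna_max = 2 * dna0`` (G2 content)::

    dna(t) = dna0 * (1 + 1 / (1 + exp(-beta * (t - s)))),   0 <= t <= tau

The synthesis steepness ``beta`` and midpoint ``s`` are tied to the cycle
period ``tau`` so that the S phase occupies the middle third of the cycle:
``beta = 24 / (3 * tau)`` and ``s = 2 * tau / 3``.

Population heterogeneity enters as error-in-variables noise: per cycle, the
period and the initial DNA content each receive an additive draw from a
configurable family (normal or Poisson), truncated to stay physical.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidParameterError, OutOfDomainError, ResamplingCapError

__all__ = [
    "CycleParams",
    "NoiseSpec",
    "Phase",
    "derive_cycle_params",
    "dna_deterministic",
    "sample_cycle",
    "phase_at",
    "phase_fraction_of_period",
]

#: Retry cap for truncated-noise rejection sampling.
MAX_RESAMPLES = 1000

#: Poisson rate used for the relative initial-DNA noise mode (dna0 * P / lam).
POISSON_DNA_RATE = 100.0


class Phase(str, enum.Enum):
    """Interphase stage label."""

    G1 = "G1"
    S = "S"
    G2 = "G2"


@dataclass(frozen=True)
class CycleParams:
    """One realized cell cycle.

    Attributes
    ----------
    dna0 : float
        Initial (G1) DNA content, arbitrary units.
    dna_max : float
        Post-synthesis DNA content; equals ``2 * dna0`` by construction.
    beta : float
        Synthesis steepness, 1/h.
    s : float
        Synthesis midpoint time, h.
    tau : float
        Cycle period, h.
    """

    dna0: float
    dna_max: float
    beta: float
    s: float
    tau: float

    def __post_init__(self) -> None:
        if not (self.dna0 > 0 and math.isfinite(self.dna0)):
            raise InvalidParameterError(f"dna0 must be positive and finite, got {self.dna0}")
        if not (self.tau > 0 and math.isfinite(self.tau)):
            raise InvalidParameterError(f"tau must be positive and finite, got {self.tau}")
        if not self.beta > 0:
            raise InvalidParameterError(f"beta must be positive, got {self.beta}")
        if not 0 < self.s < self.tau:
            raise InvalidParameterError(f"s must lie in (0, tau), got s={self.s}, tau={self.tau}")
        if not math.isclose(self.dna_max, 2.0 * self.dna0, rel_tol=1e-9):
            raise InvalidParameterError(
                f"dna_max must equal 2*dna0, got dna_max={self.dna_max}, dna0={self.dna0}"
            )


@dataclass(frozen=True)
class NoiseSpec:
    """Population noise model for the error-in-variables parameters.

    Attributes
    ----------
    mean_tau : float
        Population mean cycle period, h.
    sigma_tau : float
        Period standard deviation, h (normal family only; the Poisson family
        has variance fixed at ``mean_tau``).
    sigma_dna0 : float
        Initial-DNA standard deviation, a.u.
    family_tau, family_dna : str
        Distribution family for each noise term, ``"normal"`` or ``"poisson"``.
    tau_min : float
        Minimum admissible period, h; normal draws below it are rejected.
    """

    mean_tau: float = 24.0
    sigma_tau: float = 3.0
    sigma_dna0: float = 0.05
    family_tau: str = "normal"
    family_dna: str = "normal"
    tau_min: float = 4.0

    def __post_init__(self) -> None:
        if not self.mean_tau > 0:
            raise InvalidParameterError(f"mean_tau must be positive, got {self.mean_tau}")
        if self.sigma_tau < 0:
            raise InvalidParameterError(f"sigma_tau must be >= 0, got {self.sigma_tau}")
        if self.sigma_dna0 < 0:
            raise InvalidParameterError(f"sigma_dna0 must be >= 0, got {self.sigma_dna0}")
        if not 0 < self.tau_min < self.mean_tau:
            raise InvalidParameterError(
                f"tau_min must lie in (0, mean_tau), got tau_min={self.tau_min}, "
                f"mean_tau={self.mean_tau}"
            )
        for name, fam in (("family_tau", self.family_tau), ("family_dna", self.family_dna)):
            if fam not in ("normal", "poisson"):
                raise InvalidParameterError(f"{name} must be 'normal' or 'poisson', got {fam!r}")


def derive_cycle_params(tau: float, dna0: float) -> CycleParams:
    """Build the full parameter set for one cycle from period and initial DNA.

    ``beta = 24 / (3 * tau)``, ``s = 2 * tau / 3``, ``dna_max = 2 * dna0``,
    which centers an 8 h S phase at s = 16 h for the default 24 h period.

    Raises
    ------
    InvalidParameterError
        If ``tau`` or ``dna0`` is not strictly positive.
    """
    if not (tau > 0 and math.isfinite(tau)):
        raise InvalidParameterError(f"tau must be positive and finite, got {tau}")
    if not (dna0 > 0 and math.isfinite(dna0)):
        raise InvalidParameterError(f"dna0 must be positive and finite, got {dna0}")
    return CycleParams(
        dna0=dna0,
        dna_max=2.0 * dna0,
        beta=24.0 / (3.0 * tau),
        s=2.0 * tau / 3.0,
        tau=tau,
    )


def dna_deterministic(t, params: CycleParams):
    """Noise-free DNA content at cycle age ``t`` (scalar or array), a.u.

    Monotone non-decreasing on ``[0, tau]``; equals ``1.5 * dna0`` exactly at
    ``t = s`` and approaches (but never reaches) ``dna_max`` at ``t = tau``.

    Raises
    ------
    OutOfDomainError
        If any ``t`` falls outside ``[0, tau]``.  Cycle wrapping is the
        population simulator's job, not this function's.
    """
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0) or np.any(t_arr > params.tau):
        raise OutOfDomainError(f"t must lie in [0, {params.tau}], got {t}")
    value = params.dna0 * (1.0 + 1.0 / (1.0 + np.exp(-params.beta * (t_arr - params.s))))
    return value if isinstance(value, np.ndarray) and value.ndim else float(value)


def _draw_tau(noise: NoiseSpec, rng: np.random.Generator) -> float:
    """Draw one effective period, rejection-truncated at ``tau_min``."""
    for _ in range(MAX_RESAMPLES):
        if noise.family_tau == "normal":
            tau = noise.mean_tau + rng.normal(0.0, noise.sigma_tau) if noise.sigma_tau > 0 else noise.mean_tau
        else:
            # Poisson-distributed periods: integer hours, variance = mean_tau.
            tau = float(rng.poisson(noise.mean_tau))
        if tau >= noise.tau_min:
            return tau
    raise ResamplingCapError(
        f"period draw failed to exceed tau_min={noise.tau_min} after {MAX_RESAMPLES} tries"
    )


def _draw_dna0(noise: NoiseSpec, base_dna0: float, rng: np.random.Generator) -> float:
    """Draw one effective initial DNA content, truncated strictly positive."""
    for _ in range(MAX_RESAMPLES):
        if noise.family_dna == "normal":
            dna0 = base_dna0 + rng.normal(0.0, noise.sigma_dna0) if noise.sigma_dna0 > 0 else base_dna0
        else:
            # Mean-preserving relative Poisson noise: dna0 * P/lam, P ~ Poisson(lam).
            dna0 = base_dna0 * rng.poisson(POISSON_DNA_RATE) / POISSON_DNA_RATE
        if dna0 > 0:
            return dna0
    raise ResamplingCapError(
        f"initial-DNA draw failed to stay positive after {MAX_RESAMPLES} tries"
    )


def sample_cycle(noise: NoiseSpec, base_dna0: float, rng: np.random.Generator) -> CycleParams:
    """Draw one noisy cycle realization.

    The effective period is ``mean_tau`` plus a draw from the configured
    family (resampled until >= ``tau_min``); the effective initial DNA is
    ``base_dna0`` plus its own draw (resampled until positive).  With both
    sigmas zero and normal families this is deterministic and equal to
    ``derive_cycle_params(mean_tau, base_dna0)``.
    """
    return derive_cycle_params(_draw_tau(noise, rng), _draw_dna0(noise, base_dna0, rng))


def phase_at(t: float, tau: float) -> Phase:
    """Phase label at cycle age ``t`` for period ``tau``.

    Half-open boundary convention: G1 on ``[0, tau/2)``, S on
    ``[tau/2, 5*tau/6)``, G2 on ``[5*tau/6, tau)`` — S is the length-``tau/3``
    interval centered on the synthesis midpoint ``s = 2*tau/3``.
    """
    if not tau > 0:
        raise InvalidParameterError(f"tau must be positive, got {tau}")
    if not 0 <= t < tau:
        raise OutOfDomainError(f"t must lie in [0, {tau}), got {t}")
    if t < tau / 2.0:
        return Phase.G1
    if t < 5.0 * tau / 6.0:
        return Phase.S
    return Phase.G2


def phase_fraction_of_period(phase: Phase) -> float:
    """Fraction of the period spent in ``phase`` under the boundary convention."""
    return {Phase.G1: 0.5, Phase.S: 1.0 / 3.0, Phase.G2: 1.0 / 6.0}[phase]
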