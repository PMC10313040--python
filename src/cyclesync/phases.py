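"""DNA-content histograms and G1/S/G2 phase deconvolution.

The classifier fits a three-component model to a DNA-content histogram:
Gaussian G1 and G2 peaks (the G2 mean constrained near twice the G1 mean)
plus a broadened S component — a constant-height rectangle spanning the two
peak means, convolved with a Gaussian whose width interpolates between the
peak widths.  Component areas, normalized to 100%, give the phase fractions.

This is a transparent stand-in for the classic flow-cytometry univariate
model; the original's polynomial S-phase height is simplified to a single
constant so every parameter is identifiable on synthetic data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .errors import FitFailureError, InvalidInputError
from .interphase import Phase
from .population import PopulationTimecourse

__all__ = [
    "DNAHistogram",
    "PhaseFractions",
    "DJFResult",
    "build_histogram",
    "djf_fit",
    "phase_fraction_timecourse",
    "truth_fractions",
    "phase_residuals",
]

_SQRT_2PI = np.sqrt(2.0 * np.pi)


@dataclass(frozen=True)
class DNAHistogram:
    """Uniform-width event histogram of fluorescence values."""

    bin_edges: np.ndarray
    counts: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "bin_edges", np.asarray(self.bin_edges, dtype=float))
        object.__setattr__(self, "counts", np.asarray(self.counts, dtype=float))
        if len(self.counts) != len(self.bin_edges) - 1:
            raise InvalidInputError("len(counts) must equal len(bin_edges) - 1")
        if np.any(self.counts < 0):
            raise InvalidInputError("counts must be non-negative")
        if self.counts.sum() <= 0:
            raise InvalidInputError("histogram must contain at least one event")
        if not np.all(np.diff(self.bin_edges) > 0):
            raise InvalidInputError("bin_edges must be strictly ascending")

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def bin_width(self) -> float:
        return float(self.bin_edges[1] - self.bin_edges[0])

    @property
    def total(self) -> float:
        return float(self.counts.sum())


@dataclass(frozen=True)
class PhaseFractions:
    """Percentage of a population in each interphase stage (sums to 100)."""

    pct_g1: float
    pct_s: float
    pct_g2: float

    def __post_init__(self) -> None:
        for name in ("pct_g1", "pct_s", "pct_g2"):
            v = getattr(self, name)
            if not -1e-9 <= v <= 100 + 1e-9:
                raise InvalidInputError(f"{name} must lie in [0, 100], got {v}")
        total = self.pct_g1 + self.pct_s + self.pct_g2
        if abs(total - 100.0) > 0.1:
            raise InvalidInputError(f"fractions must sum to 100 within 0.1, got {total}")

    def as_array(self) -> np.ndarray:
        return np.array([self.pct_g1, self.pct_s, self.pct_g2])


@dataclass(frozen=True)
class DJFResult:
    """Phase fractions plus the fitted component parameters and diagnostics."""

    fractions: PhaseFractions
    mu_g1: float
    sigma_g1: float
    mu_g2: float
    sigma_g2: float
    area_g1: float
    area_s: float
    area_g2: float
    unclassified_frac: float
    rss: float


def build_histogram(sample, n_bins: int = 256, range_: tuple | None = None) -> DNAHistogram:
    """Bin events uniformly; events outside ``range_`` are clipped to the edge bins."""
    arr = np.asarray(sample, dtype=float).ravel()
    if arr.size == 0:
        raise InvalidInputError("sample must be non-empty")
    if not np.all(np.isfinite(arr)):
        raise InvalidInputError("sample must contain only finite values")
    if n_bins < 8:
        raise InvalidInputError(f"n_bins must be >= 8, got {n_bins}")
    if range_ is None:
        lo, hi = float(arr.min()), float(arr.max())
        if lo == hi:  # degenerate sample: widen symmetrically
            lo, hi = lo - 0.5, hi + 0.5
    else:
        lo, hi = float(range_[0]), float(range_[1])
        if not hi > lo:
            raise InvalidInputError(f"range upper bound must exceed lower, got {range_}")
    edges = np.linspace(lo, hi, n_bins + 1)
    # clip so out-of-range events land in the first/last bin instead of vanishing
    half_bin = (hi - lo) / n_bins / 2.0
    clipped = np.clip(arr, lo + half_bin * 1e-9, hi - half_bin * 1e-9)
    counts, _ = np.histogram(clipped, bins=edges)
    return DNAHistogram(bin_edges=edges, counts=counts)


def _gauss(x: np.ndarray, mu: float, sigma: float) -> np.ndarray:
    z = (x - mu) / sigma
    return np.exp(-0.5 * z * z) / (sigma * _SQRT_2PI)


def _s_density(x: np.ndarray, mu1: float, mu2: float, sig1: float, sig2: float,
               n_sub: int = 24) -> np.ndarray:
    """Unit-height rectangle on [mu1, mu2] convolved with a width-interpolating
    Gaussian; integrates to (mu2 - mu1)."""
    du = (mu2 - mu1) / n_sub
    u = mu1 + (np.arange(n_sub) + 0.5) * du
    sig = sig1 + (sig2 - sig1) * (u - mu1) / (mu2 - mu1)
    z = (x[:, None] - u[None, :]) / sig[None, :]
    return (np.exp(-0.5 * z * z) / (sig[None, :] * _SQRT_2PI)).sum(axis=1) * du


def _mode_estimate(hist: DNAHistogram) -> float:
    return float(hist.centers[int(np.argmax(hist.counts))])


def djf_fit(hist: DNAHistogram) -> DJFResult:
    """Deconvolve a DNA histogram into G1/S/G2 fractions.

    Least-squares fit of per-bin expected counts::

        model(x) = [a1*N(x; mu1, s1) + a2*N(x; mu2, s2) + h*S(x)] * bin_width

    with ``mu2`` constrained to ``[1.8*mu1, 2.2*mu1]`` and ``S`` the broadened
    rectangle from :func:`_s_density`.  The G1 mean is initialized at the
    histogram's global mode (and, as a fallback start, at half the mode in
    case the mode is the G2 peak); three (sigma1, sigma2) initializations are
    tried per mean start and the lowest-RSS solution wins.

    Events below ``0.5 * mu1`` are reported as an unclassified fraction and
    excluded from the 100% normalization.
    """
    x = hist.centers
    y = hist.counts
    bw = hist.bin_width
    total = hist.total
    mode = _mode_estimate(hist)
    span = float(hist.bin_edges[-1] - hist.bin_edges[0])

    def model(p: np.ndarray) -> np.ndarray:
        a1, a2, h, mu1, sig1, ratio, sig2 = p
        mu2 = ratio * mu1
        out = a1 * _gauss(x, mu1, sig1) + a2 * _gauss(x, mu2, sig2)
        if mu2 > mu1:
            out = out + h * _s_density(x, mu1, mu2, sig1, sig2)
        return out * bw

    def residuals(p: np.ndarray) -> np.ndarray:
        return model(p) - y

    lo = hist.bin_edges[0]
    mu1_starts = [mode]
    if mode / 2.0 > lo + 2 * bw:
        mu1_starts.append(mode / 2.0)
    sigma_starts = [0.02, 0.05, 0.10]  # as a fraction of mu1

    best_res = None
    best_p = None
    for mu1_0 in mu1_starts:
        for frac in sigma_starts:
            sig0 = max(frac * mu1_0, bw)
            p0 = np.array([0.5 * total, 0.2 * total, 0.3 * total / max(mu1_0, bw),
                           mu1_0, sig0, 2.0, 2.0 * sig0])
            bounds_lo = [0.0, 0.0, 0.0, lo + bw, bw / 2.0, 1.8, bw / 2.0]
            bounds_hi = [2 * total, 2 * total, 10 * total / bw, hist.bin_edges[-1],
                         span / 3.0, 2.2, span / 3.0]
            p0 = np.clip(p0, bounds_lo, bounds_hi)
            try:
                res = least_squares(residuals, p0, bounds=(bounds_lo, bounds_hi))
            except Exception:
                continue
            rss = float(np.sum(res.fun**2))
            if best_res is None or rss < best_res:
                best_res, best_p = rss, res.x
    if best_p is None:
        raise FitFailureError("phase deconvolution failed from every start", best=None)

    a1, a2, h, mu1, sig1, ratio, sig2 = best_p
    mu2 = ratio * mu1
    area_s = h * max(mu2 - mu1, 0.0)
    areas = np.array([a1, area_s, a2])
    if areas.sum() <= 0:
        raise FitFailureError("phase deconvolution produced zero total area", best=best_p)
    pct = 100.0 * areas / areas.sum()
    unclassified = float(y[x < 0.5 * mu1].sum() / total)
    return DJFResult(
        fractions=PhaseFractions(pct_g1=float(pct[0]), pct_s=float(pct[1]), pct_g2=float(pct[2])),
        mu_g1=float(mu1), sigma_g1=float(sig1),
        mu_g2=float(mu2), sigma_g2=float(sig2),
        area_g1=float(a1), area_s=float(area_s), area_g2=float(a2),
        unclassified_frac=unclassified,
        rss=float(best_res),
    )


def truth_fractions(timecourse: PopulationTimecourse) -> pd.DataFrame | None:
    """Ground-truth phase percentages per timepoint from simulation labels."""
    if timecourse.truth_phase is None:
        return None
    rows = []
    for j, t in enumerate(timecourse.times):
        labels = timecourse.truth_phase[:, j]
        n = len(labels)
        rows.append({
            "time_h": float(t),
            "pct_g1": 100.0 * np.sum(labels == Phase.G1.value) / n,
            "pct_s": 100.0 * np.sum(labels == Phase.S.value) / n,
            "pct_g2": 100.0 * np.sum(labels == Phase.G2.value) / n,
        })
    return pd.DataFrame(rows)


def phase_fraction_timecourse(
    timecourse: PopulationTimecourse, n_bins: int = 256
) -> pd.DataFrame:
    """Fit the phase deconvolution at every timepoint.

    Returns a frame with columns ``time_h, pct_g1, pct_s, pct_g2, fit_ok``
    plus ``truth_pct_*`` columns when the timecourse carries simulation
    labels.  Per-timepoint fit failures are flagged (``fit_ok = False``, NaN
    fractions), not fatal.
    """
    # shared range across timepoints so fractions are comparable
    mode = _mode_estimate(build_histogram(timecourse.measurements[:, 0].ravel(), n_bins=64))
    g1_peak = min(mode, float(np.median(timecourse.measurements)))
    hist_range = (0.0, 1.2 * 2.0 * g1_peak)
    rows = []
    for j, t in enumerate(timecourse.times):
        row = {"time_h": float(t)}
        try:
            result = djf_fit(build_histogram(timecourse.column(j), n_bins=n_bins, range_=hist_range))
            row.update(
                pct_g1=result.fractions.pct_g1,
                pct_s=result.fractions.pct_s,
                pct_g2=result.fractions.pct_g2,
                fit_ok=True,
            )
        except FitFailureError:
            row.update(pct_g1=np.nan, pct_s=np.nan, pct_g2=np.nan, fit_ok=False)
        rows.append(row)
    out = pd.DataFrame(rows)
    truth = truth_fractions(timecourse)
    if truth is not None:
        out = out.merge(
            truth.rename(columns={
                "pct_g1": "truth_pct_g1", "pct_s": "truth_pct_s", "pct_g2": "truth_pct_g2",
            }),
            on="time_h",
        )
    return out


def phase_residuals(series: pd.DataFrame, reference: pd.DataFrame) -> pd.DataFrame:
    """Per-timepoint, per-phase difference (percentage points): series - reference."""
    if len(series) != len(reference):
        raise InvalidInputError(
            f"series has {len(series)} timepoints but reference has {len(reference)}"
        )
    cols = ["pct_g1", "pct_s", "pct_g2"]
    for frame, name in ((series, "series"), (reference, "reference")):
        missing = [c for c in cols if c not in frame.columns]
        if missing:
            raise InvalidInputError(f"{name} is missing columns {missing}")
    out = pd.DataFrame({"time_h": series["time_h"].to_numpy()})
    for c in cols:
        out[c.replace("pct", "resid")] = series[c].to_numpy() - reference[c].to_numpy()
    return out
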