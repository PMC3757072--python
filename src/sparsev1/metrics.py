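"""Derived response statistics and population tables.

These are the measurements the virtual electrophysiology protocols feed:
the F1 (first-harmonic) amplitude of a rate trace over a drift cycle, the
surround suppression index (SI) and its contrast dependence, the receptive
field expansion ratio, surround facilitation ratio, orientation-tuning
half-width (1.17 sigma of a circular Gaussian fit) and its slope against
contrast, cross-orientation suppression ratio, and the population-level
correlation between suppression and CRF size.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

__all__ = [
    "TuningCurve",
    "f1",
    "suppression_index",
    "delta_si",
    "expansion_ratio",
    "facilitation_ratio",
    "orientation_halfwidth",
    "halfwidth_slope",
    "cross_orientation_ratio",
    "si_crf_size_correlation",
    "normalize_for_scatter",
]

HALFWIDTH_FACTOR = 1.17  # half-width at half-height = 1.17 * sigma


@dataclass
class TuningCurve:
    """Ordered abscissa with one response per point.

    ``statistic`` records how each response was measured: ``mean`` rate,
    ``f1`` amplitude, or ``steady_state`` rate.
    """

    abscissa_name: str
    abscissa: np.ndarray
    responses: np.ndarray
    statistic: str = "mean"
    condition: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.abscissa = np.asarray(self.abscissa, dtype=float)
        self.responses = np.asarray(self.responses, dtype=float)
        if self.abscissa.shape != self.responses.shape:
            raise ValueError("abscissa and responses must have equal length")

    @property
    def peak_abscissa(self) -> float:
        return float(self.abscissa[int(np.argmax(self.responses))])

    @property
    def peak_response(self) -> float:
        return float(np.max(self.responses))


def f1(rate_series: np.ndarray, cycle_steps: int) -> float:
    """Amplitude of the first harmonic of a rate trace over the drift cycle.

    ``2/N * |sum_t r(t) exp(-i 2 pi t / cycle_steps)|`` averaged over all
    complete cycles; the series length must be a multiple of ``cycle_steps``.
    """
    r = np.asarray(rate_series, dtype=float)
    n = r.size
    if cycle_steps < 1 or n % cycle_steps != 0:
        raise ValueError(
            f"series length {n} is not a multiple of cycle_steps {cycle_steps}"
        )
    t = np.arange(n)
    coeff = np.sum(r * np.exp(-2j * np.pi * t / cycle_steps))
    return float(2.0 / n * np.abs(coeff))


def suppression_index(curve: TuningCurve) -> float:
    """Surround suppression index (peak - min-beyond-peak) / peak in [0, 1].

    The minimum is taken over sizes strictly larger than the peak size; a
    monotone non-decreasing curve scores 0, complete suppression scores 1.
    Raises on an all-zero curve (undefined; caller flags the unit).
    """
    r = curve.responses
    if r.size == 0:
        raise ValueError("empty tuning curve")
    peak_idx = int(np.argmax(r))
    peak = r[peak_idx]
    if peak <= 0:
        raise ValueError("suppression index undefined for an unresponsive curve")
    if peak_idx == r.size - 1:
        return 0.0
    r_min = float(np.min(r[peak_idx + 1 :]))
    return float(np.clip((peak - r_min) / peak, 0.0, 1.0))


def delta_si(si_low: float, si_high: float) -> float:
    """SI difference between low and high contrast (contrast invariance -> ~0)."""
    return si_low - si_high


def expansion_ratio(peak_size_low: float, peak_size_high: float) -> float:
    """Peak size at low contrast over peak size at high contrast.

    Values > 1 indicate receptive field expansion at low contrast (points
    above the diagonal in the low-vs-high scatter).
    """
    if peak_size_high <= 0:
        raise ValueError("peak size at high contrast must be positive")
    return peak_size_low / peak_size_high


def facilitation_ratio(surround_curve: TuningCurve, center_only_optimum: float) -> float:
    """Max of the surround orientation tuning over the center-alone optimum."""
    if center_only_optimum <= 0:
        raise ValueError("facilitation ratio undefined for a zero center response")
    return float(np.max(surround_curve.responses)) / center_only_optimum


def _circular_gaussian(theta, baseline, amplitude, mu, sigma):
    # wrapped distance on the 180-degree orientation domain
    d = np.abs(theta - mu)
    d = np.minimum(d, 180.0 - d)
    return baseline + amplitude * np.exp(-0.5 * (d / sigma) ** 2)


def fit_orientation_gaussian(curve: TuningCurve):
    """Least-squares circular Gaussian fit (baseline, amplitude, mu, sigma)."""
    theta = curve.abscissa
    r = curve.responses
    if np.ptp(r) <= 0:
        raise RuntimeError("flat orientation tuning curve: no dominant peak")
    mu0 = theta[int(np.argmax(r))]
    p0 = [float(r.min()), float(np.ptp(r)), float(mu0), 20.0]
    popt, _ = optimize.curve_fit(
        _circular_gaussian,
        theta,
        r,
        p0=p0,
        bounds=([-np.inf, 0.0, -180.0, 0.5], [np.inf, np.inf, 360.0, 90.0]),
        maxfev=20000,
    )
    return popt


def orientation_halfwidth(curve: TuningCurve) -> float:
    """Half-width at half-height: 1.17 * sigma of the circular Gaussian fit.

    Raises RuntimeError when the fit fails (flat or non-Gaussian curves);
    callers record an exclusion flag rather than a value.
    """
    baseline, amplitude, mu, sigma = fit_orientation_gaussian(curve)
    if amplitude <= 0 or sigma <= 0:
        raise RuntimeError("degenerate orientation tuning fit")
    if sigma >= 85.0:
        # sigma pinned at the bound: the curve is essentially flat on the
        # 180-degree domain, i.e. there is no orientation tuning to measure
        raise RuntimeError("orientation tuning fit pinned at the sigma bound")
    return HALFWIDTH_FACTOR * float(sigma)


def halfwidth_slope(halfwidths, contrasts) -> float:
    """Least-squares slope of half-width against contrast normalized to 100.

    The contrast axis is rescaled so its maximum is 100; the slope is in
    degrees per unit normalized contrast (0 for contrast-invariant tuning).
    """
    hw = np.asarray(halfwidths, dtype=float)
    c = np.asarray(contrasts, dtype=float)
    if hw.shape != c.shape or hw.size < 2:
        raise ValueError("need >= 2 matched half-width/contrast pairs")
    c_norm = c * 100.0 / c.max()
    slope, _ = np.polyfit(c_norm, hw, 1)
    return float(slope)


def cross_orientation_ratio(test_response: float, plaid_response: float) -> float:
    """Plaid over test-alone response (1 = no suppression, < 1 = suppression)."""
    if test_response <= 0:
        raise ValueError("cross-orientation ratio undefined for zero test response")
    return plaid_response / test_response


def si_crf_size_correlation(table) -> tuple[float, float]:
    """Pearson correlation (r, two-sided p) between high-contrast SI and CRF
    size across the population table."""
    si = np.asarray(table["si_high"], dtype=float)
    size = np.asarray(table["crf_size"], dtype=float)
    ok = np.isfinite(si) & np.isfinite(size)
    si, size = si[ok], size[ok]
    if si.size < 3:
        raise ValueError("need >= 3 units for a correlation")
    if np.ptp(si) == 0 or np.ptp(size) == 0:
        raise ValueError("correlation undefined for a constant column")
    r, p = stats.pearsonr(si, size)
    return float(r), float(p)


def normalize_for_scatter(responses, mode: str = "max") -> np.ndarray:
    """Normalize a population response group so its maximum is 1."""
    r = np.asarray(responses, dtype=float)
    if mode != "max":
        raise ValueError(f"unknown normalization mode {mode!r}")
    m = np.nanmax(r)
    if not np.isfinite(m) or m <= 0:
        raise ValueError("normalization undefined for an all-zero group")
    return r / m
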