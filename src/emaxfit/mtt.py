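"""In-silico MTT viability assays and apparent-IC50 extraction.

The endpoint viability readout of an MTT plate is modelled as the ratio
of treated to untreated cell counts at the measurement day (assuming
formazan absorbance proportional to viable cell number).  Because both
counts evolve in time, the concentration at which this readout crosses
50% — the *apparent* IC50 — drifts with the measurement day, unlike the
model-level IC50 of the Emax efficacy.  This module simulates the plates
and extracts the apparent IC50 so the drift can be quantified.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq, curve_fit

from .model import DrugEffect, GrowthParameters, efficacy, effective_rate, logistic_solution

__all__ = [
    "MTTSeries",
    "IC50Estimate",
    "ApparentIC50Curve",
    "FormulationComparison",
    "simulate_mtt",
    "apparent_ic50",
    "ic50_vs_time",
    "compare_formulations",
]

#: Twofold dilution grid inferred from the printed assay endpoints
#: (0.00625 * 2**8 == 1.6 ug/mL).
MTT_DOSE_GRID = tuple(0.00625 * 2.0**i for i in range(9))
MTT_DAYS = (2.0, 4.0, 6.0, 8.0)


@dataclass
class MTTSeries:
    """Viability fraction versus dose at one measurement day."""

    measurement_day: float
    doses: np.ndarray
    viability: np.ndarray
    replicate_viability: np.ndarray | None = None  # shape (n_doses, n_reps)
    warnings: list[str] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "day": self.measurement_day,
                "dose_ug_ml": self.doses,
                "viability": self.viability,
            }
        )


@dataclass(frozen=True)
class IC50Estimate:
    """Apparent IC50 read off one viability series.

    ``value`` is NaN when the series never crosses 50% viability
    (``reached`` is False); ``method`` tags how the value was obtained.
    """

    value: float
    reached: bool
    method: str

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        v = f"{self.value:.4g}" if self.reached else "not reached"
        return f"IC50Estimate({v}, method={self.method!r})"


@dataclass
class ApparentIC50Curve:
    """Apparent IC50 as a function of measurement day."""

    days: np.ndarray
    estimates: list[IC50Estimate]

    def values(self) -> np.ndarray:
        return np.array([e.value for e in self.estimates])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "day": self.days,
                "ic50_ug_ml": self.values(),
                "reached": [e.reached for e in self.estimates],
                "method": [e.method for e in self.estimates],
            }
        )


def simulate_mtt(
    params: GrowthParameters,
    effect: DrugEffect,
    doses: Sequence[float] = MTT_DOSE_GRID,
    day: float = 2.0,
) -> MTTSeries:
    """Noise-free viability series at ``day``: treated / control count.

    Viability at dose 0 is exactly 1.  ``day=0`` degenerates to all-ones
    and is returned with a warning rather than raised.
    """
    doses = np.asarray(list(doses), dtype=float)
    if np.any(doses < 0):
        raise ValueError("doses must be >= 0")
    series_warnings: list[str] = []
    if day == 0:
        series_warnings.append("day=0: all viabilities are 1 by construction")
    eps = efficacy(doses, effect)
    control = logistic_solution(day, params)
    treated = np.array(
        [logistic_solution(day, params, rate=effective_rate(params, e)) for e in eps]
    )
    viability = treated / control
    viability[doses == 0] = 1.0
    if viability.min() > 0.55 and day > 0:
        series_warnings.append(
            "dose span does not bracket 50% viability at this day"
        )
    return MTTSeries(
        measurement_day=float(day),
        doses=doses,
        viability=viability,
        warnings=series_warnings,
    )


def _pava_decreasing(y: np.ndarray) -> np.ndarray:
    """Pool-adjacent-violators fit of a non-increasing sequence."""
    y = np.asarray(y, float)
    # fit non-decreasing on the reversed sequence
    z = y[::-1]
    merged: list[list[float]] = []
    for val in z:
        merged.append([float(val), 1.0])
        while len(merged) > 1 and merged[-2][0] > merged[-1][0]:
            v2, w2 = merged.pop()
            v1, w1 = merged.pop()
            merged.append([(v1 * w1 + v2 * w2) / (w1 + w2), w1 + w2])
    out = np.concatenate([[v] * int(wt) for v, wt in merged])
    return out[::-1]


def _loglinear_crossing(doses: np.ndarray, viability: np.ndarray) -> float | None:
    """Log-dose linear interpolation of the 0.5 crossing; None if absent."""
    logd = np.log10(doses)
    for i in range(len(doses)):
        if viability[i] == 0.5:
            return float(doses[i])
        if i > 0 and viability[i - 1] > 0.5 > viability[i]:
            v1, v2 = viability[i - 1], viability[i]
            frac = (0.5 - v1) / (v2 - v1)
            return float(10 ** (logd[i - 1] + frac * (logd[i] - logd[i - 1])))
    return None


def _fourpl(logd, top, bottom, loghalf, slope):
    return bottom + (top - bottom) / (1.0 + 10 ** (slope * (logd - loghalf)))


def apparent_ic50(series: MTTSeries, method: str = "loglinear") -> IC50Estimate:
    """Concentration at which the viability series crosses 50%.

    The default extraction interpolates linearly in log dose between the
    doses bracketing the crossing.  A non-monotone series (beyond 2%
    tolerance) is first smoothed by monotone regression, recorded in the
    method tag.  ``method="logistic4"`` instead fits a four-parameter
    logistic and solves it for 50%.
    """
    mask = series.doses > 0
    doses = series.doses[mask]
    viability = series.viability[mask]
    if len(doses) < 3:
        raise ValueError(f"need >= 3 positive doses, got {len(doses)}")
    order = np.argsort(doses)
    doses, viability = doses[order], viability[order]

    tag = method
    if method == "loglinear":
        if np.any(np.diff(viability) > 0.02):
            viability = _pava_decreasing(viability)
            tag = "loglinear+monotone-smoothed"
        if viability.min() > 0.5:
            return IC50Estimate(math.nan, False, tag)
        if viability[0] < 0.5:
            # already below 50% at the smallest tested dose
            return IC50Estimate(float(doses[0]), True, tag + "+left-censored")
        value = _loglinear_crossing(doses, viability)
        if value is None:
            return IC50Estimate(math.nan, False, tag)
        return IC50Estimate(value, True, tag)

    if method == "logistic4":
        logd = np.log10(doses)
        p0 = (float(viability.max()), float(viability.min()), float(np.median(logd)), 1.0)
        try:
            popt, _ = curve_fit(_fourpl, logd, viability, p0=p0, maxfev=10000)
        except RuntimeError:
            return IC50Estimate(math.nan, False, "logistic4+fit-failed")
        top, bottom, loghalf, slope = popt
        if not (min(top, bottom) < 0.5 < max(top, bottom)):
            return IC50Estimate(math.nan, False, tag)
        # invert the 4PL at viability 0.5
        ratio = (top - bottom) / (0.5 - bottom) - 1.0
        if ratio <= 0 or slope == 0:
            return IC50Estimate(math.nan, False, tag)
        value = float(10 ** (loghalf + np.log10(ratio) / slope))
        return IC50Estimate(value, True, tag)

    raise ValueError(f"unknown extraction method {method!r}")


def ic50_vs_time(
    params: GrowthParameters,
    effect: DrugEffect,
    doses: Sequence[float] = MTT_DOSE_GRID,
    days: Sequence[float] = MTT_DAYS,
    method: str = "loglinear",
) -> ApparentIC50Curve:
    """Apparent IC50 at each measurement day; unreached days propagate as NaN."""
    days = np.asarray(list(days), dtype=float)
    if np.any(np.diff(days) <= 0):
        raise ValueError("days must be strictly increasing")
    estimates = [
        apparent_ic50(simulate_mtt(params, effect, doses, day), method=method)
        for day in days
    ]
    return ApparentIC50Curve(days=days, estimates=estimates)


@dataclass
class FormulationComparison:
    """Per-day apparent IC50s of two formulations plus model-level ratios."""

    table: pd.DataFrame  # day, ic50_a, ic50_b, ratio_a_over_b
    model_ic50_ratio: float
    model_emax_ratio: float


def compare_formulations(
    effect_a: DrugEffect,
    effect_b: DrugEffect,
    params: GrowthParameters,
    doses: Sequence[float] = MTT_DOSE_GRID,
    days: Sequence[float] = MTT_DAYS,
    method: str = "loglinear",
) -> FormulationComparison:
    """Compare two fitted drug effects on one cell line.

    Reports the apparent IC50 of each formulation per measurement day,
    their per-day ratio (A over B), and the model-level IC50 and Emax
    ratios of the two effects.
    """
    curve_a = ic50_vs_time(params, effect_a, doses, days, method)
    curve_b = ic50_vs_time(params, effect_b, doses, days, method)
    va, vb = curve_a.values(), curve_b.values()
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = va / vb
    table = pd.DataFrame(
        {
            "day": curve_a.days,
            "ic50_a": va,
            "ic50_b": vb,
            "ratio_a_over_b": ratio,
        }
    )
    return FormulationComparison(
        table=table,
        model_ic50_ratio=effect_a.IC50 / effect_b.IC50,
        model_emax_ratio=effect_b.Emax / effect_a.Emax,
    )


def ic50_bisection(
    params: GrowthParameters,
    effect: DrugEffect,
    day: float,
    lo: float,
    hi: float,
) -> float | None:
    """Root of ``viability(D) = 0.5`` on ``[lo, hi]`` from the closed form.

    Independent of the grid-based extraction; returns None when the
    bracket does not contain a crossing.
    """

    def f(D):
        eps = efficacy(D, effect)
        r = effective_rate(params, eps)
        return logistic_solution(day, params, rate=r) / logistic_solution(day, params) - 0.5

    if f(lo) * f(hi) > 0:
        return None
    return float(brentq(f, lo, hi, xtol=1e-12, rtol=1e-12))
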