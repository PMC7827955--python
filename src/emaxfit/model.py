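"""Forward model of drugged cell growth.

Cells grow logistically, ``dN/dt = r N (1 - N/K)``, where the effective
rate ``r = lambda * (1 - eps)`` is the drug-free growth rate scaled down
by the efficacy ``eps`` of the applied drug.  Efficacy follows the Emax
model, ``eps = Emax * D / (D + IC50)``, so it is zero without drug and
saturates at ``Emax`` for large concentrations ``D``.

Because the efficacy is constant in time for a fixed concentration, the
logistic equation is solved in closed form; no numerical integration is
performed here (an ODE integrator is used only as an independent oracle
in the test suite).

Units: concentrations in ug/mL, time in days, counts in cells/well.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.special import expit

__all__ = [
    "DEFAULT_EMAX_UPPER",
    "GrowthParameters",
    "DrugEffect",
    "DoseSchedule",
    "efficacy",
    "effective_rate",
    "logistic_solution",
    "simulate_growth_curves",
]

#: Default upper bound for Emax.  Values above 1 put the net growth rate
#: below zero (net cell death), which is observed at the highest tested
#: concentrations, so the bound is deliberately larger than 1.
DEFAULT_EMAX_UPPER = 2.0


@dataclass(frozen=True)
class GrowthParameters:
    """Drug-free growth kinetics of one cell line.

    Parameters
    ----------
    lambda_ : float
        Exponential growth rate, per day.  Must be positive.
    K : float
        Carrying capacity of the well, cells/well.  Must be positive.
    N0 : float
        Cell count at time zero (the plating density), cells/well.
        Must be positive.
    """

    lambda_: float
    K: float
    N0: float

    def __post_init__(self) -> None:
        for name in ("lambda_", "K", "N0"):
            value = getattr(self, name)
            if not np.isfinite(value) or value <= 0:
                raise ValueError(f"{name} must be finite and > 0, got {value!r}")


@dataclass(frozen=True)
class DrugEffect:
    """Emax-model efficacy parameters of one drug formulation.

    Parameters
    ----------
    Emax : float
        Maximum fractional reduction of the growth rate at saturating
        concentration.  Constrained to ``[0, emax_upper]``; values above
        1 correspond to net cell death.
    IC50 : float
        Concentration producing half the maximum effect, ug/mL.
    emax_upper : float, optional
        Upper bound enforced on ``Emax`` (default 2).
    """

    Emax: float
    IC50: float
    emax_upper: float = DEFAULT_EMAX_UPPER

    def __post_init__(self) -> None:
        if not np.isfinite(self.Emax) or not 0.0 <= self.Emax <= self.emax_upper:
            raise ValueError(
                f"Emax must lie in [0, {self.emax_upper}], got {self.Emax!r}"
            )
        if not np.isfinite(self.IC50) or self.IC50 <= 0:
            raise ValueError(f"IC50 must be finite and > 0, got {self.IC50!r}")


@dataclass(frozen=True)
class DoseSchedule:
    """Ordered set of tested concentrations for one formulation arm."""

    doses: tuple[float, ...]
    label: str = ""

    def __post_init__(self) -> None:
        doses = tuple(float(d) for d in self.doses)
        if any(d < 0 for d in doses):
            raise ValueError(f"doses must be >= 0, got {doses}")
        if list(doses) != sorted(set(doses)):
            raise ValueError(
                f"doses must be sorted ascending without duplicates, got {doses}"
            )
        object.__setattr__(self, "doses", doses)


def efficacy(D, effect: DrugEffect):
    """Fractional growth-rate reduction at concentration ``D``.

    Implements ``eps = Emax * D / (D + IC50)``.  Accepts scalars or
    arrays; negative concentrations raise ``ValueError``.
    """
    D = np.asarray(D, dtype=float)
    if np.any(D < 0):
        bad = float(np.min(D))
        raise ValueError(f"concentration must be >= 0, got {bad}")
    eps = effect.Emax * D / (D + effect.IC50)
    return float(eps) if eps.ndim == 0 else eps


def effective_rate(params: GrowthParameters, eps):
    """Growth rate under drug: ``lambda * (1 - eps)``.

    Negative when ``eps > 1`` (net death regime), which is permitted.
    """
    eps = np.asarray(eps, dtype=float)
    r = params.lambda_ * (1.0 - eps)
    return float(r) if r.ndim == 0 else r


def logistic_solution(t, params: GrowthParameters, rate: float | None = None):
    """Closed-form logistic trajectory ``N(t)`` at effective rate ``rate``.

    Evaluates ``N(t) = K N0 e^{rt} / (K + N0 (e^{rt} - 1))`` in a form
    that cannot overflow for large ``|r t|``.  ``rate`` defaults to the
    drug-free rate ``params.lambda_``.

    Parameters
    ----------
    t : float or array
        Time(s) in days, must be >= 0.
    params : GrowthParameters
    rate : float, optional
        Effective growth rate per day; may be negative (decay to 0).
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError(f"time must be >= 0, got {float(np.min(t))}")
    r = params.lambda_ if rate is None else float(rate)
    N = _logistic(t, r, params.K, params.N0)
    return float(N) if N.ndim == 0 else N


def _logistic(t, r, K, N0):
    """Vectorized stable logistic closed form (no parameter validation)."""
    t = np.asarray(t, dtype=float)
    x = r * t
    if N0 == K:
        return np.full_like(t, float(K))
    if N0 < K:
        # N = K / (1 + c e^{-x}) with c = K/N0 - 1 > 0, i.e. K * expit(x - log c)
        return K * expit(x - np.log(K / N0 - 1.0))
    # Above carrying capacity: decay toward K (finite for r >= 0).
    c = K / N0 - 1.0  # in (-1, 0)
    return K / (1.0 + c * np.exp(-np.clip(x, -700.0, 700.0)))


def simulate_growth_curves(
    params: GrowthParameters,
    effect: DrugEffect,
    schedule: DoseSchedule,
    times: Sequence[float],
):
    """Noise-free growth trajectories for every dose in ``schedule``.

    Returns a :class:`~emaxfit.data.GrowthDataset` with one replicate per
    (dose, day).  Dose 0, if present, reproduces the drug-free control.
    """
    from .data import GrowthDataset, records_frame  # local import: avoid cycle

    times = np.asarray(list(times), dtype=float)
    if times.size == 0 or len(schedule.doses) == 0:
        raise ValueError("times and doses must be non-empty")
    if np.any(times < 0) or np.any(np.diff(times) < 0):
        raise ValueError("times must be nonnegative and ascending")

    rows = []
    for dose in schedule.doses:
        eps = efficacy(dose, effect)
        r = effective_rate(params, eps)
        counts = _logistic(times, r, params.K, params.N0)
        for day, count in zip(times, np.atleast_1d(counts)):
            rows.append(("", schedule.label, dose, float(day), 0, float(count)))
    records = records_frame(rows)
    return GrowthDataset(records=records, plating_density=params.N0)
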