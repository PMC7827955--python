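"""Synthetic growth-curve and viability datasets.

Generators compose the forward model with a configurable noise layer so
the full fitting pipeline is testable without external data.  Named
presets mirror the two experimental designs the analysis assumes:

* ``paper-growth`` — counts every other day from day 2 to 14 at doses
  {0, 5e-5, 5e-4, 5e-3, 5e-2} ug/mL, 3 replicate wells, 1000 cells/well.
* ``paper-mtt`` — a 9-point twofold dilution series from 0.00625 to
  1.6 ug/mL read at days 2, 4, 6 and 8, 5000 cells/well, 3 replicates.
  (The twofold structure is inferred from the endpoints:
  0.00625 * 2**8 == 1.6.)

Default noise is multiplicative lognormal with sigma 0.1 (proportional
counting error); Poisson count noise and additive Gaussian noise are
also available.
"""

from __future__ import annotations

from dataclasses import dataclass
import numpy as np

from .data import GrowthDataset, records_frame
from .model import DrugEffect, GrowthParameters, efficacy, effective_rate
from .model import _logistic
from .mtt import MTTSeries, simulate_mtt

__all__ = [
    "NoiseModel",
    "DesignTemplate",
    "GROWTH_PRESETS",
    "MTT_PRESETS",
    "design_preset",
    "generate_growth_dataset",
    "generate_mtt_dataset",
]

NOISE_KINDS = ("multiplicative-lognormal", "additive-gaussian", "poisson-count")


@dataclass(frozen=True)
class NoiseModel:
    """Observation-noise specification for synthetic datasets."""

    kind: str = "multiplicative-lognormal"
    sigma: float = 0.1
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.kind not in NOISE_KINDS:
            raise ValueError(f"kind must be one of {NOISE_KINDS}, got {self.kind!r}")
        if self.sigma < 0:
            raise ValueError(f"sigma must be >= 0, got {self.sigma}")


@dataclass(frozen=True)
class DesignTemplate:
    """Plate design: what is measured, when, and how often."""

    plating_density: float
    days: tuple[float, ...]
    doses: tuple[float, ...]
    replicates: int = 3
    cell_line: str = "MCF-7"
    condition: str = "drug"

    def __post_init__(self) -> None:
        if self.plating_density <= 0:
            raise ValueError("plating_density must be > 0")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")


GROWTH_PRESETS = {
    "paper-growth": DesignTemplate(
        plating_density=1000.0,
        days=tuple(float(d) for d in range(2, 15, 2)),
        doses=(0.0, 5e-5, 5e-4, 5e-3, 5e-2),
        replicates=3,
    ),
}

MTT_PRESETS = {
    "paper-mtt": DesignTemplate(
        plating_density=5000.0,
        days=(2.0, 4.0, 6.0, 8.0),
        doses=tuple(0.00625 * 2.0**i for i in range(9)),
        replicates=3,
    ),
}


def design_preset(name: str) -> DesignTemplate:
    """Look up a named design; raises with the list of known presets."""
    presets = {**GROWTH_PRESETS, **MTT_PRESETS}
    try:
        return presets[name]
    except KeyError:
        raise KeyError(
            f"unknown preset {name!r}; available: {sorted(presets)}"
        ) from None


def _apply_noise(mean: np.ndarray, noise: NoiseModel, rng: np.random.Generator):
    """Perturb noise-free values; integer-rounds counts only when noisy."""
    if noise.kind == "poisson-count":
        return rng.poisson(mean).astype(float)
    if noise.sigma == 0:
        return mean.copy()
    if noise.kind == "multiplicative-lognormal":
        out = mean * np.exp(noise.sigma * rng.standard_normal(mean.shape))
    else:  # additive-gaussian, sigma in count units
        out = mean + noise.sigma * rng.standard_normal(mean.shape)
    return np.maximum(np.rint(out), 0.0)


def generate_growth_dataset(
    params: GrowthParameters,
    effect: DrugEffect,
    template: DesignTemplate,
    noise: NoiseModel | None = None,
    seed: int | None = None,
) -> GrowthDataset:
    """Replicated noisy counts from the forward model under ``template``.

    The generating truth is recorded in ``dataset.truth`` for recovery
    tests.  Deterministic given ``seed`` (which overrides ``noise.seed``).
    """
    noise = noise or NoiseModel()
    if seed is None:
        seed = noise.seed
    rng = np.random.default_rng(seed)
    days = np.asarray(template.days, float)
    rows = []
    for dose in template.doses:
        eps = efficacy(dose, effect)
        r = effective_rate(params, eps)
        mean = _logistic(days, r, params.K, params.N0)
        for rep in range(template.replicates):
            counts = _apply_noise(mean, noise, rng)
            condition = "control" if dose == 0 else template.condition
            for day, count in zip(days, counts):
                rows.append(
                    (template.cell_line, condition, float(dose), float(day), rep, float(count))
                )
    truth = {
        "lambda": params.lambda_,
        "K": params.K,
        "N0": params.N0,
        "Emax": effect.Emax,
        "IC50": effect.IC50,
        "noise_kind": noise.kind,
        "sigma": noise.sigma,
        "seed": seed,
    }
    ds = GrowthDataset(
        records=records_frame(rows),
        plating_density=template.plating_density,
        truth=truth,
    )
    ds.validate()
    return ds


def generate_mtt_dataset(
    params: GrowthParameters,
    effect: DrugEffect,
    template: DesignTemplate,
    noise: NoiseModel | None = None,
    seed: int | None = None,
) -> list[MTTSeries]:
    """One noisy MTT viability series per measurement day in ``template``.

    With ``sigma=0`` the stored viabilities equal the noise-free
    simulation exactly; otherwise multiplicative Gaussian scatter is
    applied per replicate well and the per-dose mean is stored.
    """
    noise = noise or NoiseModel()
    if seed is None:
        seed = noise.seed
    rng = np.random.default_rng(seed)
    out = []
    for day in template.days:
        series = simulate_mtt(params, effect, template.doses, day)
        if noise.sigma == 0 and noise.kind != "poisson-count":
            out.append(series)
            continue
        reps = np.empty((len(series.doses), template.replicates))
        for j in range(template.replicates):
            factor = np.exp(noise.sigma * rng.standard_normal(len(series.doses)))
            reps[:, j] = np.maximum(series.viability * factor, 0.0)
        series.replicate_viability = reps
        series.viability = reps.mean(axis=1)
        out.append(series)
    return out
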