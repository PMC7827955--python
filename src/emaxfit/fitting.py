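"""Two-step estimation of growth and efficacy parameters.

Step one fits the drug-free control curves for the growth rate ``lambda``
and carrying capacity ``K``.  Step two holds those fixed and fits a
single ``(Emax, IC50)`` pair jointly to all treated curves of one
formulation.  Both steps minimize the sum of squared residuals (SSR)
with Nelder-Mead; confidence intervals come from percentile bootstrap
(1000 replicates by default).

Optimization runs in a transformed space — ``log lambda``, ``log K``,
``log IC50`` and a logit scaling of ``Emax / emax_upper`` — so the
simplex search is unconstrained while the natural-scale parameters stay
inside their bounds.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import minimize
from scipy.special import expit, logit

from .data import GrowthDataset
from .model import DEFAULT_EMAX_UPPER, DrugEffect, GrowthParameters

__all__ = [
    "DegenerateDataError",
    "FitConfig",
    "FitResult",
    "ssr",
    "fit_control",
    "fit_treated",
    "two_step_fit",
    "bootstrap_ci",
]


class DegenerateDataError(ValueError):
    """Raised when a dataset cannot identify any model parameter."""


@dataclass
class FitConfig:
    """Settings shared by both fitting steps.

    ``xtol``/``ftol`` are Nelder-Mead simplex and function tolerances
    (applied in the transformed space, so effectively relative),
    ``simplex_scale`` sets the initial simplex as a fractional
    perturbation of the starting point.
    """

    emax_upper: float = DEFAULT_EMAX_UPPER
    estimate_n0: bool = False
    max_day: float | None = None
    xtol: float = 1e-8
    ftol: float = 1e-8
    maxiter: int = 5000
    simplex_scale: float = 0.05
    n_boot: int = 1000
    bootstrap_scheme: str = "auto"  # "case" | "residual" | "auto"
    seed: int | None = None


@dataclass
class FitResult:
    """Point estimates with optimizer diagnostics and optional bootstrap CIs.

    ``params`` holds the fitted parameters by name (insertion order
    defines the column order of ``bootstrap_samples``); ``fixed`` holds
    parameters that were held constant during the fit (e.g. the control
    estimates during the treated fit).
    """

    params: dict[str, float]
    ssr: float
    converged: bool
    n_iterations: int
    fixed: dict[str, float] = field(default_factory=dict)
    bootstrap_samples: np.ndarray | None = None
    ci_lower: dict[str, float] | None = None
    ci_upper: dict[str, float] | None = None
    seed: int | None = None
    boundary_hit: bool = False
    unreliable: bool = False
    warnings: list[str] = field(default_factory=list)

    @property
    def param_names(self) -> tuple[str, ...]:
        return tuple(self.params)

    def growth_parameters(self) -> GrowthParameters:
        p = {**self.fixed, **self.params}
        return GrowthParameters(lambda_=p["lambda"], K=p["K"], N0=p["N0"])

    def drug_effect(self, emax_upper: float = DEFAULT_EMAX_UPPER) -> DrugEffect:
        p = {**self.fixed, **self.params}
        return DrugEffect(Emax=p["Emax"], IC50=p["IC50"], emax_upper=emax_upper)

    def predict(self, dataset: GrowthDataset) -> np.ndarray:
        """Model counts aligned with ``dataset.records`` rows."""
        p = {**self.fixed, **self.params}
        dose = dataset.records["dose_ug_ml"].to_numpy(float)
        day = dataset.records["day"].to_numpy(float)
        if "Emax" in p:
            eps = p["Emax"] * dose / (dose + p["IC50"])
        else:
            eps = np.zeros_like(dose)
        r = p["lambda"] * (1.0 - eps)
        return _predict_counts(day, r, p["K"], p["N0"])

    def report(self) -> dict:
        """Flat key-value summary suitable for JSON output."""
        out: dict = {**self.params}
        out.update(
            ssr=self.ssr,
            converged=self.converged,
            n_iterations=self.n_iterations,
            boundary_hit=self.boundary_hit,
            unreliable=self.unreliable,
        )
        if self.fixed:
            out["fixed"] = dict(self.fixed)
        if self.ci_lower is not None:
            out["ci_lower"] = dict(self.ci_lower)
            out["ci_upper"] = dict(self.ci_upper)
        if self.seed is not None:
            out["seed"] = self.seed
        if self.warnings:
            out["warnings"] = list(self.warnings)
        return out


def _predict_counts(day, r, K, N0):
    """Logistic counts for per-row rates (vectorized over rows)."""
    day = np.asarray(day, float)
    r = np.broadcast_to(np.asarray(r, float), day.shape)
    x = r * day
    if N0 == K:
        return np.full_like(day, float(K))
    if N0 < K:
        return K * expit(x - np.log(K / N0 - 1.0))
    c = K / N0 - 1.0
    return K / (1.0 + c * np.exp(-np.clip(x, -700.0, 700.0)))


def ssr(dataset: GrowthDataset, predicted) -> float:
    """Sum of squared residuals between observed counts and predictions.

    ``predicted`` may be a mapping ``{(dose, day): count}`` or an array
    aligned with ``dataset.records``.  Every replicate contributes its
    own squared residual.  A missing prediction raises ``KeyError``
    naming the (dose, day) point.
    """
    obs = dataset.records["count"].to_numpy(float)
    if isinstance(predicted, dict):
        dose = dataset.records["dose_ug_ml"].to_numpy(float)
        day = dataset.records["day"].to_numpy(float)
        pred = np.empty_like(obs)
        for i, key in enumerate(zip(dose, day)):
            try:
                pred[i] = predicted[key]
            except KeyError:
                raise KeyError(
                    f"no prediction for observed point (dose={key[0]}, day={key[1]})"
                ) from None
    else:
        pred = np.asarray(predicted, float)
        if pred.shape != obs.shape:
            raise ValueError(
                f"predicted has shape {pred.shape}, expected {obs.shape}"
            )
    return float(np.sum((obs - pred) ** 2))


# ---------------------------------------------------------------------------
# step one: control fit
# ---------------------------------------------------------------------------

def _control_start(day: np.ndarray, count: np.ndarray, N0: float) -> tuple[float, float]:
    """Heuristic start: lambda from log-linear regression of early counts,
    K from 1.5x the largest observed count."""
    K0 = max(1.5 * float(np.max(count)), N0 * 1.0001)
    # mean count per day, earliest up-to-4 days, zeros excluded from the log
    days = np.unique(day)
    means, used = [], []
    for d in days[:4]:
        m = float(np.mean(count[day == d]))
        if m > 0:
            means.append(np.log(m))
            used.append(d)
    if len(used) >= 2:
        slope = np.polyfit(used, means, 1)[0]
    elif len(used) == 1 and used[0] > 0:
        slope = (means[0] - np.log(N0)) / used[0]
    else:
        slope = 0.5
    lam0 = float(np.clip(slope, 0.01, 5.0))
    return lam0, K0


def _run_nelder_mead(objective, x0: np.ndarray, config: FitConfig):
    scale = config.simplex_scale
    n = len(x0)
    simplex = np.tile(x0, (n + 1, 1))
    for i in range(n):
        step = scale * abs(x0[i]) if x0[i] != 0 else scale
        simplex[i + 1, i] += step
    # scipy's fatol is absolute; scale by f(x0) to make ftol effectively relative
    f0 = abs(objective(x0))
    return minimize(
        objective,
        x0,
        method="Nelder-Mead",
        options=dict(
            xatol=config.xtol,
            fatol=config.ftol * max(1.0, f0),
            maxiter=config.maxiter,
            maxfev=4 * config.maxiter,
            initial_simplex=simplex,
        ),
    )


def fit_control(dataset: GrowthDataset, config: FitConfig | None = None) -> FitResult:
    """Fit ``(lambda, K)`` — optionally also ``N0`` — to the dose-0 curves.

    ``N0`` defaults to the recorded plating density; set
    ``config.estimate_n0`` to treat it as a free parameter.
    """
    config = config or FitConfig()
    ctrl = dataset.control()
    if config.max_day is not None:
        ctrl = ctrl.truncated(config.max_day)
    rec = ctrl.records
    if len(rec) == 0:
        raise DegenerateDataError("no dose-0 control records in dataset")
    day = rec["day"].to_numpy(float)
    count = rec["count"].to_numpy(float)
    if len(np.unique(day)) < 3:
        raise DegenerateDataError(
            f"control fit needs >= 3 distinct days, got {len(np.unique(day))}"
        )
    if np.all(count == 0):
        raise DegenerateDataError("all control counts are zero")

    result_warnings: list[str] = []
    if np.ptp(count) == 0:
        result_warnings.append(
            "control counts are constant: growth rate is unidentifiable"
        )

    if dataset.plating_density is not None:
        N0 = float(dataset.plating_density)
    else:
        d0 = np.min(day)
        N0 = float(np.mean(count[day == d0]))
        if N0 <= 0:
            N0 = 1.0
    lam0, K0 = _control_start(day, count, N0)

    if config.estimate_n0:
        x0 = np.log([lam0, K0, N0])

        def objective(x):
            lam, K, n0 = np.exp(x)
            return float(np.sum((count - _predict_counts(day, lam, K, n0)) ** 2))

    else:
        x0 = np.log([lam0, K0])

        def objective(x):
            lam, K = np.exp(x)
            return float(np.sum((count - _predict_counts(day, lam, K, N0)) ** 2))

    res = _run_nelder_mead(objective, x0, config)
    est = np.exp(res.x)
    params = {"lambda": float(est[0]), "K": float(est[1])}
    fixed = {}
    if config.estimate_n0:
        params["N0"] = float(est[2])
    else:
        fixed["N0"] = N0
    return FitResult(
        params=params,
        ssr=float(res.fun),
        converged=bool(res.success),
        n_iterations=int(res.nit),
        fixed=fixed,
        seed=config.seed,
        warnings=result_warnings,
    )


# ---------------------------------------------------------------------------
# step two: joint treated fit
# ---------------------------------------------------------------------------

def fit_treated(
    dataset: GrowthDataset,
    control: GrowthParameters,
    config: FitConfig | None = None,
) -> FitResult:
    """Fit one ``(Emax, IC50)`` pair jointly to all dose > 0 curves.

    The control parameters are held fixed; all treated curves share the
    single efficacy pair (pooled SSR), never per-dose fits.
    """
    config = config or FitConfig()
    trt = dataset.treated()
    if config.max_day is not None:
        trt = trt.truncated(config.max_day)
    rec = trt.records
    if len(rec) == 0:
        raise DegenerateDataError("no dose > 0 records in dataset")
    dose = rec["dose_ug_ml"].to_numpy(float)
    day = rec["day"].to_numpy(float)
    count = rec["count"].to_numpy(float)

    result_warnings: list[str] = []
    unique_doses = np.unique(dose)
    if len(unique_doses) < 2:
        result_warnings.append(
            "single treated dose: Emax and IC50 are confounded (unidentifiable)"
        )

    upper = config.emax_upper
    lam, K, N0 = control.lambda_, control.K, control.N0
    ic50_start = float(np.exp(np.mean(np.log(unique_doses))))
    x0 = np.array([logit(0.5 / upper), np.log(ic50_start)])

    def objective(x):
        emax = upper * expit(x[0])
        ic50 = np.exp(x[1])
        r = lam * (1.0 - emax * dose / (dose + ic50))
        return float(np.sum((count - _predict_counts(day, r, K, N0)) ** 2))

    res = _run_nelder_mead(objective, x0, config)
    emax = float(upper * expit(res.x[0]))
    ic50 = float(np.exp(res.x[1]))

    boundary = bool(abs(res.x[0]) > 12.0)  # Emax within ~1e-5 of a bound
    log_doses = np.log(unique_doses)
    if res.x[1] > log_doses.max() + np.log(100) or res.x[1] < log_doses.min() - np.log(100):
        boundary = True
        result_warnings.append(
            "fitted IC50 lies far outside the tested dose range"
        )

    return FitResult(
        params={"Emax": emax, "IC50": ic50},
        ssr=float(res.fun),
        converged=bool(res.success),
        n_iterations=int(res.nit),
        fixed={"lambda": lam, "K": K, "N0": N0},
        seed=config.seed,
        boundary_hit=boundary,
        warnings=result_warnings,
    )


def two_step_fit(dataset: GrowthDataset, config: FitConfig | None = None) -> FitResult:
    """Control fit followed by the treated fit; returns all four parameters.

    The combined result reports ``lambda, K, Emax, IC50`` (plus ``N0``
    when it was estimated) with the pooled SSR of both steps.
    """
    config = config or FitConfig()
    ctrl_fit = fit_control(dataset, config)
    trt_fit = fit_treated(dataset, ctrl_fit.growth_parameters(), config)
    params = {**ctrl_fit.params, **trt_fit.params}
    fixed = {k: v for k, v in ctrl_fit.fixed.items() if k not in params}
    return FitResult(
        params=params,
        ssr=ctrl_fit.ssr + trt_fit.ssr,
        converged=ctrl_fit.converged and trt_fit.converged,
        n_iterations=ctrl_fit.n_iterations + trt_fit.n_iterations,
        fixed=fixed,
        seed=config.seed,
        boundary_hit=trt_fit.boundary_hit,
        warnings=ctrl_fit.warnings + trt_fit.warnings,
    )


# ---------------------------------------------------------------------------
# bootstrap confidence intervals
# ---------------------------------------------------------------------------

def _resample_case(dataset: GrowthDataset, groups, counts, rng) -> GrowthDataset:
    new_counts = counts.copy()
    for idx in groups:
        pick = rng.integers(0, len(idx), len(idx))
        new_counts[idx] = counts[idx[pick]]
    return dataset.with_counts(new_counts)


def _resample_residual(dataset, counts, predicted, rng) -> GrowthDataset:
    resid = counts - predicted
    pick = rng.integers(0, len(resid), len(resid))
    new_counts = np.maximum(predicted + resid[pick], 0.0)
    return dataset.with_counts(new_counts)


def bootstrap_ci(
    dataset: GrowthDataset,
    fitted: FitResult,
    n_boot: int | None = None,
    seed: int | None = None,
    config: FitConfig | None = None,
    fit_fn=None,
) -> FitResult:
    """Percentile bootstrap confidence intervals for a fitted result.

    Resamples the dataset ``n_boot`` times (default from config: 1000),
    refits with ``fit_fn`` (default: the two-step procedure) and takes
    the 2.5/97.5 percentiles of each parameter.  Case resampling of
    replicate wells within each (condition, dose, day) cell is used when
    true replicates exist; otherwise residual resampling.  The draw
    sequence is fully determined by ``seed``.
    """
    config = config or FitConfig()
    if n_boot is None:
        n_boot = config.n_boot
    if n_boot < 2:
        raise ValueError(f"n_boot must be >= 2, got {n_boot}")
    if not fitted.converged:
        raise ValueError("bootstrap requires a converged point fit")
    if fit_fn is None:
        fit_fn = lambda ds: two_step_fit(ds, config)  # noqa: E731

    if seed is None:
        seed = config.seed
    rng = np.random.default_rng(seed)

    rec = dataset.records
    counts = rec["count"].to_numpy(float)
    groups = [
        idx.to_numpy()
        for _, idx in rec.groupby(["condition", "dose_ug_ml", "day"]).groups.items()
    ]
    max_reps = max(len(g) for g in groups)
    scheme = config.bootstrap_scheme
    if scheme == "auto":
        scheme = "case" if max_reps > 1 else "residual"
    if scheme == "residual":
        predicted = fitted.predict(dataset)

    names = fitted.param_names
    samples = np.full((n_boot, len(names)), np.nan)
    n_failed = 0
    for b in range(n_boot):
        if scheme == "case":
            ds_b = _resample_case(dataset, groups, counts, rng)
        else:
            ds_b = _resample_residual(dataset, counts, predicted, rng)
        try:
            res_b = fit_fn(ds_b)
        except (DegenerateDataError, ValueError):
            n_failed += 1
            continue
        if not res_b.converged:
            n_failed += 1
            continue
        samples[b] = [res_b.params[k] for k in names]

    ok = ~np.isnan(samples[:, 0])
    result_warnings = list(fitted.warnings)
    unreliable = False
    if n_failed > 0.2 * n_boot:
        unreliable = True
        result_warnings.append(
            f"{n_failed}/{n_boot} bootstrap refits failed to converge"
        )
    lo = np.percentile(samples[ok], 2.5, axis=0)
    hi = np.percentile(samples[ok], 97.5, axis=0)
    ci_lower = dict(zip(names, map(float, lo)))
    ci_upper = dict(zip(names, map(float, hi)))
    for k in names:
        if not ci_lower[k] <= fitted.params[k] <= ci_upper[k]:
            result_warnings.append(
                f"point estimate of {k} lies outside its percentile interval"
            )
    return replace(
        fitted,
        bootstrap_samples=samples,
        ci_lower=ci_lower,
        ci_upper=ci_upper,
        seed=seed,
        unreliable=unreliable,
        warnings=result_warnings,
    )
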