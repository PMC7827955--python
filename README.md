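# emaxfit

Time-independent estimation of drug efficacy from cell growth curves.

Endpoint viability readouts (e.g. MTT assays) yield an IC50 that drifts
with the measurement day, because both treated and untreated cultures
keep growing.  `emaxfit` instead fits a mechanistic model whose
parameters do not depend on when you measure:

* cells grow logistically, `dN/dt = λ N (1 − N/K)`;
* a drug at concentration `D` scales the growth rate by `(1 − ε)` with
  the Emax efficacy model `ε = Emax · D / (D + IC50)`.

The package provides:

* **`emaxfit.model`** — closed-form forward model (efficacy, effective
  rate, logistic trajectories, dosed growth curves).
* **`emaxfit.fitting`** — the two-step procedure: fit `(λ, K)` to the
  untreated control, then hold those fixed and fit one `(Emax, IC50)`
  pair jointly to all treated curves by minimizing the sum of squared
  residuals with Nelder–Mead; percentile bootstrap confidence intervals
  (1000 replicates by default, case-resampling replicate wells).
* **`emaxfit.mtt`** — forward simulation of MTT viability plates
  (viability = treated/control count at the measurement day) and
  extraction of the apparent, day-dependent IC50 (log-dose
  interpolation at the 50% crossing, or a 4-parameter logistic fit);
  formulation comparison tables.
* **`emaxfit.synth`** — synthetic datasets with configurable noise
  (multiplicative lognormal, additive Gaussian, Poisson counts) and
  named design presets `paper-growth` (counts every other day over 14
  days at doses 0–0.05 µg/mL, 3 replicates) and `paper-mtt` (twofold
  dilutions 0.00625–1.6 µg/mL read at days 2, 4, 6, 8).
* **`emaxfit.io`** — CSV readers/writers, YAML run configuration, and
  the corrected-total-cell-fluorescence (CTCF) utility.

## Quick start

```python
from emaxfit import (DrugEffect, GrowthParameters, NoiseModel,
                     two_step_fit, bootstrap_ci, ic50_vs_time)
from emaxfit.synth import design_preset, generate_growth_dataset

truth = GrowthParameters(lambda_=0.6, K=6e4, N0=1000)
effect = DrugEffect(Emax=0.8, IC50=2e-3)
data = generate_growth_dataset(truth, effect, design_preset("paper-growth"),
                               NoiseModel(sigma=0.1), seed=1)

fit = two_step_fit(data)                       # lambda, K, Emax, IC50
fit = bootstrap_ci(data, fit, n_boot=1000, seed=1)
print(fit.report())

curve = ic50_vs_time(truth, effect)            # apparent IC50 vs day
print(curve.to_frame())
```

## Command line

```sh
emaxfit synth --preset paper-growth --seed 7 --sigma 0.1 --outdir out/
emaxfit fit --data out/growth.csv --n-boot 1000 --seed 7 --out out/report.json
emaxfit mtt --lam 0.6 --capacity 5e6 --n0 5000 --emax 0.9 --ic50 0.15 \
            --days 2,4,6,8 --out out/ic50.csv
emaxfit compare --lam 0.6 --capacity 5e6 --n0 5000 \
            --emax-a 0.85 --ic50-a 0.54 --emax-b 0.935 --ic50-b 0.1 \
            --out out/compare.csv
```

Growth tables are long-format CSV with header
`cell_line,condition,dose_ug_ml,day,replicate,count`; dose 0 encodes the
untreated control.  Synthetic tables carry their generating truth in a
`*.meta.json` sidecar.

## Tests and acceptance

```sh
python -m pytest -q                      # full suite (bootstrap coverage
                                         # test takes several minutes)
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

The acceptance script exercises the full pipeline (synthesize → fit →
MTT drift) and writes the machine-readable report; the quantitative
acceptance properties live in `tests/test_acceptance.py`.
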