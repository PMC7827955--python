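"""Delimited-text readers/writers, run configuration, and the CTCF utility.

All tables are comma-separated UTF-8 with a header row; no binary
formats.  Synthetic datasets carry their generating truth in a JSON
sidecar next to the CSV (``<name>.meta.json``).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .data import REQUIRED_COLUMNS, GrowthDataset
from .mtt import ApparentIC50Curve, MTTSeries

__all__ = [
    "SchemaError",
    "RunConfig",
    "read_growth_table",
    "write_growth_table",
    "read_mtt_table",
    "write_mtt_table",
    "write_ic50_table",
    "compute_ctcf",
]


class SchemaError(ValueError):
    """A table is missing required columns or contains invalid values."""


def read_growth_table(path) -> GrowthDataset:
    """Read a long-format growth table (see ``REQUIRED_COLUMNS``).

    Raises :class:`SchemaError` naming any missing column; negative
    counts are reported with their line numbers.  A ``.meta.json``
    sidecar, if present, supplies plating density and generating truth.
    """
    path = Path(path)
    df = pd.read_csv(path)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path.name}: missing required column(s) {missing}")
    for col in ("dose_ug_ml", "day", "count"):
        values = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[values.isna()]
        if len(bad):
            # +2: header line plus 1-based numbering
            lines = [int(i) + 2 for i in bad[:5]]
            raise SchemaError(f"{path.name}: non-numeric {col!r} at line(s) {lines}")
        df[col] = values
    bad = df.index[df["count"] < 0]
    if len(bad):
        lines = [int(i) + 2 for i in bad[:5]]
        raise SchemaError(f"{path.name}: negative count at line(s) {lines}")

    plating, truth = None, None
    sidecar = path.with_suffix(".meta.json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        plating = meta.get("plating_density")
        truth = meta.get("truth")
    ds = GrowthDataset(records=df, plating_density=plating, truth=truth)
    ds.validate(require_control=False)
    return ds


def write_growth_table(dataset: GrowthDataset, path) -> None:
    """Write the records CSV plus a ``.meta.json`` sidecar."""
    path = Path(path)
    dataset.records.to_csv(path, index=False)
    meta = {"plating_density": dataset.plating_density}
    if dataset.truth is not None:
        meta["truth"] = dataset.truth
    path.with_suffix(".meta.json").write_text(
        json.dumps(meta, indent=2, sort_keys=True) + "\n"
    )


def write_mtt_table(series_list: list[MTTSeries], path) -> None:
    """Stack viability series into one (day, dose_ug_ml, viability) CSV."""
    frames = [s.to_frame() for s in series_list]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_mtt_table(path) -> list[MTTSeries]:
    """Read a stacked viability CSV back into per-day series.

    Also accepts plate-style wide input with one ``dose_ug_ml`` column
    and one column per day named ``day_<d>`` (reshaped to long form).
    """
    path = Path(path)
    df = pd.read_csv(path)
    day_cols = [c for c in df.columns if c.startswith("day_")]
    if "viability" not in df.columns and day_cols:
        if "dose_ug_ml" not in df.columns:
            raise SchemaError(f"{path.name}: missing required column(s) ['dose_ug_ml']")
        df = df.melt(
            id_vars=["dose_ug_ml"], value_vars=day_cols,
            var_name="day", value_name="viability",
        )
        df["day"] = df["day"].str.removeprefix("day_").astype(float)
    missing = [c for c in ("day", "dose_ug_ml", "viability") if c not in df.columns]
    if missing:
        raise SchemaError(f"{path.name}: missing required column(s) {missing}")
    out = []
    for day, sub in df.groupby("day"):
        sub = sub.sort_values("dose_ug_ml")
        out.append(
            MTTSeries(
                measurement_day=float(day),
                doses=sub["dose_ug_ml"].to_numpy(float),
                viability=sub["viability"].to_numpy(float),
            )
        )
    return out


def write_ic50_table(curve: ApparentIC50Curve, path) -> None:
    curve.to_frame().to_csv(path, index=False)


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Serializable settings of one analysis run.

    A run is reproducible from its config plus seed alone.
    """

    seed: int | None = None
    preset: str = "paper-growth"
    noise_kind: str = "multiplicative-lognormal"
    sigma: float = 0.1
    emax_upper: float = 2.0
    estimate_n0: bool = False
    max_day: float | None = None
    n_boot: int = 1000
    bootstrap_scheme: str = "auto"
    output_dir: str = "."

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise SchemaError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))


# ---------------------------------------------------------------------------
# corrected total cell fluorescence
# ---------------------------------------------------------------------------

def compute_ctcf(integrated_density, cell_area, mean_background):
    """Corrected total cell fluorescence.

    ``integrated_density - cell_area * mean_background`` (a.u.).  Inputs
    must be nonnegative; the result may legitimately be negative (a dim
    cell on a bright background) and is returned unclipped.
    """
    integrated_density = np.asarray(integrated_density, dtype=float)
    cell_area = np.asarray(cell_area, dtype=float)
    mean_background = np.asarray(mean_background, dtype=float)
    for name, value in (
        ("integrated_density", integrated_density),
        ("cell_area", cell_area),
        ("mean_background", mean_background),
    ):
        if np.any(value < 0):
            raise ValueError(f"{name} must be >= 0, got {float(np.min(value))}")
    ctcf = integrated_density - cell_area * mean_background
    return float(ctcf) if ctcf.ndim == 0 else ctcf
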