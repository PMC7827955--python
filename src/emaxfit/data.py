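"""Tabular container for replicated cell-count time courses."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

__all__ = ["REQUIRED_COLUMNS", "GrowthDataset", "records_frame"]

#: Long-format schema: one row per counted well.
REQUIRED_COLUMNS = ("cell_line", "condition", "dose_ug_ml", "day", "replicate", "count")


def records_frame(rows: Iterable[tuple]) -> pd.DataFrame:
    """Build a records table from (cell_line, condition, dose, day, replicate, count) tuples."""
    return pd.DataFrame(list(rows), columns=list(REQUIRED_COLUMNS))


@dataclass
class GrowthDataset:
    """Replicated cell counts indexed by (condition, dose, day).

    ``records`` is a long-format table with columns
    ``cell_line, condition, dose_ug_ml, day, replicate, count``.
    Dose 0 encodes the untreated control arm.

    ``truth`` optionally records the generating parameters of a
    synthetic dataset (for recovery tests); it is never used by fitting.
    """

    records: pd.DataFrame
    plating_density: float | None = None
    truth: dict | None = None

    def __post_init__(self) -> None:
        missing = [c for c in REQUIRED_COLUMNS if c not in self.records.columns]
        if missing:
            raise ValueError(f"records missing required column(s): {missing}")
        self.records = self.records.reset_index(drop=True)

    # -- views -----------------------------------------------------------
    @property
    def doses(self) -> np.ndarray:
        return np.sort(self.records["dose_ug_ml"].unique())

    @property
    def days(self) -> np.ndarray:
        return np.sort(self.records["day"].unique())

    @property
    def cell_lines(self) -> list[str]:
        return sorted(self.records["cell_line"].astype(str).unique())

    def __len__(self) -> int:
        return len(self.records)

    def control(self) -> "GrowthDataset":
        """Subset at dose 0 (the untreated arm)."""
        sub = self.records[self.records["dose_ug_ml"] == 0.0]
        return GrowthDataset(sub.copy(), self.plating_density, self.truth)

    def treated(self) -> "GrowthDataset":
        """Subset at dose > 0."""
        sub = self.records[self.records["dose_ug_ml"] > 0.0]
        return GrowthDataset(sub.copy(), self.plating_density, self.truth)

    def truncated(self, max_day: float) -> "GrowthDataset":
        """Drop observations after ``max_day`` (overcrowding guard)."""
        sub = self.records[self.records["day"] <= max_day]
        return GrowthDataset(sub.copy(), self.plating_density, self.truth)

    def with_counts(self, counts: np.ndarray) -> "GrowthDataset":
        """Copy with the count column replaced (used by resampling)."""
        rec = self.records.copy()
        rec["count"] = np.asarray(counts, dtype=float)
        return GrowthDataset(rec, self.plating_density, self.truth)

    # -- validation ------------------------------------------------------
    def validate(self, require_control: bool = True) -> None:
        """Raise ``ValueError`` on schema violations.

        Checks nonnegative counts and days and, when ``require_control``,
        the presence of exactly one dose-0 condition per cell line.
        """
        rec = self.records
        bad = rec.index[rec["count"] < 0]
        if len(bad):
            raise ValueError(f"negative count at record row(s) {list(bad[:5])}")
        bad = rec.index[rec["day"] < 0]
        if len(bad):
            raise ValueError(f"negative day at record row(s) {list(bad[:5])}")
        bad = rec.index[rec["dose_ug_ml"] < 0]
        if len(bad):
            raise ValueError(f"negative dose at record row(s) {list(bad[:5])}")
        if require_control:
            for line, sub in rec.groupby("cell_line"):
                ctrl = sub[sub["dose_ug_ml"] == 0.0]["condition"].unique()
                if len(ctrl) != 1:
                    raise ValueError(
                        f"cell line {line!r} must have exactly one dose-0 "
                        f"control condition, found {sorted(map(str, ctrl))}"
                    )
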