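"""Cohort dataset container and CSV IO.

A cohort is a pair of tables: one row per patient (observed time, event
status, baseline covariates) and a long-format biomarker table (id, t, y)
with y on the natural-log scale.  Raw-scale biomarker input must be
strictly positive and is log-transformed at load.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["CohortDataset"]

DEFAULT_SCHEDULE = (0.0, 1.0, 3.0, 6.0, 9.0, 12.0)


@dataclass
class CohortDataset:
    baseline: pd.DataFrame
    longitudinal: pd.DataFrame
    schedule: tuple[float, ...] = DEFAULT_SCHEDULE
    covariates: list[str] = field(default_factory=lambda: ["age", "sex", "extra_mets"])

    def __post_init__(self) -> None:
        need = {"id", "time_obs", "status"}
        if not need.issubset(self.baseline.columns):
            raise ValueError(f"baseline table needs columns {sorted(need)}")
        if not {"id", "t", "y"}.issubset(self.longitudinal.columns):
            raise ValueError("longitudinal table needs columns id, t, y")
        if (self.baseline["time_obs"] <= 0).any():
            raise ValueError("observed times must be positive")

    @classmethod
    def from_csv(
        cls,
        baseline_csv: str | Path,
        longitudinal_csv: str | Path,
        schedule: tuple[float, ...] = DEFAULT_SCHEDULE,
        covariates: list[str] | None = None,
        value_scale: str = "log",
    ) -> "CohortDataset":
        baseline = pd.read_csv(baseline_csv)
        long = pd.read_csv(longitudinal_csv).dropna(subset=["y"])
        if value_scale == "raw":
            if (long["y"] <= 0).any():
                raise ValueError(
                    "raw-scale biomarker values must be strictly positive "
                    "before log transformation"
                )
            long = long.assign(y=np.log(long["y"]))
        elif value_scale != "log":
            raise ValueError("value_scale must be 'log' or 'raw'")
        if covariates is None:
            covariates = [
                c for c in baseline.columns if c not in {"id", "time_obs", "status"}
            ]
        return cls(
            baseline=baseline,
            longitudinal=long,
            schedule=schedule,
            covariates=covariates,
        )

    def snapshot(self, month: float) -> pd.Series:
        """Log-biomarker value at a given visit month, indexed by patient id."""
        sub = self.longitudinal[np.isclose(self.longitudinal["t"], month)]
        return sub.set_index("id")["y"]
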