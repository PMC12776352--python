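"""Admission container: one ICU stay on a regular hourly grid.

An :class:`AdmissionTable` holds one admission window's per-variable values
on a unit-spaced hourly grid, with NaN marking missing cells, plus the name
of the output variable (default ``pH``).  Long-format CSV round trips use
the columns ``admission_id, hour, variable, value``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["AdmissionTable", "OUTPUT_VAR", "COVARIATES"]

OUTPUT_VAR = "pH"
COVARIATES = ("pCO2", "SID", "lactate")


@dataclass
class AdmissionTable:
    """Hourly grid of one admission's measurements.

    ``frame`` is indexed by integer hour (strictly increasing, unit
    spaced), one column per variable; the output column must be present.
    """

    admission_id: str
    frame: pd.DataFrame
    output_var: str = OUTPUT_VAR

    def __post_init__(self) -> None:
        hours = np.asarray(self.frame.index)
        if hours.size == 0:
            raise ValueError("admission has no rows")
        if not np.array_equal(hours, np.arange(hours[0], hours[0] + hours.size)):
            raise ValueError("hours must be strictly increasing and unit-spaced")
        if self.output_var not in self.frame.columns:
            raise ValueError(f"output column {self.output_var!r} missing")

    @property
    def hours(self) -> np.ndarray:
        return np.asarray(self.frame.index, dtype=float)

    @property
    def covariates(self) -> list:
        return [c for c in self.frame.columns if c != self.output_var]

    @property
    def n_hours(self) -> int:
        return len(self.frame)

    def covariate_matrix(self) -> np.ndarray:
        """(N, P) covariate values with NaN for missing cells."""
        return self.frame[self.covariates].to_numpy(dtype=float)

    def copy(self) -> "AdmissionTable":
        return AdmissionTable(self.admission_id, self.frame.copy(),
                              self.output_var)

    # -- long-format CSV ---------------------------------------------------
    def to_long(self) -> pd.DataFrame:
        long = (self.frame.reset_index(names="hour")
                .melt(id_vars="hour", var_name="variable", value_name="value")
                .dropna(subset=["value"]))
        long.insert(0, "admission_id", self.admission_id)
        return long.sort_values(["variable", "hour"]).reset_index(drop=True)

    @classmethod
    def from_long(cls, long: pd.DataFrame, admission_id: str | None = None,
                  output_var: str = OUTPUT_VAR) -> "AdmissionTable":
        df = long
        if admission_id is not None:
            df = df[df["admission_id"] == admission_id]
        elif "admission_id" in df.columns:
            ids = df["admission_id"].unique()
            if len(ids) != 1:
                raise ValueError("long table contains multiple admissions; "
                                 "pass admission_id")
            admission_id = ids[0]
        wide = df.pivot_table(index="hour", columns="variable", values="value",
                              aggfunc="mean")
        lo, hi = int(wide.index.min()), int(wide.index.max())
        wide = wide.reindex(range(lo, hi + 1))
        wide.columns.name = None
        cols = [output_var] + sorted(c for c in wide.columns if c != output_var)
        return cls(str(admission_id), wide[cols], output_var)
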