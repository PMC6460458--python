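"""Tidy time-course datasets of photoconverted-cell counts.

One row per measurement: ``(design_id, condition, t_pc, site, t_harvest,
replicate, count)``. All times are hours post-injection.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd

from .designs import SITES, PhotoconversionDesign
from .parameters import Condition

COLUMNS = ("design_id", "condition", "t_pc", "site", "t_harvest", "replicate", "count")


class ValidationError(ValueError):
    """Raised when observation records violate the schema."""


def _validate_frame(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"missing required column(s): {missing}")
    df = df.loc[:, list(COLUMNS)].copy()
    if len(df) == 0:
        raise ValidationError("dataset contains no observations")
    df["condition"] = df["condition"].map(lambda v: Condition.coerce(v).value)
    bad_site = ~df["site"].isin(SITES)
    if bad_site.any():
        row = int(np.flatnonzero(bad_site.to_numpy())[0])
        raise ValidationError(f"row {row}: site must be one of {SITES}")
    for col in ("t_pc", "t_harvest", "count"):
        df[col] = pd.to_numeric(df[col], errors="raise").astype(float)
    df["replicate"] = df["replicate"].astype(int)
    for col, msg in (
        ("t_pc", "t_pc must be >= 0"),
        ("count", "count must be >= 0"),
    ):
        bad = df[col].to_numpy() < 0
        if bad.any():
            raise ValidationError(f"row {int(np.flatnonzero(bad)[0])}: {msg}")
    bad = (df["t_harvest"].to_numpy() < df["t_pc"].to_numpy())
    if bad.any():
        raise ValidationError(
            f"row {int(np.flatnonzero(bad)[0])}: t_harvest must be >= t_pc"
        )
    if not np.all(np.isfinite(df["count"].to_numpy())):
        raise ValidationError("counts must be finite")
    return df


@dataclass
class TimeCourseDataset:
    """Collection of photoconverted-cell counts keyed by
    (design, condition, site, harvest time, replicate)."""

    frame: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        self.frame = _validate_frame(pd.DataFrame(self.frame))

    # -- constructors -------------------------------------------------
    @classmethod
    def from_records(cls, records: Iterable[tuple]) -> "TimeCourseDataset":
        return cls(pd.DataFrame(list(records), columns=list(COLUMNS)))

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "TimeCourseDataset":
        return cls(df)

    # -- accessors ----------------------------------------------------
    @property
    def n_obs(self) -> int:
        return len(self.frame)

    @property
    def conditions(self) -> list[Condition]:
        return [Condition(c) for c in sorted(self.frame["condition"].unique())]

    def designs(self) -> list[PhotoconversionDesign]:
        """Reconstruct the design list from the observation rows."""
        out = []
        for (design_id, cond, t_pc), grp in self.frame.groupby(
            ["design_id", "condition", "t_pc"], sort=True
        ):
            sites = tuple(s for s in SITES if s in set(grp["site"]))
            harvests = tuple(sorted(grp["t_harvest"].unique()))
            n_rep = int(grp.groupby(["site", "t_harvest"]).size().max())
            out.append(
                PhotoconversionDesign(
                    cond, float(t_pc), harvests, n_rep, sites, design_id=design_id
                )
            )
        return out

    def subset(self, condition: Condition | str) -> "TimeCourseDataset":
        cond = Condition.coerce(condition).value
        return TimeCourseDataset(self.frame[self.frame["condition"] == cond])

    def scaled(self, factor: float) -> "TimeCourseDataset":
        """Same dataset with all counts multiplied by ``factor``."""
        df = self.frame.copy()
        df["count"] = df["count"] * factor
        return TimeCourseDataset(df)

    def equals(self, other: "TimeCourseDataset") -> bool:
        a = self.frame.sort_values(list(COLUMNS)).reset_index(drop=True)
        b = other.frame.sort_values(list(COLUMNS)).reset_index(drop=True)
        return a.equals(b)
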