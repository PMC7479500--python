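"""Participant table container.

A :class:`Cohort` wraps a pandas DataFrame with one row per participant and
a documented column schema. It is the hub every stage keys off: sampling,
leave-one-participant-out prediction, and the nested (family/subject)
grouping of the longitudinal model.

Column schema
-------------
subject_id : str, unique
family_id : str; shared only within the high-risk groups under defaults
group : one of ``C-well``, ``HR-well``, ``HR-MD`` (optionally ``C-MD``)
sex : int, 0 = male, 1 = female
age_t1 : float, years at baseline
age_t2 : float, years at follow-up; NaN when ``has_followup`` is False
has_followup : bool
hrsd_t1, hrsd_t2 : int Hamilton depression scores (hrsd_t2 NaN w/o follow-up)
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .config import GROUP_C_MD, GROUPS

COLUMNS = [
    "subject_id",
    "family_id",
    "group",
    "sex",
    "age_t1",
    "age_t2",
    "has_followup",
    "hrsd_t1",
    "hrsd_t2",
]

_VALID_GROUPS = set(GROUPS) | {GROUP_C_MD}


@dataclass(frozen=True)
class Cohort:
    """Immutable participant table (one row per participant)."""

    table: pd.DataFrame

    def __post_init__(self):
        df = self.table
        missing = [c for c in COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"cohort table missing columns: {missing}")
        if df["subject_id"].duplicated().any():
            dupes = df.loc[df["subject_id"].duplicated(), "subject_id"].tolist()
            raise ValueError(f"duplicate subject_ids: {dupes}")
        bad = set(df["group"]) - _VALID_GROUPS
        if bad:
            raise ValueError(f"unknown group labels: {sorted(bad)}")
        fu = df["has_followup"].astype(bool)
        if df.loc[fu, "age_t2"].isna().any() or df.loc[~fu, "age_t2"].notna().any():
            raise ValueError("age_t2 must be present iff has_followup")
        if (df.loc[fu, "age_t2"] <= df.loc[fu, "age_t1"]).any():
            raise ValueError("age_t2 must exceed age_t1")

    def __len__(self) -> int:
        return len(self.table)

    @property
    def subjects(self) -> list[str]:
        return self.table["subject_id"].tolist()

    def row(self, subject_id: str) -> pd.Series:
        hit = self.table[self.table["subject_id"] == subject_id]
        if hit.empty:
            raise KeyError(f"unknown subject {subject_id!r}")
        return hit.iloc[0]

    def group_sizes(self, timepoint: str = "t1") -> dict[str, int]:
        """Number of participants per group contributing a scan at a timepoint."""
        df = self.table if timepoint == "t1" else self.table[self.table["has_followup"]]
        return df.groupby("group").size().to_dict()

    def age_of(self, subject_id: str, timepoint: str) -> float:
        r = self.row(subject_id)
        age = r["age_t1"] if timepoint == "t1" else r["age_t2"]
        if pd.isna(age):
            raise ValueError(f"{subject_id} has no {timepoint} scan")
        return float(age)

    def scans(self) -> list[tuple[str, str]]:
        """All (subject_id, timepoint) scan identifiers, t1 first, table order."""
        out = [(s, "t1") for s in self.table["subject_id"]]
        out += [(s, "t2") for s in self.table.loc[self.table["has_followup"], "subject_id"]]
        return out

    def to_csv(self, path: str | Path) -> None:
        self.table.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "Cohort":
        df = pd.read_csv(
            path,
            dtype={"subject_id": str, "family_id": str, "group": str},
        )
        df["has_followup"] = df["has_followup"].astype(bool)
        df["sex"] = df["sex"].astype(int)
        return cls(df)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "Cohort":
        return cls(df.reset_index(drop=True))


def well_subjects(cohort: Cohort) -> pd.DataFrame:
    """Rows of participants who remained well (the training pool)."""
    return cohort.table[cohort.table["group"].isin(["C-well", "HR-well"])]


def md_subjects(cohort: Cohort) -> pd.DataFrame:
    """Rows of participants who developed a mood disorder."""
    return cohort.table[cohort.table["group"].isin(["HR-MD", GROUP_C_MD])]
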