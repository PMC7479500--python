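"""Residuals-corrected brain-predicted age difference (brain-PAD).

Brain-age predictions correlate with chronological age and may carry a
sex offset, so the raw gap ``predicted - chronological`` is biased by age.
The standard residuals approach regresses predicted age on chronological
age and sex over a reference set — here the leave-one-out predictions of
the training-sample scans — and defines brain-PAD as the residual from
those frozen coefficients. Positive brain-PAD means an older-appearing
brain. Out-of-reference scans are scored with the same frozen model.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .brainage import Prediction
from .cohort import Cohort


@dataclass(frozen=True)
class ResidualModel:
    """OLS fit of predicted age on [1, chronological age, sex code]."""

    intercept: float
    slope_age: float
    slope_sex: float
    fit_n: int

    def expected(self, age: float | np.ndarray, sex: float | np.ndarray) -> np.ndarray:
        return self.intercept + self.slope_age * np.asarray(age) + self.slope_sex * np.asarray(sex)

    def to_json(self, path: str | Path) -> None:
        meta = dict(vars(self), sex_coding="0=male,1=female")
        Path(path).write_text(json.dumps(meta, indent=2))


def fit_residual_model(reference_preds: list[Prediction], cohort: Cohort) -> ResidualModel:
    """Least squares of predicted age on age and sex over the reference set."""
    if len(reference_preds) < 4:
        raise ValueError("need at least 4 reference predictions")
    ages = np.array([p.chronological_age for p in reference_preds])
    sexes = np.array([cohort.row(p.subject_id)["sex"] for p in reference_preds], dtype=float)
    yhat = np.array([p.predicted_age for p in reference_preds])
    if np.ptp(ages) == 0:
        raise ValueError("reference ages are constant; residual design is collinear")
    X = np.column_stack([np.ones_like(ages), ages, sexes])
    coef, *_ = np.linalg.lstsq(X, yhat, rcond=None)
    return ResidualModel(float(coef[0]), float(coef[1]), float(coef[2]), len(reference_preds))


def compute_brainpad(
    preds: list[Prediction], model: ResidualModel, cohort: Cohort
) -> pd.DataFrame:
    """Brain-PAD for every scan of every participant.

    Returns one row per scan with columns ``subject_id, timepoint,
    chronological_age, predicted_age, brain_pad, mode``.
    """
    rows = []
    for p in preds:
        rec = cohort.row(p.subject_id)
        if pd.isna(rec["sex"]) or not np.isfinite(p.chronological_age):
            raise ValueError(f"missing age/sex for scan ({p.subject_id}, {p.timepoint})")
        expected = float(model.expected(p.chronological_age, float(rec["sex"])))
        rows.append(
            (
                p.subject_id,
                p.timepoint,
                p.chronological_age,
                p.predicted_age,
                p.predicted_age - expected,
                p.mode,
            )
        )
    return pd.DataFrame(
        rows,
        columns=["subject_id", "timepoint", "chronological_age", "predicted_age", "brain_pad", "mode"],
    )
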