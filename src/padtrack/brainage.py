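"""Brain-age model: training-sample construction, PCA + RVR fit,
leave-one-participant-out prediction, and evaluation.

The training sample holds one scan per participant who remained well,
balanced across timepoints to maximise the covered age range. Each well
participant's own predictions come from a model refit without their
training entry (mask, PCA and RVR all refit, so no information leaks);
participants who developed a mood disorder are out-of-training-sample and
are predicted from the full model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import Cohort, md_subjects, well_subjects
from .config import ModelOptions
from .pca import PCAModel, fit_pca
from .rvr import RVRModel, fit_rvr
from .volumes import BrainMask, GreyMatterVolume, feature_matrix, threshold_mask, vectorize

Entry = tuple[str, str]  # (subject_id, timepoint)


@dataclass(frozen=True)
class TrainingSample:
    """One scan per well participant, with per-group timepoint counts."""

    entries: tuple[Entry, ...]
    counts: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.entries)

    def subjects(self) -> set[str]:
        return {sid for sid, _ in self.entries}


def build_training_sample(cohort: Cohort) -> TrainingSample:
    """Select the training scans.

    C-well participants contribute their follow-up scan when available,
    otherwise baseline. HR-well participants with follow-up are ranked by
    follow-up age descending (ties broken by subject id) and the top
    ``floor(n_HR-well / 2)`` contribute their follow-up scan; every other
    HR-well participant contributes baseline.
    """
    well = well_subjects(cohort)
    if well.empty:
        raise ValueError("cohort has no well-group participants to train on")
    entries: list[Entry] = []

    cw = well[well["group"] == "C-well"]
    for rec in cw.itertuples(index=False):
        entries.append((rec.subject_id, "t2" if rec.has_followup else "t1"))

    hw = well[well["group"] == "HR-well"]
    n_t2 = math.floor(len(hw) / 2)
    with_fu = hw[hw["has_followup"]].sort_values(
        ["age_t2", "subject_id"], ascending=[False, True]
    )
    t2_ids = set(with_fu["subject_id"].head(n_t2))
    for rec in hw.itertuples(index=False):
        entries.append((rec.subject_id, "t2" if rec.subject_id in t2_ids else "t1"))

    counts: dict[tuple[str, str], int] = {}
    gmap = dict(zip(well["subject_id"], well["group"]))
    for sid, tp in entries:
        key = (gmap[sid], tp)
        counts[key] = counts.get(key, 0) + 1
    return TrainingSample(tuple(entries), counts)


@dataclass(frozen=True)
class FittedBrainAge:
    """The frozen two-stage predictor: union mask -> PCA scores -> RVR."""

    mask: BrainMask
    pca: PCAModel
    rvr: RVRModel
    entries: tuple[Entry, ...]
    ages: np.ndarray

    def predict_volume(self, vol: GreyMatterVolume) -> float:
        """Brain age (years) for one preprocessed volume."""
        fv = vectorize(vol, self.mask)
        return self.predict_features(fv.values)

    def save(self, path) -> None:
        """Persist the model as compressed binary with JSON metadata
        (retained components, relevance-set size, convergence)."""
        import json
        from pathlib import Path

        path = Path(path)
        np.savez_compressed(
            path.with_suffix(".npz"),
            mask_include=self.mask.include,
            mask_voxel_size=np.array([self.mask.voxel_size_mm]),
            pca_mean=self.pca.mean_vector,
            pca_loadings=self.pca.loadings,
            pca_eigenvalues=self.pca.eigenvalues,
            rvr_weights=self.rvr.weights,
            rvr_alphas=self.rvr.alphas,
            rvr_active=self.rvr.active,
            rvr_beta=np.array([self.rvr.beta]),
            rvr_training_scores=self.rvr.training_scores,
            ages=self.ages,
        )
        meta = {
            "format_version": 1,
            "pca_k": self.pca.k,
            "explained_variance_fraction": self.pca.explained_variance_fraction,
            "n_relevance_vectors": int(len(self.rvr.relevance_indices)),
            "rvr_converged": bool(self.rvr.converged),
            "rvr_n_iter": int(self.rvr.n_iter),
            "alpha_min": float(np.min(self.rvr.alphas)),
            "alpha_max": float(np.max(self.rvr.alphas)),
            "entries": [list(e) for e in self.entries],
        }
        path.with_suffix(".json").write_text(json.dumps(meta, indent=2))

    @classmethod
    def load(cls, path) -> "FittedBrainAge":
        import json
        from pathlib import Path

        from .pca import PCAModel
        from .rvr import RVRModel

        path = Path(path)
        data = np.load(path.with_suffix(".npz"))
        meta = json.loads(path.with_suffix(".json").read_text())
        mask = BrainMask(data["mask_include"], float(data["mask_voxel_size"][0]))
        eig = data["pca_eigenvalues"]
        pca = PCAModel(
            data["pca_mean"],
            data["pca_loadings"],
            eig,
            int(meta["pca_k"]),
            float(meta["explained_variance_fraction"]),
        )
        rvr = RVRModel(
            data["rvr_weights"],
            data["rvr_alphas"],
            float(data["rvr_beta"][0]),
            data["rvr_active"],
            data["rvr_training_scores"],
            bool(meta["rvr_converged"]),
            int(meta["rvr_n_iter"]),
            float("nan"),
        )
        entries = tuple((s, t) for s, t in meta["entries"])
        return cls(mask, pca, rvr, entries, data["ages"])

    def predict_features(self, values: np.ndarray) -> float:
        values = np.asarray(values, dtype=float)
        if values.shape != (self.mask.n_voxels,):
            raise ValueError(
                f"feature length {values.shape} does not match mask ({self.mask.n_voxels},)"
            )
        scores = self.pca.transform(values[None, :])
        return float(self.rvr.predict(scores)[0])


def fit_brainage_model(
    store: dict[Entry, GreyMatterVolume],
    entries: tuple[Entry, ...],
    ages: np.ndarray,
    options: ModelOptions | None = None,
) -> FittedBrainAge:
    """Fit mask + PCA + RVR on the given training entries.

    ``store`` maps scan identifiers to *preprocessed* volumes (smoothed,
    downsampled, thresholded). The union-support mask, the PCA and the
    regressor are all estimated from exactly these entries.
    """
    options = options or ModelOptions()
    missing = [e for e in entries if e not in store]
    if missing:
        raise KeyError(f"missing preprocessed volumes for scans: {missing[:5]}")
    vols = [store[e] for e in entries]
    mask = threshold_mask(vols, options.mask_threshold)
    if mask.n_voxels == 0:
        raise ValueError("empty brain mask: no voxel reaches threshold in any training volume")
    X = feature_matrix(vols, mask)
    criterion = "kaiser" if options.pca_criterion == "kaiser" else "mean-eigenvalue"
    pca = fit_pca(X, criterion)
    scores = pca.transform(X)
    rvr = fit_rvr(
        scores,
        np.asarray(ages, dtype=float),
        prune_threshold=options.rvr_prune_threshold,
        tol=options.rvr_tol,
        max_iter=options.rvr_max_iter,
    )
    return FittedBrainAge(mask, pca, rvr, tuple(entries), np.asarray(ages, dtype=float))


@dataclass(frozen=True)
class Prediction:
    subject_id: str
    timepoint: str
    chronological_age: float
    predicted_age: float
    mode: str  # "loo" | "full-model"
    is_training_entry: bool = False


@dataclass(frozen=True)
class LOOResult:
    predictions: tuple[Prediction, ...]
    training_sample: TrainingSample
    full_model: FittedBrainAge
    n_refits: int
    #: For each well participant, the entries their predicting model was fit on.
    refit_entries: dict[str, tuple[Entry, ...]]

    def reference_predictions(self) -> list[Prediction]:
        """LOO predictions of the training-sample scans (one per well participant)."""
        return [p for p in self.predictions if p.is_training_entry]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(p) for p in self.predictions])


def loo_predictions(
    cohort: Cohort,
    store: dict[Entry, GreyMatterVolume],
    options: ModelOptions | None = None,
) -> LOOResult:
    """Predict every scan in the cohort exactly once.

    Well participants: the entire pipeline is refit on the training sample
    minus that participant's entry, and both of their scans are predicted
    from the refit (mode ``loo``). Mood-disorder participants: both scans
    are predicted from the model fit on the complete training sample
    (mode ``full-model``).
    """
    options = options or ModelOptions()
    ts = build_training_sample(cohort)
    age_of = cohort.age_of
    ages = np.array([age_of(sid, tp) for sid, tp in ts.entries])
    full = fit_brainage_model(store, ts.entries, ages, options)
    n_refits = 0
    refit_entries: dict[str, tuple[Entry, ...]] = {}

    def scans_of(rec) -> list[Entry]:
        out = [(rec.subject_id, "t1")]
        if rec.has_followup:
            out.append((rec.subject_id, "t2"))
        return out

    entry_by_subject = {sid: (sid, tp) for sid, tp in ts.entries}
    predictions: list[Prediction] = []

    for rec in well_subjects(cohort).itertuples(index=False):
        held_out = entry_by_subject[rec.subject_id]
        sub_entries = tuple(e for e in ts.entries if e != held_out)
        sub_ages = np.array([age_of(s, t) for s, t in sub_entries])
        model = fit_brainage_model(store, sub_entries, sub_ages, options)
        n_refits += 1
        refit_entries[rec.subject_id] = sub_entries
        for sid, tp in scans_of(rec):
            if (sid, tp) not in store:
                raise KeyError(f"missing preprocessed volume for scan {(sid, tp)}")
            predictions.append(
                Prediction(
                    sid,
                    tp,
                    age_of(sid, tp),
                    model.predict_volume(store[(sid, tp)]),
                    mode="loo",
                    is_training_entry=(sid, tp) == held_out,
                )
            )

    for rec in md_subjects(cohort).itertuples(index=False):
        for sid, tp in scans_of(rec):
            if (sid, tp) not in store:
                raise KeyError(f"missing preprocessed volume for scan {(sid, tp)}")
            predictions.append(
                Prediction(
                    sid, tp, age_of(sid, tp), full.predict_volume(store[(sid, tp)]), mode="full-model"
                )
            )

    return LOOResult(tuple(predictions), ts, full, n_refits, refit_entries)


@dataclass(frozen=True)
class ModelEvaluation:
    mae: float
    scaled_mae: float
    pearson_r: float
    pearson_p: float
    n: int

    @property
    def df(self) -> int:
        """Degrees of freedom of the correlation test (n - 2)."""
        return self.n - 2


def scaled_mae(mae: float, age_min: float, age_max: float) -> float:
    """MAE divided by the training age range."""
    if age_max <= age_min:
        raise ValueError("age range must be positive")
    return mae / (age_max - age_min)


def evaluate_model(preds: list[Prediction]) -> ModelEvaluation:
    """MAE, scaled MAE, and Pearson r (two-sided t-transform p) of predictions."""
    if len(preds) < 3:
        raise ValueError("need at least 3 predictions to evaluate")
    y = np.array([p.chronological_age for p in preds])
    yhat = np.array([p.predicted_age for p in preds])
    mae = float(np.mean(np.abs(yhat - y)))
    smae = scaled_mae(mae, y.min(), y.max())
    r, p = stats.pearsonr(yhat, y)
    return ModelEvaluation(mae, smae, float(r), float(p), len(preds))
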