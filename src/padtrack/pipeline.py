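"""End-to-end orchestration: simulate -> preprocess -> train/predict ->
brain-PAD -> mixed model -> report, with a reproducibility manifest.

A single global seed fans out to per-stage child seeds through
``numpy.random.SeedSequence([seed, stage_index])``, so any stage can be
re-run in isolation. Stage outputs are written as CSV/JSON under the work
directory and hashed into the manifest; deterministic stages reproduce
identical hashes on re-runs with the same configuration.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .brainage import LOOResult, evaluate_model, loo_predictions
from .brainpad import compute_brainpad, fit_residual_model
from .cohort import Cohort
from .cohort_stats import attrition_report, demographics_table
from .config import RunConfig, SimulationConfig
from .lmm import LMMFit, STAGES, build_long_dataset, fit_trajectory_model, pairwise_contrasts
from .simulate import iter_cohort_volumes, simulate_cohort, simulate_latent_ages
from .volumes import preprocess_volume

STAGE_NAMES = ("simulate", "preprocess", "train_predict", "brainpad", "lmm", "report")


def child_seed(seed: int, stage_index: int) -> int:
    """Derive a per-stage seed (< 2^31) from the global seed."""
    return int(np.random.SeedSequence([int(seed), int(stage_index)]).generate_state(1)[0] % (2**31))


@dataclass(frozen=True)
class RunManifest:
    """Per-stage hashes, seeds and convergence flags of a pipeline run."""

    version: str
    seed: int
    stages: dict
    timestamps: dict

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "version": self.version,
                    "seed": self.seed,
                    "stages": self.stages,
                    "timestamps": self.timestamps,
                },
                indent=2,
                sort_keys=True,
            )
        )


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


@dataclass
class EndToEndResult:
    """In-memory outputs of one full analysis run."""

    cohort: Cohort
    latent: pd.DataFrame
    loo: LOOResult
    evaluation: object
    brainpad: pd.DataFrame
    long_data: pd.DataFrame
    trajectory_fit: LMMFit
    contrasts: dict[str, pd.DataFrame]


def run_analysis(config: RunConfig) -> EndToEndResult:
    """Execute the full chain in memory and return every intermediate."""
    config.validate()
    sim: SimulationConfig = config.simulation.replace(seed=child_seed(config.seed, 0))
    cohort = simulate_cohort(sim)
    latent = simulate_latent_ages(cohort, sim)

    store = {}
    for key, vol in iter_cohort_volumes(cohort, latent, sim):
        store[key] = preprocess_volume(
            vol, config.model.smoothing_fwhm_mm, config.model.mask_threshold
        )

    loo = loo_predictions(cohort, store, config.model)
    refs = loo.reference_predictions()
    evaluation = evaluate_model(refs)
    residual = fit_residual_model(refs, cohort)
    bp = compute_brainpad(list(loo.predictions), residual, cohort)
    long_data = build_long_dataset(bp, cohort)
    fit = fit_trajectory_model(long_data)
    contrasts = {stage: pairwise_contrasts(fit, stage) for stage in STAGES}
    return EndToEndResult(cohort, latent, loo, evaluation, bp, long_data, fit, contrasts)


def run_pipeline(config: RunConfig) -> RunManifest:
    """Run all stages, write outputs under ``config.workdir``, return the manifest."""
    config.validate()
    workdir = Path(config.workdir)
    workdir.mkdir(parents=True, exist_ok=True)
    stages: dict = {}
    timestamps: dict = {}

    def record(stage: str, files: list[Path], **extra) -> None:
        timestamps[stage] = time.time()
        stages[stage] = {
            "files": {f.name: _sha256(f) for f in files},
            "seed": child_seed(config.seed, STAGE_NAMES.index(stage)),
            **extra,
        }

    try:
        result = _run_staged(config, workdir, record)
    except Exception as err:
        # retain partial outputs and flag the failing stage in the manifest
        done = set(stages)
        failed = next((s for s in STAGE_NAMES if s not in done), "unknown")
        manifest = RunManifest(__version__, config.seed, {**stages, "failed_stage": failed}, timestamps)
        manifest.to_json(workdir / "manifest.json")
        raise RuntimeError(f"pipeline failed at stage {failed!r}: {err}") from err

    manifest = RunManifest(__version__, config.seed, stages, timestamps)
    manifest.to_json(workdir / "manifest.json")
    return manifest


def _run_staged(config: RunConfig, workdir: Path, record) -> EndToEndResult:
    sim = config.simulation.replace(seed=child_seed(config.seed, 0))
    cohort = simulate_cohort(sim)
    latent = simulate_latent_ages(cohort, sim)
    cohort_csv = workdir / "cohort.csv"
    latent_csv = workdir / "latent.csv"
    cohort.to_csv(cohort_csv)
    latent.to_csv(latent_csv, index=False)
    record("simulate", [cohort_csv, latent_csv])

    store = {}
    vol_files = []
    for key, vol in iter_cohort_volumes(cohort, latent, sim):
        if config.write_volumes:
            path = workdir / f"{key[0]}_{key[1]}.nii.gz"
            vol.save(path)
            vol_files.append(path)
        store[key] = preprocess_volume(
            vol, config.model.smoothing_fwhm_mm, config.model.mask_threshold
        )
    prep_digest = hashlib.sha256()
    for key in sorted(store):
        prep_digest.update(store[key].values.tobytes())
    record("preprocess", vol_files, feature_digest=prep_digest.hexdigest())

    loo = loo_predictions(cohort, store, config.model)
    refs = loo.reference_predictions()
    evaluation = evaluate_model(refs)
    preds_csv = workdir / "predictions.csv"
    loo.to_frame().to_csv(preds_csv, index=False)
    eval_json = workdir / "evaluation.json"
    eval_json.write_text(json.dumps(dataclasses.asdict(evaluation), indent=2))
    record(
        "train_predict",
        [preds_csv, eval_json],
        pca_k=loo.full_model.pca.k,
        rvr_converged=loo.full_model.rvr.converged,
        n_refits=loo.n_refits,
    )

    residual = fit_residual_model(refs, cohort)
    bp = compute_brainpad(list(loo.predictions), residual, cohort)
    bp_csv = workdir / "brainpad.csv"
    bp.to_csv(bp_csv, index=False)
    res_json = workdir / "residual_model.json"
    residual.to_json(res_json)
    record("brainpad", [bp_csv, res_json])

    long_data = build_long_dataset(bp, cohort)
    fit = fit_trajectory_model(long_data)
    contrasts = {stage: pairwise_contrasts(fit, stage) for stage in STAGES}
    fe_csv = workdir / "lmm_fixed_effects.csv"
    fit.fixed_effects.to_csv(fe_csv, index=False)
    ct_csv = workdir / "contrasts.csv"
    pd.concat(contrasts.values()).to_csv(ct_csv, index=False)
    record("lmm", [fe_csv, ct_csv], converged=fit.converged)

    result = EndToEndResult(cohort, latent, loo, evaluation, bp, long_data, fit, contrasts)
    report = make_report(result)
    report_md = workdir / "report.md"
    report_md.write_text(report)
    files = [report_md]
    if config.make_plot:
        plot_path = workdir / "trajectories.png"
        plot_trajectories(result, plot_path)
        files.append(plot_path)
    record("report", files)
    return result


def make_report(result: EndToEndResult) -> str:
    """Markdown report: cohort table, model evaluation, fixed effects, contrasts."""
    ev = result.evaluation
    lines = ["# Brain-PAD trajectory analysis", ""]
    lines += ["## Cohort", "", demographics_table(result.cohort).to_markdown(index=False), ""]
    att = attrition_report(result.cohort)
    lines += ["### Attrition", ""]
    for g, pct in att.attrition_percent.items():
        lines.append(f"- {g}: {pct:.1f}%")
    lines += ["", att.pairwise.to_markdown(index=False), ""]
    lines += [
        "## Brain-age model evaluation (training-sample LOO)",
        "",
        f"- MAE: {ev.mae:.2f} years",
        f"- scaled MAE (MAE / age range): {ev.scaled_mae:.2f}",
        f"- Pearson r({ev.df}) = {ev.pearson_r:.2f}, p = {ev.pearson_p:.3g}",
        f"- retained PCA components: {result.loo.full_model.pca.k}",
        "",
    ]
    fe = result.trajectory_fit.fixed_effects.copy()
    fe[["beta", "se", "t", "p"]] = fe[["beta", "se", "t", "p"]].round(3)
    lines += ["## Mixed-model fixed effects (z scale)", "", fe.to_markdown(index=False), ""]
    for stage, table in result.contrasts.items():
        t = table.copy()
        num = ["estimate_years", "estimate_z", "se", "t", "p_raw", "p_holm"]
        t[num] = t[num].round(3)
        lines += [f"## Pairwise contrasts: {stage}", "", t.to_markdown(index=False), ""]
    return "\n".join(lines)


def plot_trajectories(result: EndToEndResult, path: str | Path) -> None:
    """Modelled group trajectories of brain-PAD (years scale)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fit = result.trajectory_fit
    terms = list(fit.terms)
    sd = fit.outcome_sd_years

    def effect(name: str) -> float:
        return fit.beta[terms.index(name)] * sd if name in terms else 0.0

    fig, ax = plt.subplots(figsize=(5, 4))
    for group in ("C-well", "HR-well", "HR-MD"):
        g = 0.0 if group == "C-well" else effect(group)
        gi = 0.0 if group == "C-well" else effect(f"t2:{group}")
        # displayed relative to C-well: its intercept and timepoint effect removed
        ax.plot([1, 2], [g, g + gi], marker="o", label=group)
    ax.set_xticks([1, 2], ["timepoint 1", "timepoint 2"])
    ax.set_ylabel("brain-PAD relative to C-well (years)")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
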