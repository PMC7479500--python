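"""Synthetic cohort and grey-matter volume generator.

This module produces data with the statistical structure the downstream
analysis assumes, so the whole chain is testable without access to any
MRI data: a three-group familial-risk cohort with exact per-group baseline
and follow-up counts, family nesting within the high-risk groups, latent
"biological brain age" values with group-specific trajectory offsets, and
grey-matter density volumes in which that latent age is affinely encoded
by smooth spatial patterns.

Every draw is a pure function of ``(config, config.seed)``: each stage
uses its own child generator derived from the seed, and per-scan render
noise is keyed by subject and timepoint so single volumes can be
regenerated in isolation.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .cohort import COLUMNS, Cohort
from .config import GROUPS, ConfigurationError, SimulationConfig, VolumeParams
from .volumes import FWHM_TO_SIGMA, GreyMatterVolume

_GROUP_CODE = {"C-well": "C", "HR-well": "H", "HR-MD": "M", "C-MD": "D"}

# Stage codes for child generators derived from the config seed.
_STAGE_COHORT = 0
_STAGE_LATENT = 1
_STAGE_SPATIAL = 2
_STAGE_RENDER = 3


def _rng(seed: int, *path: int) -> np.random.Generator:
    return np.random.default_rng([int(seed)] + [int(p) for p in path])


def _scan_key(subject_id: str, timepoint: str) -> int:
    return zlib.crc32(f"{subject_id}|{timepoint}".encode()) & 0x7FFFFFFF


def simulate_cohort(config: SimulationConfig) -> Cohort:
    """Draw a participant table with exact group and follow-up counts.

    Baseline ages are uniform on ``age_range_baseline``; follow-up
    intervals are Normal(mean, sd) truncated to be positive. Attrition is
    assigned by sampling exactly ``followup_counts[g]`` subjects per group
    without replacement, so the printed ns are reproduced deterministically.
    High-risk participants join an existing high-risk family with
    probability ``family_share_prob``; controls are singletons.
    """
    config.validate()
    rng = _rng(config.seed, _STAGE_COHORT)
    hrsd = config.hrsd_params

    rows = []
    hr_families: list[str] = []
    n_families = 0
    for gi, group in enumerate(GROUPS):
        code = _GROUP_CODE[group]
        n = int(config.group_sizes[gi])
        n_fu = int(config.followup_counts[gi])
        followup_ids = set(rng.choice(n, size=n_fu, replace=False).tolist())
        for i in range(n):
            subject_id = f"{code}{i + 1:03d}"
            if group == "C-well":
                n_families += 1
                family_id = f"F{n_families:03d}"
            else:
                if hr_families and rng.random() < config.family_share_prob:
                    family_id = hr_families[rng.integers(len(hr_families))]
                else:
                    n_families += 1
                    family_id = f"F{n_families:03d}"
                    hr_families.append(family_id)
            sex = int(rng.random() < config.female_prob)
            age_t1 = rng.uniform(*config.age_range_baseline)
            has_followup = i in followup_ids
            interval = rng.normal(config.followup_interval_mean, config.followup_interval_sd)
            while interval <= 0:  # truncate the interval at zero
                interval = rng.normal(config.followup_interval_mean, config.followup_interval_sd)
            age_t2 = age_t1 + interval if has_followup else np.nan
            hrsd_t1 = _nbinom(rng, hrsd.means_t1[gi], hrsd.dispersion)
            hrsd_t2 = _nbinom(rng, hrsd.means_t2[gi], hrsd.dispersion) if has_followup else np.nan
            rows.append(
                (subject_id, family_id, group, sex, age_t1, age_t2, has_followup, hrsd_t1, hrsd_t2)
            )
    return Cohort(pd.DataFrame(rows, columns=COLUMNS))


def _nbinom(rng: np.random.Generator, mean: float, dispersion: float) -> int:
    if mean <= 0:
        return 0
    p = dispersion / (dispersion + mean)
    return int(rng.negative_binomial(dispersion, p))


def simulate_latent_ages(cohort: Cohort, config: SimulationConfig) -> pd.DataFrame:
    """Latent biological brain age ``b`` per scan.

    ``b = age + baseline_offset[g] + 1{t2} * trajectory_increment[g]
    + a_family + u_subject + eps_scan`` with the subject effect drawn once
    per subject. Returns one row per scan with columns
    ``subject_id, group, timepoint, age, b``.
    """
    config.validate()
    rng = _rng(config.seed, _STAGE_LATENT)
    gi = {g: i for i, g in enumerate(GROUPS)}
    fam_effects: dict[str, float] = {}
    rows = []
    for rec in cohort.table.itertuples(index=False):
        g = gi[rec.group]
        if rec.family_id not in fam_effects:
            fam_effects[rec.family_id] = (
                rng.normal(0.0, config.family_sd) if config.family_sd > 0 else 0.0
            )
        u = rng.normal(0.0, config.subject_sd) if config.subject_sd > 0 else 0.0
        a = fam_effects[rec.family_id]
        for tp, age in (("t1", rec.age_t1), ("t2", rec.age_t2)):
            if tp == "t2" and not rec.has_followup:
                continue
            eps = rng.normal(0.0, config.noise_sd) if config.noise_sd > 0 else 0.0
            delta = config.baseline_offset[g] + (tp == "t2") * config.trajectory_increment[g]
            rows.append((rec.subject_id, rec.group, tp, float(age), float(age) + delta + a + u + eps))
    return pd.DataFrame(rows, columns=["subject_id", "group", "timepoint", "age", "b"])


def latent_to_brainpad_records(latent: pd.DataFrame) -> pd.DataFrame:
    """Treat the latent ``b`` as a noise-free brain-age prediction.

    Convenience for model-stage-only simulation studies: brain-PAD is
    ``b - age``, i.e. the generator's ground truth, bypassing the imaging
    decode entirely.
    """
    out = latent.rename(columns={"age": "chronological_age", "b": "predicted_age"}).copy()
    out["brain_pad"] = out["predicted_age"] - out["chronological_age"]
    return out[["subject_id", "timepoint", "chronological_age", "predicted_age", "brain_pad"]]


@dataclass(frozen=True)
class SpatialModel:
    """Fixed spatial machinery of the volume generator (one per seed).

    ``template`` is a smooth positive map on an ellipsoidal support;
    ``patterns`` are P smooth unit-RMS fields on the same support and
    ``weights`` their age slopes (density units per year), so the rendered
    volume depends affinely on the latent brain age before clipping.
    """

    template: np.ndarray
    patterns: np.ndarray  # (P, nx, ny, nz)
    weights: np.ndarray  # (P,)
    support: np.ndarray  # bool grid
    params: VolumeParams


def make_spatial_model(params: VolumeParams, seed: int) -> SpatialModel:
    params.validate()
    rng = _rng(seed, _STAGE_SPATIAL)
    shape = tuple(int(s) for s in params.shape)
    axes = [np.linspace(-1.0, 1.0, s) / 0.9 for s in shape]
    rho2 = (
        axes[0][:, None, None] ** 2 + axes[1][None, :, None] ** 2 + axes[2][None, None, :] ** 2
    )
    support = rho2 <= 1.0
    if not support.any():
        raise ConfigurationError("ellipsoid support is empty; grid too small")
    template = params.template_peak * np.clip(1.0 - rho2, 0.0, None)

    sigma = params.pattern_fwhm_mm * FWHM_TO_SIGMA / params.voxel_size_mm
    patterns = np.empty((params.n_patterns,) + shape)
    for p in range(params.n_patterns):
        raw = gaussian_filter(rng.standard_normal(shape), sigma=sigma)
        raw = raw * support
        rms = np.sqrt(np.mean(raw[support] ** 2))
        patterns[p] = raw / rms
    signs = rng.choice([-1.0, 1.0], size=params.n_patterns)
    weights = params.age_slope_scale * signs * rng.uniform(0.5, 1.5, size=params.n_patterns)
    return SpatialModel(template, patterns, weights, support, params)


def render_volume(
    subject_id: str,
    timepoint: str,
    b: float,
    config: SimulationConfig,
    model: SpatialModel | None = None,
    clip: bool = True,
) -> GreyMatterVolume:
    """Render one grey-matter volume carrying latent brain age ``b``.

    ``V(x) = template(x) + sum_p s_p(x) (w_p (b - b_ref) + eta_p) + nu(x)``
    restricted to the ellipsoid support, with values clipped at zero unless
    ``clip=False`` (used to verify the affine construction). Component and
    voxel noise are keyed by ``(config.seed, subject_id, timepoint)``.
    """
    if not np.isfinite(b):
        raise ValueError(f"latent brain age must be finite, got {b}")
    params = config.volume_params
    if model is None:
        model = make_spatial_model(params, config.seed)
    rng = _rng(config.seed, _STAGE_RENDER, _scan_key(subject_id, timepoint))
    amp = model.weights * (b - params.reference_age)
    if params.component_noise_sd > 0:
        amp = amp + rng.normal(0.0, params.component_noise_sd, size=amp.shape)
    values = model.template + np.tensordot(amp, model.patterns, axes=(0, 0))
    if params.voxel_noise_sd > 0:
        values = values + rng.normal(0.0, params.voxel_noise_sd, size=values.shape)
    if clip:
        values = np.clip(values, 0.0, None)
    values = values * model.support
    return GreyMatterVolume(values, params.voxel_size_mm, subject_id, timepoint)


def iter_cohort_volumes(cohort: Cohort, latent: pd.DataFrame, config: SimulationConfig):
    """Yield ``((subject_id, timepoint), GreyMatterVolume)`` for every scan.

    Builds the spatial model once; volumes stream so callers can
    preprocess and discard them without holding the raw cohort in memory.
    """
    model = make_spatial_model(config.volume_params, config.seed)
    b_map = {(r.subject_id, r.timepoint): r.b for r in latent.itertuples(index=False)}
    for sid, tp in cohort.scans():
        yield (sid, tp), render_volume(sid, tp, b_map[(sid, tp)], config, model=model)
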