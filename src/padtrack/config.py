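"""Configuration objects for the simulation and pipeline.

The defaults encode the study design the analysis assumes: a three-group
familial-risk cohort (controls who remained well, high-risk who remained
well, high-risk who developed a mood disorder), two scanning timepoints
roughly two years apart, differential attrition, and group-specific
brain-aging trajectory offsets in years.
"""

from __future__ import annotations

import dataclasses
import tomllib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

#: Canonical group labels, in fixed order (reference group first).
GROUPS = ("C-well", "HR-well", "HR-MD")

#: Optional fourth group supported by the schema (controls who became ill).
GROUP_C_MD = "C-MD"

#: Timepoint labels.
TIMEPOINTS = ("t1", "t2")


class ConfigurationError(ValueError):
    """Raised when a configuration violates its invariants."""


@dataclass(frozen=True)
class VolumeParams:
    """Parameters of the synthetic grey-matter volume generator.

    The generator writes a smooth positive "grey-matter density" template
    supported on an ellipsoidal brain, plus ``n_patterns`` fixed smooth
    spatial patterns whose amplitudes depend affinely on the latent brain
    age ``b``, so that linear decoding of ``b`` from voxels is possible.

    Attributes
    ----------
    shape:
        Input grid shape (before 2x downsampling).
    voxel_size_mm:
        Isotropic input voxel size; 1.5 mm doubles to the 3 mm analysis
        resolution.
    n_patterns:
        Number of age-coding spatial patterns P.
    pattern_fwhm_mm:
        Smoothness (FWHM) of the random spatial patterns.
    template_peak:
        Peak density of the ellipsoidal template (arbitrary density units).
    age_slope_scale:
        Scale of per-pattern age slopes w_p (density units per year).
    component_noise_sd:
        SD of the per-pattern amplitude noise eta_p (density units).
    voxel_noise_sd:
        SD of the i.i.d. voxel noise nu(x) (density units).
    reference_age:
        Centre b-bar of the affine age coding, in years.
    """

    shape: tuple[int, int, int] = (48, 56, 48)
    voxel_size_mm: float = 1.5
    n_patterns: int = 8
    pattern_fwhm_mm: float = 9.0
    template_peak: float = 0.7
    age_slope_scale: float = 0.02
    component_noise_sd: float = 0.011
    voxel_noise_sd: float = 0.01
    reference_age: float = 22.4

    def validate(self) -> None:
        if any(int(s) <= 0 for s in self.shape) or len(self.shape) != 3:
            raise ConfigurationError(f"volume grid shape must be 3 positive ints, got {self.shape}")
        if self.voxel_size_mm <= 0:
            raise ConfigurationError("voxel_size_mm must be > 0")
        if self.n_patterns < 1:
            raise ConfigurationError("n_patterns must be >= 1")
        for name in ("component_noise_sd", "voxel_noise_sd"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")


@dataclass(frozen=True)
class HRSDParams:
    """Negative-binomial parameters for Hamilton depression scores.

    ``means_t1``/``means_t2`` are per-group expected scores in the order of
    :data:`GROUPS`; ``dispersion`` is the shared NB size parameter (smaller
    means heavier tail). Defaults put the HR-MD group stochastically higher
    at both timepoints, rising at follow-up, with the well groups near zero.
    """

    means_t1: tuple[float, float, float] = (0.8, 1.0, 3.8)
    means_t2: tuple[float, float, float] = (0.8, 0.9, 6.0)
    dispersion: float = 0.9

    def validate(self) -> None:
        if any(m < 0 for m in self.means_t1 + self.means_t2):
            raise ConfigurationError("HRSD means must be >= 0")
        if self.dispersion <= 0:
            raise ConfigurationError("HRSD dispersion must be > 0")


@dataclass(frozen=True)
class SimulationConfig:
    """Full description of a simulated cohort.

    Group-wise tuples are ordered (C-well, HR-well, HR-MD). The latent
    biological brain age of a scan is

        b = age + baseline_offset[g] + 1{t2} * trajectory_increment[g]
            + u_subject + eps_scan,

    with ``u ~ N(0, subject_sd^2)`` drawn once per subject and
    ``eps ~ N(0, noise_sd^2)`` per scan. The default offsets are the
    years-scale group effects the design targets: an intermediate
    deceleration for HR-well and the largest deceleration (-0.70 y over the
    follow-up interval) for HR-MD.
    """

    group_sizes: tuple[int, int, int] = (93, 74, 35)
    followup_counts: tuple[int, int, int] = (46, 47, 31)
    age_range_baseline: tuple[float, float] = (15.0, 28.0)
    followup_interval_mean: float = 2.0
    followup_interval_sd: float = 0.25
    family_share_prob: float = 0.3
    female_prob: float = 0.53
    baseline_offset: tuple[float, float, float] = (0.0, -0.42, -0.05)
    trajectory_increment: tuple[float, float, float] = (0.0, -0.28, -0.70)
    subject_sd: float = 1.00
    noise_sd: float = 0.50
    family_sd: float = 0.0
    hrsd_params: HRSDParams = field(default_factory=HRSDParams)
    volume_params: VolumeParams = field(default_factory=VolumeParams)
    seed: int = 0

    def validate(self) -> None:
        if len(self.group_sizes) != 3 or any(int(n) <= 0 for n in self.group_sizes):
            raise ConfigurationError(f"group_sizes must be 3 positive ints, got {self.group_sizes}")
        if len(self.followup_counts) != 3 or any(int(n) < 0 for n in self.followup_counts):
            raise ConfigurationError("followup_counts must be 3 non-negative ints")
        if any(f > g for f, g in zip(self.followup_counts, self.group_sizes)):
            raise ConfigurationError(
                f"followup_counts {self.followup_counts} exceed group_sizes {self.group_sizes}"
            )
        lo, hi = self.age_range_baseline
        if not lo < hi:
            raise ConfigurationError("age_range_baseline must be an increasing interval")
        if self.followup_interval_mean <= 0:
            raise ConfigurationError("followup_interval_mean must be > 0")
        for name in ("followup_interval_sd", "subject_sd", "noise_sd", "family_sd"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        for name in ("family_share_prob", "female_prob"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ConfigurationError(f"{name} must lie in [0, 1]")
        self.hrsd_params.validate()
        self.volume_params.validate()

    def replace(self, **kwargs) -> "SimulationConfig":
        """Return a copy with the given fields replaced (and re-validated)."""
        cfg = dataclasses.replace(self, **kwargs)
        cfg.validate()
        return cfg


@dataclass(frozen=True)
class ModelOptions:
    """Options for the brain-age prediction stage."""

    smoothing_fwhm_mm: float = 8.0
    mask_threshold: float = 0.01
    pca_criterion: str = "kaiser"  # or "mean-eigenvalue"
    rvr_prune_threshold: float = 1e9
    rvr_tol: float = 1e-3
    rvr_max_iter: int = 1000

    def validate(self) -> None:
        if self.smoothing_fwhm_mm <= 0:
            raise ConfigurationError("smoothing_fwhm_mm must be > 0")
        if self.pca_criterion not in ("kaiser", "mean-eigenvalue"):
            raise ConfigurationError(f"unknown pca_criterion {self.pca_criterion!r}")


@dataclass(frozen=True)
class RunConfig:
    """End-to-end pipeline configuration."""

    workdir: Path = Path("padtrack_run")
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    model: ModelOptions = field(default_factory=ModelOptions)
    seed: int = 0
    write_volumes: bool = False
    make_plot: bool = False

    def validate(self) -> None:
        self.simulation.validate()
        self.model.validate()


def _tuple3(value: Sequence, cast=float) -> tuple:
    out = tuple(cast(v) for v in value)
    if len(out) != 3:
        raise ConfigurationError(f"expected 3 values, got {value!r}")
    return out


def simulation_config_from_dict(data: dict) -> SimulationConfig:
    data = dict(data)
    for key, cast in (
        ("group_sizes", int),
        ("followup_counts", int),
        ("baseline_offset", float),
        ("trajectory_increment", float),
    ):
        if key in data:
            data[key] = _tuple3(data[key], cast)
    if "age_range_baseline" in data:
        lo, hi = data["age_range_baseline"]
        data["age_range_baseline"] = (float(lo), float(hi))
    if "hrsd_params" in data:
        hp = dict(data["hrsd_params"])
        for key in ("means_t1", "means_t2"):
            if key in hp:
                hp[key] = _tuple3(hp[key])
        data["hrsd_params"] = HRSDParams(**hp)
    if "volume_params" in data:
        vp = dict(data["volume_params"])
        if "shape" in vp:
            vp["shape"] = _tuple3(vp["shape"], int)
        data["volume_params"] = VolumeParams(**vp)
    cfg = SimulationConfig(**data)
    cfg.validate()
    return cfg


def load_run_config(path: str | Path) -> RunConfig:
    """Read a :class:`RunConfig` from a TOML file."""
    with open(path, "rb") as fh:
        raw = tomllib.load(fh)
    sim = simulation_config_from_dict(raw.get("simulation", {}))
    model = ModelOptions(**raw.get("model", {}))
    cfg = RunConfig(
        workdir=Path(raw.get("workdir", "padtrack_run")),
        simulation=sim,
        model=model,
        seed=int(raw.get("seed", sim.seed)),
        write_volumes=bool(raw.get("write_volumes", False)),
        make_plot=bool(raw.get("make_plot", False)),
    )
    cfg.validate()
    return cfg
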