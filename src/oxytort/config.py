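"""Pipeline configuration.

Every tunable constant of the analysis lives here as a named, documented
field: the measurement annuli (in multiples of the optic-nerve-head radius),
the 25 µm caliber cutoff, the 5 px profile spacing, the centerline-spline
regularization 3e-5, the SO2 calibration line, and the forward-model render
parameters.  Configs round-trip losslessly through YAML.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .errors import ConfigError


@dataclass
class CalibrationParams:
    """Linear SO2 calibration and oxygen-carrying constants.

    SO2 (%) is obtained from the optical density ratio (ODR) as
    ``so2 = a + b * odr``.  The coefficients are instrument/calibration
    specific; the defaults below define the package's reference calibration,
    chosen so that the physiological SO2 range (roughly 40-100 %) maps onto
    optical densities that a dark-vessel forward model can render.

    o2max is the oxygen-binding capacity of hemoglobin (mL O2 per g HgB);
    hgb_per_hct converts hematocrit (%) to hemoglobin concentration (g/dL)
    via the standard one-third clinical rule.
    """

    a: float = 120.0          # percent (intercept)
    b: float = -50.0          # percent per unit ODR (slope)
    od_mode: str = "ratio"    # "ratio" (inside/outside) or "log" (log10 outside/inside)
    o2max: float = 1.34       # mL O2 per g hemoglobin
    hgb_per_hct: float = 1.0 / 3.0  # g/dL per HCT percent

    def __post_init__(self) -> None:
        if self.b == 0:
            raise ConfigError("calibration slope b must be nonzero")
        if self.o2max <= 0:
            raise ConfigError("o2max must be positive")
        if self.od_mode not in ("ratio", "log"):
            raise ConfigError(f"od_mode must be 'ratio' or 'log', got {self.od_mode!r}")

    def odr_from_so2(self, so2: float) -> float:
        """Invert the calibration line (used by the forward model)."""
        return (so2 - self.a) / self.b


@dataclass
class RenderConfig:
    """Geometry and photometry of the synthetic fundus renderer."""

    image_size: tuple[int, int] = (576, 576)   # (height, width) px
    onh_center: tuple[float, float] = (288.0, 288.0)  # (x, y) px
    onh_radius: float = 55.0                   # px
    um_per_px: float = 8.0                     # µm per pixel
    background: float = 0.55                   # retinal background intensity, [0, 1]
    onh_intensity: float = 0.90                # optic disc intensity, [0, 1]
    od532_base: float = 0.60                   # inside/outside intensity ratio at 532 nm
    noise_sd: float = 0.0                      # additive Gaussian noise sd, intensity units
    seed: int = 0

    def __post_init__(self) -> None:
        h, w = self.image_size
        if self.onh_radius <= 0:
            raise ConfigError("onh_radius must be positive")
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be >= 0")
        cx, cy = self.onh_center
        r5 = 5.0 * self.onh_radius
        if cx - r5 < 0 or cy - r5 < 0 or cx + r5 > w or cy + r5 > h:
            raise ConfigError("5x onh_radius must fit inside the image frame")
        if not (0 < self.background <= 1 and 0 < self.onh_intensity <= 1):
            raise ConfigError("intensities must lie in (0, 1]")
        if not (0 < self.od532_base < 1):
            raise ConfigError("od532_base must lie in (0, 1)")


@dataclass
class OximetryConfig:
    """Oximetry stage: vessel detection and profile photometry in the 1-2
    ONH-radius circumpapillary annulus."""

    annulus: tuple[float, float] = (1.0, 2.0)  # inner/outer ONH-radius factors
    profile_spacing: float = 5.0               # px between perpendicular profiles
    profile_half_width: float = 34.0           # px, half extent of each profile
                                               # (must exceed ~2.6x the widest expected FWHM
                                               # so the flanking background windows fit)
    min_diameter_um: float = 25.0              # caliber exclusion threshold
    frangi_sigmas: tuple[float, ...] = (1.0, 1.5, 2.0, 3.0, 4.0, 5.0)
    frangi_gamma: float = 0.01                 # fixed Hessian-norm scale (keeps the
                                               # response comparable across structures)
    vesselness_threshold: float = 0.08         # absolute threshold on vesselness
    min_chain_px: float = 20.0                 # minimum centerline length
    min_profiles: int = 3                      # usable profiles per segment
    min_dip_depth: float = 0.02                # minimum profile dip (intensity units)


@dataclass
class TortuosityConfig:
    """Tortuosity stage: centerlines and VTI/VII in the 1.5-5 ONH-radius
    annulus, measured on the 532 nm image."""

    annulus: tuple[float, float] = (1.5, 5.0)
    spline_regularization: float = 3e-5        # penalty weight on unit arclength domain
    resample_step: float = 1.0                 # px between resampled centerline points
    min_chain_px: float = 20.0
    min_diameter_um: float = 25.0
    # dead zones sit above the skeleton-quantization noise floor of
    # image-derived centerlines but far below the curvature/slope of any
    # real undulation; analytic centerlines can use much tighter values
    kappa_eps: float = 5e-3                    # 1/px; |kappa| below this counts as zero
    deriv_eps: float = 2e-2                    # dead zone for dy/ds at critical points
    endpoint_buffer: int = 5                   # samples ignored at each end for VII
    sdtheta_mode: str = "angles"               # "angles" (chord-frame) or "diffs"
    frangi_sigmas: tuple[float, ...] = (1.0, 1.5, 2.0, 3.0, 4.0, 5.0)
    frangi_gamma: float = 0.01
    vesselness_threshold: float = 0.08


@dataclass
class StatsConfig:
    """Cohort statistics: outlier rule, entropy binning, model options."""

    outlier_n_sd: float = 3.0       # mean +/- n*SD band per diagnosis x vessel-type stratum
    outlier_min_rows: int = 5       # strata smaller than this are left untouched
    entropy_bins: int | None = None  # None -> ceil(sqrt(n)) equal-width bins
    reml: bool = True


@dataclass
class CohortEffects:
    """Group-level effects imposed on a simulated cohort.

    o2_vii_slope is the change in vascular O2 content (mL O2/dL) per
    additional inflection point; vii_shift is the extra mean vessel
    inflection count in the disease group; scr_so2_deficit subtracts SO2
    percentage points from every disease-group vessel on top of the
    anemia-driven O2 content reduction that low hematocrit already causes.
    """

    o2_vii_slope: float = -0.5
    vii_shift: float = 2.0
    scr_so2_deficit: float = 0.0


@dataclass
class CohortConfig:
    """Synthetic cohort composition (defaults mirror the study conditions:
    12 controls + 12 sickle-cell-retinopathy subjects, both eyes)."""

    n_nc: int = 12
    n_scr: int = 12
    vessels_per_eye: int = 8        # alternating arteries/veins crossing both annuli
    include_capillary: bool = True  # add one sub-25 µm vessel per eye
    effects: CohortEffects = field(default_factory=CohortEffects)
    # per-group covariate distributions (mean, sd)
    age_nc: tuple[float, float] = (46.0, 4.0)
    age_scr: tuple[float, float] = (41.0, 15.0)
    hct_nc: tuple[float, float] = (42.0, 3.0)
    hct_scr: tuple[float, float] = (27.0, 3.0)
    map_nc: tuple[float, float] = (93.0, 11.0)
    map_scr: tuple[float, float] = (82.0, 9.0)
    pulse_pressure: tuple[float, float] = (42.0, 8.0)
    artery_diameter_um: tuple[float, float] = (60.0, 6.0)
    vein_diameter_um: tuple[float, float] = (80.0, 8.0)
    artery_so2: tuple[float, float] = (93.0, 2.0)
    vein_so2: tuple[float, float] = (63.0, 4.0)
    undulation_amplitude_px: tuple[float, float] = (2.5, 0.4)


@dataclass
class PipelineConfig:
    """Top-level configuration for the simulate -> oximetry -> tortuosity ->
    stats pipeline."""

    seed: int = 1
    render: RenderConfig = field(default_factory=RenderConfig)
    calibration: CalibrationParams = field(default_factory=CalibrationParams)
    oximetry: OximetryConfig = field(default_factory=OximetryConfig)
    tortuosity: TortuosityConfig = field(default_factory=TortuosityConfig)
    stats: StatsConfig = field(default_factory=StatsConfig)
    cohort: CohortConfig = field(default_factory=CohortConfig)


_SECTIONS = {
    "render": RenderConfig,
    "calibration": CalibrationParams,
    "oximetry": OximetryConfig,
    "tortuosity": TortuosityConfig,
    "stats": StatsConfig,
    "cohort": CohortConfig,
}

# Sections that must be written out explicitly in a run configuration;
# the calibration line is instrument-specific and must never be implicit.
_REQUIRED_SECTIONS = ("calibration",)


def _build(cls, data: dict):
    if not isinstance(data, dict):
        raise ConfigError(f"section for {cls.__name__} must be a mapping")
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ConfigError(f"unknown keys for {cls.__name__}: {sorted(unknown)}")
    kwargs = dict(data)
    if cls is CohortConfig and "effects" in kwargs:
        kwargs["effects"] = _build(CohortEffects, kwargs["effects"])
    # YAML has no tuple type; restore tuples where the dataclass default uses them
    for f in dataclasses.fields(cls):
        if f.name in kwargs and isinstance(kwargs[f.name], list):
            kwargs[f.name] = tuple(kwargs[f.name])
    return cls(**kwargs)


def config_from_dict(data: dict) -> PipelineConfig:
    """Build a :class:`PipelineConfig` from a plain mapping, validating
    eagerly so that a bad config fails before any compute."""
    if not isinstance(data, dict):
        raise ConfigError("configuration root must be a mapping")
    unknown = set(data) - set(_SECTIONS) - {"seed"}
    if unknown:
        raise ConfigError(f"unknown configuration sections: {sorted(unknown)}")
    for name in _REQUIRED_SECTIONS:
        if name not in data:
            raise ConfigError(f"missing required configuration section: {name!r}")
    kwargs = {"seed": int(data.get("seed", 1))}
    for name, cls in _SECTIONS.items():
        if name in data:
            kwargs[name] = _build(cls, data[name])
    return PipelineConfig(**kwargs)


def config_to_dict(cfg: PipelineConfig) -> dict:
    """Plain-dict form (tuples become lists; lossless on round trip)."""

    def _clean(obj):
        if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
            return {f.name: _clean(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
        if isinstance(obj, tuple):
            return [_clean(v) for v in obj]
        return obj

    return _clean(cfg)


def load_config(path: str | Path) -> PipelineConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if data is None:
        raise ConfigError(f"empty configuration file: {path}")
    return config_from_dict(data)


def save_config(cfg: PipelineConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config_to_dict(cfg), fh, sort_keys=True)


def config_hash(cfg: PipelineConfig) -> str:
    """Stable sha256 of the canonical JSON form (for run manifests)."""
    payload = json.dumps(config_to_dict(cfg), sort_keys=True).encode()
    return hashlib.sha256(payload).hexdigest()
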