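"""Dual-wavelength retinal vessel oximetry.

Vessels are segmented in the circumpapillary annulus spanning 1-2 optic
nerve head (ONH) radii.  For each vessel segment, intensity profiles are
extracted perpendicular to the centerline every 5 px; the vessel boundary
is the full width at half maximum (FWHM) of the profile dip.  Per
wavelength, the optical density (OD) is the average ratio of intensity
inside the vessel to intensity just outside it; the oxygen-sensitive ratio
ODR = OD633 / OD532 is converted to hemoglobin oxygen saturation through a
linear calibration, SO2 = a + b * ODR, and finally to oxygen content::

    O2 content = O2max * HgB * SO2 / 100      [mL O2 / dL]

with HgB (g/dL) derived from hematocrit and O2max the oxygen-binding
capacity of hemoglobin (default 1.34 mL O2/g).

The 532 nm wavelength is near-isosbestic (absorption independent of
oxygenation), 633 nm is oxygen sensitive.  Because the inside/outside
ratio definition of OD makes a fully transmissive vessel read OD = 1 (the
inverse of the conventional log sense), a log10 OD mode is also provided;
the calibration coefficients must match whichever mode is configured.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import map_coordinates
from scipy.special import erf

from .centerline import VesselCenterline, extract_centerlines, smooth_centerline
from .config import CalibrationParams, PipelineConfig
from .errors import (
    InvalidMeasurementError,
    InvalidSubjectError,
    NoProfilesError,
    NoVesselError,
)
from .segmentation import annulus_mask, label_components, segment_vessels

__all__ = [
    "FundusImagePair",
    "IntensityProfile",
    "FWHM_PER_SIGMA",
    "GAUSSIAN_FWHM_MEAN",
    "extract_profiles",
    "resample_profile",
    "fwhm_bounds",
    "optical_density",
    "so2_from_odr",
    "hgb_from_hct",
    "o2_content",
    "analyze_pair",
    "segment_vessels",
    "annulus_mask",
]

log = logging.getLogger(__name__)

#: FWHM of a Gaussian in units of its sigma.
FWHM_PER_SIGMA = 2.0 * math.sqrt(2.0 * math.log(2.0))

#: Mean of exp(-r^2 / 2 sigma^2) over the FWHM interval [-FWHM/2, FWHM/2].
#: Used by the forward model to set a Gaussian dip depth such that the mean
#: intensity inside the FWHM equals a prescribed inside/outside ratio.
GAUSSIAN_FWHM_MEAN = float(
    math.sqrt(2.0 * math.pi) * erf(math.sqrt(math.log(2.0))) / FWHM_PER_SIGMA
)


@dataclass
class FundusImagePair:
    """Co-registered 532/633 nm fundus images with ONH geometry."""

    image_532: np.ndarray
    image_633: np.ndarray
    onh_center: tuple[float, float]  # (x, y) px
    onh_radius: float                # px
    um_per_px: float

    def __post_init__(self) -> None:
        a = np.asarray(self.image_532, float)
        b = np.asarray(self.image_633, float)
        if a.shape != b.shape:
            raise InvalidMeasurementError("image shapes must match")
        if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
            raise InvalidMeasurementError("image intensities must be finite")
        if a.min() < 0 or b.min() < 0:
            raise InvalidMeasurementError("image intensities must be >= 0")
        if self.onh_radius <= 0:
            raise InvalidMeasurementError("onh_radius must be positive")
        self.image_532, self.image_633 = a, b


@dataclass
class IntensityProfile:
    """Intensity samples along a line perpendicular to the centerline.

    ``offsets`` (px, odd count, centered on 0) run along the profile's
    normal direction; ``coords`` holds the sampled (x, y) image positions.
    """

    offsets: np.ndarray
    values: np.ndarray
    center: np.ndarray            # (x, y) centerline point
    normal: np.ndarray            # unit normal (x, y)
    coords: np.ndarray = field(repr=False)  # (2, n) sampled (x, y)


def extract_profiles(
    cl: VesselCenterline,
    image: np.ndarray,
    spacing: float = 5.0,
    half_width: float = 34.0,
) -> list[IntensityProfile]:
    """Perpendicular intensity profiles every ``spacing`` px of arclength.

    Profiles are exactly perpendicular to the local tangent (the normal is
    rotated 90 degrees from the spline tangent).  Profiles whose support
    would leave the image frame are dropped with a warning.
    """
    if len(cl.points) < 2:
        raise NoProfilesError("centerline too short for profile extraction")
    h, w = image.shape
    n_steps = int(math.floor(cl.la / spacing)) + 1
    s_vals = cl.s[0] + spacing * np.arange(n_steps)
    theta = np.interp(s_vals, cl.s, np.radians(cl.theta_deg))
    hw = int(math.floor(half_width))
    offsets = np.arange(-hw, hw + 1, dtype=float)  # odd count, centered

    profiles: list[IntensityProfile] = []
    n_dropped = 0
    for s, th in zip(s_vals, theta):
        center = cl.point_at(s)
        normal = np.array([-math.sin(th), math.cos(th)])
        xs = center[0] + offsets * normal[0]
        ys = center[1] + offsets * normal[1]
        if xs.min() < 0 or ys.min() < 0 or xs.max() > w - 1 or ys.max() > h - 1:
            n_dropped += 1
            continue
        values = map_coordinates(image, np.vstack([ys, xs]), order=1)
        profiles.append(
            IntensityProfile(
                offsets=offsets.copy(), values=values, center=center,
                normal=normal, coords=np.vstack([xs, ys]),
            )
        )
    if n_dropped:
        log.warning("extract_profiles: dropped %d profiles leaving the frame", n_dropped)
    if not profiles:
        raise NoProfilesError("no profile lies fully inside the frame")
    return profiles


def resample_profile(profile: IntensityProfile, image: np.ndarray) -> IntensityProfile:
    """Sample a second image at exactly the same profile geometry."""
    values = map_coordinates(image, profile.coords[::-1], order=1)
    return IntensityProfile(
        offsets=profile.offsets, values=values, center=profile.center,
        normal=profile.normal, coords=profile.coords,
    )


def fwhm_bounds(profile: IntensityProfile, min_depth: float = 0.02) -> tuple[float, float]:
    """Sub-pixel FWHM edges of the vessel dip in one profile.

    The background level is estimated from the outer quarter of samples on
    each side; the half level is background - depth/2, and the two edges are
    the linearly interpolated crossings of that level flanking the interior
    minimum.  A profile with no dip deeper than ``min_depth`` raises
    :class:`NoVesselError`.
    """
    o, v = profile.offsets, profile.values
    n = len(v)
    if n < 7:
        raise NoVesselError("profile too short")
    q = max(n // 4, 2)
    bg = 0.5 * (float(np.median(v[:q])) + float(np.median(v[-q:])))
    interior = slice(2, n - 2)
    imin = int(np.argmin(v[interior])) + 2
    depth = bg - v[imin]
    if depth < max(min_depth, 1e-9):
        raise NoVesselError(f"no dip below half level (depth {depth:.4g})")
    half = bg - 0.5 * depth

    def _cross(j_inner: int, direction: int) -> float:
        j = j_inner
        while 0 <= j + direction < n:
            k = j + direction
            if v[k] >= half:
                # linear interpolation between (o[j], v[j]) and (o[k], v[k])
                frac = (half - v[j]) / (v[k] - v[j])
                return float(o[j] + frac * (o[k] - o[j]))
            j = k
        raise NoVesselError("half level not reached on one side")

    left = _cross(imin, -1)
    right = _cross(imin, +1)
    return left, right


def optical_density(
    profiles: list[IntensityProfile],
    bounds: list[tuple[float, float]],
    od_mode: str = "ratio",
    min_profiles: int = 3,
) -> float:
    """Segment optical density at one wavelength.

    Per profile, the inside intensity is the mean between the FWHM edges and
    the outside intensity is the mean over two flanking windows, each one
    vessel-width wide and one vessel-width away from its edge.  Profiles
    whose flanking windows leave the sampled support are skipped.  With
    ``od_mode="ratio"`` the OD is the mean over profiles of inside/outside;
    with ``"log"`` it is the mean of log10(outside/inside).
    """
    if od_mode not in ("ratio", "log"):
        raise InvalidMeasurementError(f"unknown od_mode {od_mode!r}")
    per_profile = []
    for p, (left, right) in zip(profiles, bounds):
        width = right - left
        o = p.offsets
        if left - 2 * width < o[0] or right + 2 * width > o[-1]:
            continue
        inside = p.values[(o >= left) & (o <= right)]
        out_sel = ((o >= left - 2 * width) & (o <= left - width)) | (
            (o >= right + width) & (o <= right + 2 * width)
        )
        outside = p.values[out_sel]
        if inside.size == 0 or outside.size == 0 or outside.mean() <= 0:
            continue
        if od_mode == "ratio":
            per_profile.append(inside.mean() / outside.mean())
        else:
            if inside.mean() <= 0:
                continue
            per_profile.append(math.log10(outside.mean() / inside.mean()))
    if len(per_profile) < min_profiles:
        raise NoProfilesError(
            f"only {len(per_profile)} usable profiles (< {min_profiles})"
        )
    return float(np.mean(per_profile))


def so2_from_odr(odr: float, cal: CalibrationParams) -> float:
    """SO2 (%) from the optical density ratio via the linear calibration,
    clamped to [0, 100] (measurement noise can overshoot the physical range)."""
    if not np.isfinite(odr) or odr <= 0:
        raise InvalidMeasurementError(f"ODR must be finite and positive, got {odr}")
    raw = cal.a + cal.b * odr
    if raw < 0 or raw > 100:
        log.warning("so2_from_odr: raw SO2 %.1f%% clamped to [0, 100]", raw)
    return float(np.clip(raw, 0.0, 100.0))


def hgb_from_hct(hct: float, hgb_per_hct: float = 1.0 / 3.0) -> float:
    """Hemoglobin concentration (g/dL) from hematocrit (%), by the standard
    one-third clinical rule."""
    if not (0 < hct < 100):
        raise InvalidSubjectError(f"HCT must lie in (0, 100), got {hct}")
    return hct * hgb_per_hct


def o2_content(so2: float, hgb: float, o2max: float = 1.34) -> float:
    """Vascular oxygen content (mL O2/dL): o2max * hgb * so2 / 100."""
    if not (0 <= so2 <= 100):
        raise InvalidMeasurementError(f"SO2 must lie in [0, 100], got {so2}")
    if hgb <= 0 or o2max <= 0:
        raise InvalidMeasurementError("hgb and o2max must be positive")
    return o2max * hgb * so2 / 100.0


def _own_label(labels: np.ndarray, chain_points: np.ndarray) -> int:
    rr = np.clip(np.rint(chain_points[:, 1]).astype(int), 0, labels.shape[0] - 1)
    cc = np.clip(np.rint(chain_points[:, 0]).astype(int), 0, labels.shape[1] - 1)
    vals = labels[rr, cc]
    vals = vals[vals > 0]
    if vals.size == 0:
        return 0
    return int(np.bincount(vals).argmax())


def _window_hits_other_vessel(
    profile: IntensityProfile,
    left: float,
    right: float,
    labels: np.ndarray,
    own: int,
) -> bool:
    width = right - left
    o = profile.offsets
    sel = ((o >= left - 2 * width) & (o <= left - width)) | (
        (o >= right + width) & (o <= right + 2 * width)
    )
    xs, ys = profile.coords[0][sel], profile.coords[1][sel]
    rr = np.clip(np.rint(ys).astype(int), 0, labels.shape[0] - 1)
    cc = np.clip(np.rint(xs).astype(int), 0, labels.shape[1] - 1)
    vals = labels[rr, cc]
    return bool(np.any((vals > 0) & (vals != own)))


def analyze_pair(
    pair: FundusImagePair,
    cfg: PipelineConfig,
    hct: float | None = None,
    mask: np.ndarray | None = None,
) -> pd.DataFrame:
    """Per-segment oximetry table for one image pair.

    Segments vessels in the 1-2 ONH-radius annulus, measures OD at both
    wavelengths with shared FWHM geometry from the 532 nm image, and converts
    to SO2.  If ``hct`` is given, oxygen content is computed per segment;
    otherwise the column is left NaN for a later join against subject data.
    """
    ocfg, cal = cfg.oximetry, cfg.calibration
    if mask is None:
        mask = segment_vessels(
            pair.image_532,
            um_per_px=pair.um_per_px,
            sigmas=ocfg.frangi_sigmas,
            vesselness_threshold=ocfg.vesselness_threshold,
            min_diameter_um=ocfg.min_diameter_um,
            gamma=ocfg.frangi_gamma,
        )
    ann = annulus_mask(
        pair.onh_center, pair.onh_radius, ocfg.annulus[0], ocfg.annulus[1],
        pair.image_532.shape,
    )
    labels = label_components(mask)
    chains = extract_centerlines(
        mask, annulus=ann, min_length=ocfg.min_chain_px, image=pair.image_532
    )
    hgb = hgb_from_hct(hct, cal.hgb_per_hct) if hct is not None else None

    rows = []
    for i, chain in enumerate(chains):
        cl = smooth_centerline(chain, regularization=cfg.tortuosity.spline_regularization)
        try:
            profiles_532 = extract_profiles(
                cl, pair.image_532, spacing=ocfg.profile_spacing,
                half_width=ocfg.profile_half_width,
            )
        except NoProfilesError as exc:
            log.warning("segment %d skipped: %s", i, exc)
            continue
        own = _own_label(labels, cl.points)
        usable_532, usable_633, usable_bounds = [], [], []
        for p in profiles_532:
            try:
                left, right = fwhm_bounds(p, min_depth=ocfg.min_dip_depth)
            except NoVesselError:
                continue
            if _window_hits_other_vessel(p, left, right, labels, own):
                continue
            usable_532.append(p)
            usable_633.append(resample_profile(p, pair.image_633))
            usable_bounds.append((left, right))
        try:
            od_532 = optical_density(usable_532, usable_bounds, cal.od_mode, ocfg.min_profiles)
            od_633 = optical_density(usable_633, usable_bounds, cal.od_mode, ocfg.min_profiles)
        except NoProfilesError as exc:
            log.warning("segment %d excluded: %s", i, exc)
            continue
        if od_532 <= 0:
            log.warning("segment %d excluded: nonpositive OD532", i)
            continue
        odr = od_633 / od_532
        so2 = so2_from_odr(odr, cal)
        widths = np.array([r - l for l, r in usable_bounds])
        diam_um = float(widths.mean() * pair.um_per_px)
        if diam_um < ocfg.min_diameter_um:
            log.info("segment %d excluded: FWHM caliber %.1f um below %.1f um",
                     i, diam_um, ocfg.min_diameter_um)
            continue
        rows.append(
            {
                "segment_id": f"o{i:03d}",
                "angle_deg": _segment_angle(cl.points, pair.onh_center),
                "mean_diameter_um": diam_um,
                "od_532": od_532,
                "od_633": od_633,
                "odr": odr,
                "so2": so2,
                "o2_content": o2_content(so2, hgb, cal.o2max) if hgb is not None else np.nan,
                "n_profiles": len(usable_bounds),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "segment_id", "angle_deg", "mean_diameter_um", "od_532", "od_633",
            "odr", "so2", "o2_content", "n_profiles",
        ],
    )


def _segment_angle(points: np.ndarray, onh_center: tuple[float, float]) -> float:
    ang = np.arctan2(points[:, 1] - onh_center[1], points[:, 0] - onh_center[0])
    return float(np.degrees(np.angle(np.mean(np.exp(1j * ang)))))
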