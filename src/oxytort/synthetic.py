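"""Synthetic dual-wavelength fundus generator with known ground truth.

This is the forward model that the oximetry and tortuosity stages invert.
It renders a circumpapillary field — a bright optic-nerve-head (ONH) disc on
a uniform retinal background — crossed by dark vessels with:

* a Gaussian cross-profile whose FWHM equals the nominal vessel diameter,
  with the dip depth set so that the *mean* intensity inside the FWHM
  equals ``background * OD`` (making both the FWHM caliber and the
  inside/outside optical density exactly recoverable in the noiseless
  case);
* wavelength-dependent darkening that encodes a known SO2 through the
  inverse of the linear SO2 calibration (532 nm near-isosbestic, 633 nm
  oxygen sensitive);
* analytically known centerline geometry: straight segments, sinusoids
  (k full periods have exactly 2k-1 interior curvature sign changes), and
  composite radial vessels whose undulation is confined to a band of the
  path (a raised-cosine wave with m periods contributing exactly 2m
  inflection points, joining the straight tails with continuous tangent).

The cohort generator arranges such vessels around the ONH for every eye of
a two-group cohort (healthy controls, NC, versus sickle cell retinopathy,
SCR) and draws subject vitals from group-specific distributions; low SCR
hematocrit reproduces the anemia-driven oxygen-content deficit.  A separate
table-level simulator (`simulate_cohort_table`) draws per-eye/vessel-type
aggregate rows directly from the statistical model that the cohort mixed
models assume — it is the fast forward model used to validate inference,
while `render_pair`/`generate_cohort` exercise the full imaging chain.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from scipy.spatial import cKDTree

from .config import CalibrationParams, CohortConfig, CohortEffects, PipelineConfig, RenderConfig
from .errors import InvalidSpecError, RenderRangeError
from .oximetry import FWHM_PER_SIGMA, GAUSSIAN_FWHM_MEAN, FundusImagePair
from .stats import map_from_bp

log = logging.getLogger(__name__)

#: Inside/outside intensity ratios that the Gaussian-dip profile can render:
#: the dip depth (1 - od) / GAUSSIAN_FWHM_MEAN must stay within [0, 1].
OD_RENDER_MIN = 1.0 - GAUSSIAN_FWHM_MEAN + 0.005
OD_RENDER_MAX = 0.98

_GT_COLUMNS = [
    "vessel_id", "vessel_type", "so2_true", "diameter_um",
    "inflection_count_true", "arc_length_true", "angle_deg",
    "subject_id", "eye", "diagnosis",
]


@dataclass
class VesselSpec:
    """Geometry and physiology of one synthetic vessel.

    ``path_kind`` is one of:

    straight
        a straight segment of the given length.
    sinusoid
        transverse displacement A*sin(2*pi*k*t/L); with k >= 1 full periods
        the interior curvature changes sign exactly 2k-1 times.
    composite
        straight tails with a raised-cosine undulation
        (A/2)*(1 - cos(2*pi*k*u)) confined to the ``band`` fraction of the
        path; contributes exactly 2k interior curvature sign changes and
        joins the tails with a continuous tangent.
    """

    path_kind: str
    length: float                      # px
    diameter_um: float
    vessel_type: str = "artery"        # "artery" | "vein"
    so2_true: float = 95.0             # percent
    amplitude: float = 0.0             # px, transverse
    periods: int = 0
    start: tuple[float, float] = (0.0, 0.0)   # (x, y) px
    orientation_deg: float = 0.0
    band: tuple[float, float] = (0.2, 0.9)    # fraction of length (composite only)

    def __post_init__(self) -> None:
        if self.path_kind not in ("straight", "sinusoid", "composite"):
            raise InvalidSpecError(f"unknown path_kind {self.path_kind!r}")
        if self.length <= 0:
            raise InvalidSpecError("length must be positive")
        if self.diameter_um <= 0:
            raise InvalidSpecError("diameter must be positive")
        if not (0 <= self.so2_true <= 100):
            raise InvalidSpecError("so2_true must lie in [0, 100]")
        if self.periods < 0:
            raise InvalidSpecError("periods must be >= 0")
        if self.amplitude < 0:
            raise InvalidSpecError("amplitude must be >= 0")
        if self.vessel_type not in ("artery", "vein"):
            raise InvalidSpecError(f"unknown vessel_type {self.vessel_type!r}")
        if not (0.0 <= self.band[0] < self.band[1] <= 1.0):
            raise InvalidSpecError("band must satisfy 0 <= lo < hi <= 1")

    @property
    def inflection_count_true(self) -> int:
        """Analytic interior curvature sign-change count of the path."""
        if self.amplitude == 0 or self.periods == 0 or self.path_kind == "straight":
            return 0
        if self.path_kind == "sinusoid":
            return 2 * self.periods - 1
        return 2 * self.periods  # composite raised-cosine band


def _transverse(spec: VesselSpec, t: np.ndarray) -> np.ndarray:
    if spec.path_kind == "straight" or spec.periods == 0 or spec.amplitude == 0:
        return np.zeros_like(t)
    if spec.path_kind == "sinusoid":
        return spec.amplitude * np.sin(2.0 * np.pi * spec.periods * t / spec.length)
    f0, f1 = spec.band
    u = (t / spec.length - f0) / (f1 - f0)
    v = np.zeros_like(t)
    inside = (u >= 0) & (u <= 1)
    v[inside] = 0.5 * spec.amplitude * (1.0 - np.cos(2.0 * np.pi * spec.periods * u[inside]))
    return v


def make_vessel_path(spec: VesselSpec, samples_per_px: float = 2.0) -> np.ndarray:
    """Ordered (n, 2) point sequence tracing the vessel path, >= length *
    samples_per_px points."""
    if samples_per_px <= 0:
        raise InvalidSpecError("samples_per_px must be positive")
    if spec.length < 10:
        raise InvalidSpecError("vessel length must be >= 10 px")
    n = int(math.ceil(spec.length * samples_per_px)) + 1
    t = np.linspace(0.0, spec.length, n)
    v = _transverse(spec, t)
    ang = math.radians(spec.orientation_deg)
    ca, sa = math.cos(ang), math.sin(ang)
    x = spec.start[0] + t * ca - v * sa
    y = spec.start[1] + t * sa + v * ca
    return np.column_stack([x, y])


def _polyline_length(xy: np.ndarray) -> float:
    return float(np.sum(np.hypot(*np.diff(xy, axis=0).T)))


def vessel_ods(spec: VesselSpec, cfg: RenderConfig, cal: CalibrationParams) -> tuple[float, float]:
    """Inside/outside intensity ratios at 532 and 633 nm encoding so2_true.

    Raises :class:`RenderRangeError` when the SO2 maps outside the renderable
    optical-density window.
    """
    od532 = cfg.od532_base
    odr = cal.odr_from_so2(spec.so2_true)
    if not np.isfinite(odr) or odr <= 0:
        raise RenderRangeError(
            f"so2_true={spec.so2_true} maps to non-positive ODR {odr:.3f}"
        )
    od633 = od532 * odr
    for name, od in (("532", od532), ("633", od633)):
        if not (OD_RENDER_MIN <= od <= OD_RENDER_MAX):
            raise RenderRangeError(
                f"OD{name}={od:.3f} outside renderable range "
                f"[{OD_RENDER_MIN:.3f}, {OD_RENDER_MAX:.3f}] (so2={spec.so2_true})"
            )
    return od532, od633


def render_pair(
    vessels: list[VesselSpec],
    cfg: RenderConfig,
    cal: CalibrationParams,
) -> tuple[FundusImagePair, pd.DataFrame]:
    """Render a 532/633 nm image pair plus its ground-truth table.

    Vessel attenuation is multiplicative on the local background (so vessels
    remain visible over the ONH disc); images are quantized to 16 bit so the
    in-memory arrays match what a TIFF round trip yields, and identical
    seeds give bit-identical pairs.
    """
    h, w = cfg.image_size
    cx, cy = cfg.onh_center
    yy, xx = np.mgrid[0:h, 0:w].astype(float)
    d = np.hypot(xx - cx, yy - cy)
    base = cfg.background + (cfg.onh_intensity - cfg.background) / (
        1.0 + np.exp((d - cfg.onh_radius) / 1.5)
    )
    att532 = np.ones((h, w))
    att633 = np.ones((h, w))

    rows = []
    for idx, spec in enumerate(vessels):
        path = make_vessel_path(spec, samples_per_px=4.0)
        if (
            path[:, 0].min() < 0 or path[:, 1].min() < 0
            or path[:, 0].max() > w - 1 or path[:, 1].max() > h - 1
        ):
            raise InvalidSpecError(f"vessel {idx} does not fit in the frame")
        od532, od633 = vessel_ods(spec, cfg, cal)
        sigma = (spec.diameter_um / cfg.um_per_px) / FWHM_PER_SIGMA
        d532 = (1.0 - od532) / GAUSSIAN_FWHM_MEAN
        d633 = (1.0 - od633) / GAUSSIAN_FWHM_MEAN

        reach = 4.0 * sigma + 2.0
        x0 = max(int(path[:, 0].min() - reach), 0)
        x1 = min(int(path[:, 0].max() + reach) + 1, w)
        y0 = max(int(path[:, 1].min() - reach), 0)
        y1 = min(int(path[:, 1].max() + reach) + 1, h)
        sub_y, sub_x = np.mgrid[y0:y1, x0:x1]
        tree = cKDTree(path)
        dist, _ = tree.query(np.column_stack([sub_x.ravel(), sub_y.ravel()]))
        g = np.exp(-(dist**2) / (2.0 * sigma**2)).reshape(sub_y.shape)
        att532[y0:y1, x0:x1] *= 1.0 - d532 * g
        att633[y0:y1, x0:x1] *= 1.0 - d633 * g

        ang = np.arctan2(path[:, 1] - cy, path[:, 0] - cx)
        rows.append(
            {
                "vessel_id": f"v{idx:02d}",
                "vessel_type": spec.vessel_type,
                "so2_true": spec.so2_true,
                "diameter_um": spec.diameter_um,
                "inflection_count_true": spec.inflection_count_true,
                "arc_length_true": _polyline_length(path),
                "angle_deg": float(np.degrees(np.angle(np.mean(np.exp(1j * ang))))),
                "subject_id": "", "eye": "", "diagnosis": "",
            }
        )

    img532 = base * att532
    img633 = base * att633
    if cfg.noise_sd > 0:
        rng = np.random.default_rng(cfg.seed)
        img532 = img532 + rng.normal(0.0, cfg.noise_sd, (h, w))
        img633 = img633 + rng.normal(0.0, cfg.noise_sd, (h, w))
    q532 = np.round(np.clip(img532, 0.0, 1.0) * 65535.0).astype(np.uint16)
    q633 = np.round(np.clip(img633, 0.0, 1.0) * 65535.0).astype(np.uint16)
    pair = FundusImagePair(
        image_532=q532 / 65535.0,
        image_633=q633 / 65535.0,
        onh_center=cfg.onh_center,
        onh_radius=cfg.onh_radius,
        um_per_px=cfg.um_per_px,
    )
    return pair, pd.DataFrame(rows, columns=_GT_COLUMNS)


def pair_to_uint16(pair: FundusImagePair) -> tuple[np.ndarray, np.ndarray]:
    """16-bit arrays for lossless TIFF storage."""
    return (
        np.round(pair.image_532 * 65535.0).astype(np.uint16),
        np.round(pair.image_633 * 65535.0).astype(np.uint16),
    )


# ---------------------------------------------------------------------------
# cohort generation


def _draw_subjects(n_nc: int, n_scr: int, ccfg: CohortConfig, rng: np.random.Generator) -> pd.DataFrame:
    if n_nc < 1 or n_scr < 1:
        raise InvalidSpecError("need at least one subject per group")
    rows = []
    for i in range(n_nc + n_scr):
        scr = i >= n_nc
        diag = "SCR" if scr else "NC"
        age_mu, age_sd = ccfg.age_scr if scr else ccfg.age_nc
        hct_mu, hct_sd = ccfg.hct_scr if scr else ccfg.hct_nc
        map_mu, map_sd = ccfg.map_scr if scr else ccfg.map_nc
        age = float(np.clip(rng.normal(age_mu, age_sd), 18.0, 80.0))
        hct = float(np.clip(rng.normal(hct_mu, hct_sd), 18.0, 50.0))
        map_t = float(np.clip(rng.normal(map_mu, map_sd), 60.0, 120.0))
        pp = float(np.clip(rng.normal(*ccfg.pulse_pressure), 25.0, 65.0))
        dbp = map_t - pp / 3.0
        sbp = dbp + pp
        rows.append(
            {
                "subject_id": f"{'S' if scr else 'N'}{i:03d}",
                "diagnosis": diag,
                "sex": str(rng.choice(["M", "F"])),
                "age": round(age, 1),
                "hct": round(hct, 1),
                "sbp": round(sbp, 1),
                "dbp": round(dbp, 1),
            }
        )
    return pd.DataFrame(rows)


def _eye_vessel_specs(
    subject: pd.Series,
    ccfg: CohortConfig,
    rcfg: RenderConfig,
    cal: CalibrationParams,
    rng: np.random.Generator,
) -> list[VesselSpec]:
    scr = subject["diagnosis"] == "SCR"
    eff = ccfg.effects
    r = rcfg.onh_radius
    cx, cy = rcfg.onh_center
    hgb = subject["hct"] / 3.0
    o2cap = cal.o2max * hgb

    n = ccfg.vessels_per_eye
    base_angles = 360.0 / n * np.arange(n) + rng.uniform(0.0, 360.0 / n)
    angles = base_angles + rng.uniform(-8.0, 8.0, n)
    length = 4.2 * r
    band = ((1.8 - 0.85) / 4.2, (4.6 - 0.85) / 4.2)  # undulation within 1.8-4.6 ONH radii
    specs: list[VesselSpec] = []
    for j, ang in enumerate(angles):
        vtype = "artery" if j % 2 == 0 else "vein"
        d_mu, d_sd = ccfg.artery_diameter_um if vtype == "artery" else ccfg.vein_diameter_um
        s_mu, s_sd = ccfg.artery_so2 if vtype == "artery" else ccfg.vein_so2
        diam = float(np.clip(rng.normal(d_mu, d_sd), 45.0, 100.0))
        mu_m = 4.0 + (eff.vii_shift / 2.0 if scr else 0.0)
        m = int(np.clip(round(rng.normal(mu_m, 0.7)), 2, 6))
        amp = float(np.clip(rng.normal(*ccfg.undulation_amplitude_px), 1.8, 3.5))
        so2 = rng.normal(s_mu, s_sd)
        so2 += eff.o2_vii_slope * (2 * m - 8) * 100.0 / o2cap
        if scr:
            so2 -= eff.scr_so2_deficit
        so2 = float(np.clip(so2, 42.0, 97.0))
        rad = math.radians(ang)
        start = (cx + 0.85 * r * math.cos(rad), cy + 0.85 * r * math.sin(rad))
        specs.append(
            VesselSpec(
                path_kind="composite", length=length, diameter_um=diam,
                vessel_type=vtype, so2_true=so2, amplitude=amp, periods=m,
                start=start, orientation_deg=float(ang), band=band,
            )
        )
    if ccfg.include_capillary:
        # sub-25 µm vessel crossing the oximetry annulus; exercises the
        # caliber filter and must never appear in the measured tables
        ang = float(angles[0] + 180.0 / n)
        rad = math.radians(ang)
        start = (cx + 1.05 * r * math.cos(rad), cy + 1.05 * r * math.sin(rad))
        specs.append(
            VesselSpec(
                path_kind="straight", length=1.4 * r, diameter_um=15.0,
                vessel_type="vein", so2_true=60.0, start=start,
                orientation_deg=ang,
            )
        )
    return specs


def generate_cohort(
    out_dir: str | Path,
    cfg: PipelineConfig,
    n_nc: int | None = None,
    n_scr: int | None = None,
    seed: int | None = None,
) -> dict:
    """Render a full synthetic cohort to ``out_dir``.

    Writes one 16-bit grayscale TIFF per wavelength and eye
    (``<subject>_<eye>_532.tif`` / ``_633.tif``), ``subjects.csv``,
    ``ground_truth.csv`` and ``annotations.json`` (ONH geometry, pixel scale
    and the eye-to-file index).  Fully deterministic for a fixed seed.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ccfg = cfg.cohort
    n_nc = ccfg.n_nc if n_nc is None else n_nc
    n_scr = ccfg.n_scr if n_scr is None else n_scr
    rng = np.random.default_rng(cfg.seed if seed is None else seed)

    subjects = _draw_subjects(n_nc, n_scr, ccfg, rng)
    annotations = {
        "um_per_px": cfg.render.um_per_px,
        "onh_center": list(cfg.render.onh_center),
        "onh_radius": cfg.render.onh_radius,
        "eyes": [],
    }
    gt_frames = []
    for _, subject in subjects.iterrows():
        for eye in ("OD", "OS"):
            specs = _eye_vessel_specs(subject, ccfg, cfg.render, cfg.calibration, rng)
            render_seed = int(rng.integers(0, 2**31 - 1))
            rcfg_eye = dataclasses.replace(cfg.render, seed=render_seed)
            pair, gt = render_pair(specs, rcfg_eye, cfg.calibration)
            stem = f"{subject['subject_id']}_{eye}"
            q532, q633 = pair_to_uint16(pair)
            tifffile.imwrite(out / f"{stem}_532.tif", q532)
            tifffile.imwrite(out / f"{stem}_633.tif", q633)
            gt["vessel_id"] = [f"{stem}_{v}" for v in gt["vessel_id"]]
            gt["subject_id"] = subject["subject_id"]
            gt["eye"] = eye
            gt["diagnosis"] = subject["diagnosis"]
            gt_frames.append(gt)
            annotations["eyes"].append(
                {
                    "subject_id": subject["subject_id"],
                    "eye": eye,
                    "file_532": f"{stem}_532.tif",
                    "file_633": f"{stem}_633.tif",
                }
            )
    subjects.to_csv(out / "subjects.csv", index=False, float_format="%.10g")
    ground_truth = pd.concat(gt_frames, ignore_index=True)
    ground_truth.to_csv(out / "ground_truth.csv", index=False, float_format="%.10g")
    with open(out / "annotations.json", "w") as fh:
        json.dump(annotations, fh, sort_keys=True, indent=1)
    log.info("generated cohort: %d subjects, %d eyes", len(subjects), 2 * len(subjects))
    return {
        "subjects": out / "subjects.csv",
        "ground_truth": out / "ground_truth.csv",
        "annotations": out / "annotations.json",
        "dir": out,
    }


# ---------------------------------------------------------------------------
# table-level statistical simulator


def simulate_cohort_table(
    n_nc: int,
    n_scr: int,
    effects: CohortEffects | None = None,
    seed: int = 0,
    o2_deficit: float = 0.0,
    subject_sd: float = 1.0,
    residual_sd: float = 0.8,
    ccfg: CohortConfig | None = None,
) -> pd.DataFrame:
    """Draw per-eye x vessel-type aggregate rows from the mixed-model data
    generating process (no image rendering).

    Each subject contributes a random intercept (sd ``subject_sd``), each
    row an independent residual (sd ``residual_sd``); per-row O2 content is

        o2 = mu_type + o2_vii_slope * (vii - 8) - o2_deficit * [SCR] + b_subj + eps

    with mu set to 15 (arteries) / 10 (veins) mL O2/dL, and VII the mean of
    four per-vessel inflection counts whose group mean shifts by
    ``effects.vii_shift``.  ``o2_deficit`` is a group effect not mediated by
    VII; leave it at 0 when validating slope recovery so the imposed slope
    is the only systematic O2-VII pathway.
    """
    effects = effects or CohortEffects()
    ccfg = ccfg or CohortConfig()
    rng = np.random.default_rng(seed)
    subjects = _draw_subjects(n_nc, n_scr, ccfg, rng)
    rows = []
    for _, subject in subjects.iterrows():
        scr = subject["diagnosis"] == "SCR"
        b_subj = rng.normal(0.0, subject_sd)
        mu_m = 4.0 + (effects.vii_shift / 2.0 if scr else 0.0)
        for eye in ("OD", "OS"):
            for vtype in ("artery", "vein"):
                m = np.clip(np.round(rng.normal(mu_m, 0.7, 4)), 2, 7)
                vii = float(np.mean(2 * m))
                mu_o2 = 15.0 if vtype == "artery" else 10.0
                o2 = (
                    mu_o2
                    + effects.o2_vii_slope * (vii - 8.0)
                    - (o2_deficit if scr else 0.0)
                    + b_subj
                    + rng.normal(0.0, residual_sd)
                )
                vti = float(max(rng.normal(0.16, 0.04), 0.03))
                rows.append(
                    {
                        "subject_id": subject["subject_id"],
                        "diagnosis": subject["diagnosis"],
                        "eye": eye,
                        "vessel_type": vtype,
                        "age": subject["age"],
                        "map_mmhg": map_from_bp(subject["sbp"], subject["dbp"]),
                        "hct": subject["hct"],
                        "o2_content": float(o2),
                        "vti": vti,
                        "vii": vii,
                    }
                )
    return pd.DataFrame(rows)
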