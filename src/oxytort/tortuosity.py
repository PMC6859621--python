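"""Vessel tortuosity metrics: VTI and the vessel inflection index (VII).

The vessel tortuosity index combines local and global shape features of a
smoothed centerline::

    VTI = 0.1 * SD_theta * N * M * (LA / LC)

where SD_theta is the standard deviation (degrees) of the tangent angles
measured in the chord-aligned frame, N is the number of critical points
(sign changes of dy/ds in the chord frame, i.e. extrema of the deflection),
M is the mean arc/chord ratio over the sub-segments delimited by inflection
points and the two endpoints, and LA/LC is the arc-to-chord length ratio.
Every factor is dimensionless, so VTI is invariant to rigid transformation
and to uniform magnification.  A straight segment has N = 0 and therefore
VTI = 0 exactly.

VII is the number of sign changes of the signed curvature along the
centerline interior — a count of inflection points that separates smoothly
curved vessels from undulated ones.

All angle/derivative computations are done in the chord-aligned frame: the
formulation's "x-axis" is taken as the segment's own chord, the only
reading consistent with rigid invariance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .centerline import VesselCenterline, extract_centerlines, smooth_centerline
from .config import PipelineConfig
from .segmentation import annulus_mask, segment_vessels

__all__ = [
    "TortuosityRecord",
    "VesselCenterline",
    "extract_centerlines",
    "smooth_centerline",
    "count_critical_points",
    "count_inflections",
    "mean_arc_chord_ratio",
    "compute_vti",
    "analyze_tortuosity",
]

log = logging.getLogger(__name__)


@dataclass
class TortuosityRecord:
    """Per-segment tortuosity measurement."""

    sd_theta: float      # degrees, chord-frame tangent-angle SD
    n_critical: int      # N, deflection extrema
    m_ratio: float       # M, mean sub-segment arc/chord ratio (>= 1)
    la: float            # arc length, px
    lc: float            # chord length, px
    vti: float
    vii: int             # inflection count
    segment_id: str | None = None
    vessel_type: str | None = None


def _signed_sequence(values: np.ndarray, eps: float) -> np.ndarray:
    return np.where(values > eps, 1, np.where(values < -eps, -1, 0))


def _sign_change_indices(signs: np.ndarray) -> list[tuple[int, int]]:
    """Index pairs (i, j) of consecutive nonzero entries with opposite sign.

    Zero runs between them are skipped: a crossing requires an actual sign
    change across the sub-threshold gap, so zeros touched without crossing
    are never counted.
    """
    nz = np.nonzero(signs)[0]
    if nz.size < 2:
        return []
    vals = signs[nz]
    flips = np.nonzero(vals[:-1] * vals[1:] < 0)[0]
    return [(int(nz[k]), int(nz[k + 1])) for k in flips]


def count_critical_points(cl: VesselCenterline, eps: float = 1e-4) -> int:
    """N: sign changes of dy/ds along the chord-aligned centerline.

    The curve is rotated so its chord lies on the +x axis; critical points
    are where the deflection derivative dy/ds crosses zero.  |dy/ds| below
    ``eps`` is treated as zero, so a straight segment (derivative
    identically ~0) yields N = 0.
    """
    phi = np.radians(cl.theta_deg - cl.chord_angle_deg)
    dyds = np.sin(phi)
    return len(_sign_change_indices(_signed_sequence(dyds, eps)))


def count_inflections(
    cl: VesselCenterline,
    kappa_eps: float = 1e-6,
    endpoint_buffer: int = 2,
) -> tuple[int, list[float]]:
    """VII and arclength locations of curvature sign changes.

    |kappa| below ``kappa_eps`` (1/px) is treated as zero, and crossings
    within ``endpoint_buffer`` samples of either end are ignored: both
    guards suppress phantom inflections from noise and spline end effects.
    """
    n = len(cl.kappa)
    b = int(endpoint_buffer)
    lo, hi = b, n - b
    if hi - lo < 2:
        return 0, []
    kappa = cl.kappa[lo:hi]
    s = cl.s[lo:hi]
    pairs = _sign_change_indices(_signed_sequence(kappa, kappa_eps))
    locations = [float(0.5 * (s[i] + s[j])) for i, j in pairs]
    return len(pairs), locations


def mean_arc_chord_ratio(cl: VesselCenterline, inflection_s) -> float:
    """M: mean of (sub-arc length / sub-chord length) over the partition of
    the curve at its inflection points plus the two endpoints.

    With no inflection points the whole curve is a single sub-segment and
    M = LA / LC.
    """
    cuts = np.concatenate([[cl.s[0]], np.sort(np.asarray(inflection_s, float)), [cl.s[-1]]])
    ratios = []
    for s0, s1 in zip(cuts[:-1], cuts[1:]):
        arc = s1 - s0
        if arc <= 1e-9:
            continue
        p0, p1 = cl.point_at(s0), cl.point_at(s1)
        chord = float(np.hypot(*(p1 - p0)))
        if chord <= 1e-12:
            continue  # degenerate (closed) sub-segment
        ratios.append(arc / chord)
    return float(np.mean(ratios)) if ratios else 1.0


def compute_vti(
    cl: VesselCenterline,
    deriv_eps: float = 1e-4,
    kappa_eps: float = 1e-6,
    endpoint_buffer: int = 2,
    sdtheta_mode: str = "angles",
) -> TortuosityRecord:
    """All VTI components and VII for one smoothed centerline.

    ``sdtheta_mode`` selects whether SD_theta is the SD of the chord-frame
    tangent angles themselves ("angles", the default) or of their
    consecutive differences ("diffs").
    """
    n_crit = count_critical_points(cl, eps=deriv_eps)
    vii, locations = count_inflections(cl, kappa_eps=kappa_eps, endpoint_buffer=endpoint_buffer)
    m = mean_arc_chord_ratio(cl, locations)
    phi = cl.theta_deg - cl.chord_angle_deg
    if sdtheta_mode == "diffs":
        sd_theta = float(np.std(np.diff(phi)))
    else:
        # arclength-weighted SD (trapezoid rule) so the value does not
        # depend on the resampling grid
        s = cl.s
        w = np.empty_like(s)
        w[1:-1] = 0.5 * (s[2:] - s[:-2])
        w[0] = 0.5 * (s[1] - s[0])
        w[-1] = 0.5 * (s[-1] - s[-2])
        mu = float(np.average(phi, weights=w))
        sd_theta = float(np.sqrt(np.average((phi - mu) ** 2, weights=w)))
    la, lc = cl.la, cl.lc
    vti = 0.1 * sd_theta * n_crit * m * (la / lc)
    return TortuosityRecord(
        sd_theta=sd_theta, n_critical=n_crit, m_ratio=m,
        la=la, lc=lc, vti=vti, vii=vii,
    )


def _segment_angle_deg(points: np.ndarray, onh_center: tuple[float, float]) -> float:
    """Circular mean of the angular position of a segment around the ONH."""
    ang = np.arctan2(points[:, 1] - onh_center[1], points[:, 0] - onh_center[0])
    return float(np.degrees(np.angle(np.mean(np.exp(1j * ang)))))


def analyze_tortuosity(pair, cfg: PipelineConfig, mask: np.ndarray | None = None) -> pd.DataFrame:
    """Tortuosity table for one image pair.

    Measurements use the 532 nm image (higher vessel/tissue contrast) inside
    the 1.5-5 ONH-radius annulus.  Returns one row per centerline segment
    with the VTI components, VII and the segment's mean angular position
    (used downstream to match segments to their artery/vein labels).
    """
    tcfg = cfg.tortuosity
    if mask is None:
        mask = segment_vessels(
            pair.image_532,
            um_per_px=pair.um_per_px,
            sigmas=tcfg.frangi_sigmas,
            vesselness_threshold=tcfg.vesselness_threshold,
            min_diameter_um=tcfg.min_diameter_um,
            gamma=tcfg.frangi_gamma,
        )
    ann = annulus_mask(
        pair.onh_center, pair.onh_radius, tcfg.annulus[0], tcfg.annulus[1],
        pair.image_532.shape,
    )
    chains = extract_centerlines(
        mask, annulus=ann, min_length=tcfg.min_chain_px, image=pair.image_532
    )
    rows = []
    for i, chain in enumerate(chains):
        cl = smooth_centerline(
            chain,
            regularization=tcfg.spline_regularization,
            resample_step=tcfg.resample_step,
        )
        rec = compute_vti(
            cl,
            deriv_eps=tcfg.deriv_eps,
            kappa_eps=tcfg.kappa_eps,
            endpoint_buffer=tcfg.endpoint_buffer,
            sdtheta_mode=tcfg.sdtheta_mode,
        )
        rows.append(
            {
                "segment_id": f"t{i:03d}",
                "angle_deg": _segment_angle_deg(cl.points, pair.onh_center),
                "sd_theta": rec.sd_theta,
                "n_critical": rec.n_critical,
                "m_ratio": rec.m_ratio,
                "la": rec.la,
                "lc": rec.lc,
                "vti": rec.vti,
                "vii": rec.vii,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "segment_id", "angle_deg", "sd_theta", "n_critical",
            "m_ratio", "la", "lc", "vti", "vii",
        ],
    )
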