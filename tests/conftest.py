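import math

import numpy as np
import pytest

from oxytort.config import PipelineConfig
from oxytort.synthetic import VesselSpec, render_pair


@pytest.fixture(scope="session")
def cfg() -> PipelineConfig:
    return PipelineConfig()


@pytest.fixture(scope="session")
def cal(cfg):
    return cfg.calibration


def radial_spec(cfg, angle_deg, so2, vessel_type="artery", diameter_um=60.0, **kw):
    """A straight vessel running radially outward from just inside the ONH rim."""
    r = cfg.render.onh_radius
    cx, cy = cfg.render.onh_center
    rad = math.radians(angle_deg)
    return VesselSpec(
        path_kind=kw.pop("path_kind", "straight"),
        length=kw.pop("length", 4.2 * r),
        diameter_um=diameter_um,
        vessel_type=vessel_type,
        so2_true=so2,
        start=(cx + 0.85 * r * math.cos(rad), cy + 0.85 * r * math.sin(rad)),
        orientation_deg=angle_deg,
        **kw,
    )


def sinusoid_fixture_spec(cfg, k: int, diameter_um=60.0, so2=90.0):
    """A k-period sinusoid spanning the tortuosity annulus horizontally.

    Amplitude scales as 1/k^2 so the peak curvature (and hence the tube
    geometry the skeletonizer sees) is the same for every k.
    """
    r = cfg.render.onh_radius
    cx, cy = cfg.render.onh_center
    return VesselSpec(
        path_kind="sinusoid",
        length=3.3 * r,
        diameter_um=diameter_um,
        so2_true=so2,
        amplitude=40.0 / k**2,
        periods=k,
        start=(cx + 1.6 * r, cy),
        orientation_deg=0.0,
    )


@pytest.fixture(scope="session")
def three_vessel_render(cfg):
    """Noiseless render of three straight vessels with known SO2/caliber."""
    specs = [
        radial_spec(cfg, 0.0, 90.0, "artery", 60.0),
        radial_spec(cfg, 90.0, 60.0, "vein", 80.0),
        radial_spec(cfg, 200.0, 75.0, "artery", 45.0),
    ]
    pair, gt = render_pair(specs, cfg.render, cfg.calibration)
    return pair, gt, specs


def match_by_angle(table, angle_deg, tol=10.0):
    """Row of a measured segment table nearest in ONH angle, or None."""
    if len(table) == 0:
        return None
    delta = np.abs((table["angle_deg"] - angle_deg + 180.0) % 360.0 - 180.0)
    j = delta.idxmin()
    return table.loc[j] if delta[j] <= tol else None
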