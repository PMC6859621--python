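"""Oximetry: annulus geometry, FWHM boundaries, optical density, SO2, O2."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import ndimage

from oxytort.config import CalibrationParams
from oxytort.errors import (
    InvalidGeometryError,
    InvalidMeasurementError,
    InvalidSubjectError,
    NoProfilesError,
    NoVesselError,
)
from oxytort.centerline import smooth_centerline
from oxytort.oximetry import (
    FWHM_PER_SIGMA,
    IntensityProfile,
    analyze_pair,
    annulus_mask,
    extract_profiles,
    fwhm_bounds,
    hgb_from_hct,
    o2_content,
    optical_density,
    segment_vessels,
    so2_from_odr,
)
from oxytort.synthetic import make_vessel_path, render_pair

from conftest import match_by_angle, radial_spec


def _profile(values, offsets=None):
    values = np.asarray(values, float)
    if offsets is None:
        n = len(values)
        offsets = np.arange(n, dtype=float) - n // 2
    return IntensityProfile(
        offsets=np.asarray(offsets, float),
        values=values,
        center=np.zeros(2),
        normal=np.array([0.0, 1.0]),
        coords=np.vstack([offsets, np.zeros_like(offsets)]),
    )


class TestAnnulus:
    @pytest.mark.parametrize(
        "factors,area_factor",
        [((1.0, 2.0), 3.0), ((1.5, 5.0), 25.0 - 2.25)],
    )
    def test_pixel_count_matches_annulus_area(self, factors, area_factor):
        r = 50.0
        mask = annulus_mask((300.0, 300.0), r, *factors, (600, 600))
        expected = area_factor * math.pi * r**2
        assert mask.sum() == pytest.approx(expected, rel=0.02)

    def test_inverted_factors_rejected(self):
        with pytest.raises(InvalidGeometryError):
            annulus_mask((50.0, 50.0), 10.0, 2.0, 1.0, (100, 100))


class TestFwhm:
    def test_gaussian_dip_width_matches_analytic_fwhm(self):
        sigma = 4.0
        o = np.arange(-30, 31, dtype=float)
        v = 1.0 - 0.5 * np.exp(-(o**2) / (2 * sigma**2))
        left, right = fwhm_bounds(_profile(v, o))
        assert right - left == pytest.approx(FWHM_PER_SIGMA * sigma, abs=0.2)

    def test_rectangular_dip_width(self):
        o = np.arange(-30, 31, dtype=float)
        v = np.where(np.abs(o) <= 5.0, 0.4, 1.0)
        left, right = fwhm_bounds(_profile(v, o))
        assert right - left == pytest.approx(10.0, abs=1.0)

    def test_flat_profile_raises(self):
        with pytest.raises(NoVesselError):
            fwhm_bounds(_profile(np.ones(41)))


class TestProfiles:
    def _straight_centerline(self, length, x0=100.0, y0=100.0):
        t = np.linspace(0.0, length, max(int(length), 8))
        return smooth_centerline(np.column_stack([x0 + t, np.full_like(t, y0)]))

    def test_profile_count_is_floor_len_over_spacing_plus_one(self):
        cl = self._straight_centerline(52.0)
        img = np.full((200, 260), 0.5)
        profiles = extract_profiles(cl, img, spacing=5.0, half_width=10.0)
        assert len(profiles) == int(cl.la // 5) + 1 == 11

    def test_profiles_perpendicular_to_horizontal_centerline(self):
        cl = self._straight_centerline(50.0)
        img = np.full((200, 260), 0.5)
        for p in extract_profiles(cl, img, spacing=5.0, half_width=10.0):
            assert abs(p.normal[0]) < math.sin(math.radians(1.0))
            assert abs(abs(p.normal[1]) - 1.0) < 1e-6

    def test_edge_hugging_centerline_drops_profiles(self, caplog):
        cl = self._straight_centerline(50.0, y0=4.0)  # 10 px half-width leaves frame
        img = np.full((200, 260), 0.5)
        with caplog.at_level("WARNING"):
            with pytest.raises(NoProfilesError):
                extract_profiles(cl, img, spacing=5.0, half_width=10.0)


class TestOpticalDensity:
    def _uniform_dip_profiles(self, inside, outside, n=5):
        profiles, bounds = [], []
        o = np.arange(-30, 31, dtype=float)
        for _ in range(n):
            v = np.where(np.abs(o) <= 5.0, inside, outside)
            profiles.append(_profile(v, o))
            bounds.append((-5.0, 5.0))
        return profiles, bounds

    def test_no_absorption_gives_od_one(self):
        profiles, bounds = self._uniform_dip_profiles(100.0, 100.0)
        assert optical_density(profiles, bounds, "ratio") == pytest.approx(1.0)

    def test_ratio_and_log_modes(self):
        profiles, bounds = self._uniform_dip_profiles(50.0, 100.0)
        assert optical_density(profiles, bounds, "ratio") == pytest.approx(0.5)
        assert optical_density(profiles, bounds, "log") == pytest.approx(math.log10(2.0), abs=1e-9)

    def test_fewer_than_three_profiles_rejected(self):
        profiles, bounds = self._uniform_dip_profiles(50.0, 100.0, n=2)
        with pytest.raises(NoProfilesError):
            optical_density(profiles, bounds, "ratio")


class TestConversions:
    def test_so2_linear_transform_examples(self):
        cal = CalibrationParams(a=110.0, b=-70.0)
        assert so2_from_odr(0.5, cal) == pytest.approx(75.0)
        assert so2_from_odr(0.05, cal) == 100.0  # raw 106.5 clamps
        with pytest.raises(InvalidMeasurementError):
            so2_from_odr(float("nan"), cal)

    def test_calibration_round_trip_is_identity(self, cal):
        for so2 in (45.0, 60.0, 75.0, 97.0):
            assert so2_from_odr(cal.odr_from_so2(so2), cal) == pytest.approx(so2, abs=1e-9)

    def test_hgb_from_hct_one_third_rule(self):
        assert hgb_from_hct(45.0) == pytest.approx(15.0)
        assert hgb_from_hct(30.0) == pytest.approx(10.0)
        with pytest.raises(InvalidSubjectError):
            hgb_from_hct(0.0)

    def test_o2_content_examples(self):
        assert o2_content(100.0, 15.0, 1.34) == pytest.approx(20.1)
        assert o2_content(0.0, 15.0, 1.34) == 0.0
        assert o2_content(50.0, 10.0, 1.34) == pytest.approx(6.7)
        with pytest.raises(InvalidMeasurementError):
            o2_content(-1.0, 15.0)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        so2=st.floats(0.0, 100.0),
        hgb=st.floats(1.0, 25.0),
        o2max=st.floats(0.5, 2.0),
        bump=st.floats(0.1, 10.0),
    )
    def test_o2_content_linear_and_monotone(self, so2, hgb, o2max, bump):
        base = o2_content(so2, hgb, o2max)
        assert 0.0 <= base <= o2max * hgb + 1e-12
        if so2 + bump <= 100.0:
            assert o2_content(so2 + bump, hgb, o2max) >= base
        assert o2_content(so2, hgb * 2.0, o2max) == pytest.approx(base * 2.0, rel=1e-12)


class TestSegmentation:
    def test_blank_image_yields_empty_mask(self):
        assert not segment_vessels(np.full((128, 128), 0.5), um_per_px=8.0).any()

    def test_mask_overlaps_true_vessel_raster(self, cfg, three_vessel_render):
        pair, gt, specs = three_vessel_render
        mask = segment_vessels(pair.image_532, um_per_px=pair.um_per_px)
        # ground truth raster: pixels within FWHM/2 of the 60 um vessel path
        spec = specs[0]
        path = make_vessel_path(spec, 4.0)
        h, w = pair.image_532.shape
        yy, xx = np.mgrid[0:h, 0:w]
        from scipy.spatial import cKDTree

        dist, _ = cKDTree(path).query(np.column_stack([xx.ravel(), yy.ravel()]))
        truth = (dist.reshape(h, w)) <= 0.5 * spec.diameter_um / pair.um_per_px
        covered = (mask & truth).sum() / truth.sum()
        assert covered >= 0.90
        background = ~ndimage.binary_dilation(truth, iterations=3)
        # restrict to this vessel's neighborhood so the other two vessels
        # do not count as false positives
        near = ndimage.binary_dilation(truth, iterations=15)
        false_pos = (mask & background & near).sum() / (background & near).sum()
        assert false_pos <= 0.05

    def test_caliber_filter_drops_sub_25um_vessel(self, cfg):
        specs = [
            radial_spec(cfg, 0.0, 90.0, "artery", 60.0),
            radial_spec(cfg, 180.0, 60.0, "vein", 15.0),
        ]
        pair, _ = render_pair(specs, cfg.render, cfg.calibration)
        mask = segment_vessels(pair.image_532, um_per_px=pair.um_per_px, min_diameter_um=25.0)
        labels, n = ndimage.label(mask, structure=np.ones((3, 3), int))
        assert n == 1
        # the survivor is on the 60 um side (x > center)
        cx = cfg.render.onh_center[0]
        assert np.argwhere(mask)[:, 1].mean() > cx


class TestRoundTrip:
    def test_so2_and_caliber_recovered_on_noiseless_render(self, cfg, three_vessel_render):
        pair, gt, specs = three_vessel_render
        table = analyze_pair(pair, cfg, hct=45.0)
        assert len(table) == len(specs)
        for _, truth in gt.iterrows():
            row = match_by_angle(table, truth["angle_deg"])
            assert row is not None
            assert row["so2"] == pytest.approx(truth["so2_true"], abs=2.0)
            assert row["mean_diameter_um"] == pytest.approx(truth["diameter_um"], rel=0.10)
        # Eq. 1 consistency: o2 = o2max * hgb * so2 / 100 with HCT 45
        expect = cfg.calibration.o2max * 15.0 * table["so2"] / 100.0
        assert np.allclose(table["o2_content"], expect, atol=1e-9)

    def test_brute_force_od_oracle(self, cfg, three_vessel_render):
        """Independent route: pure-python bilinear sampling and per-sample
        means must reproduce optical_density to 1e-6."""
        pair, gt, specs = three_vessel_render
        from oxytort.centerline import extract_centerlines
        from oxytort.oximetry import resample_profile

        mask = segment_vessels(pair.image_532, um_per_px=pair.um_per_px)
        ann = annulus_mask(pair.onh_center, pair.onh_radius, 1.0, 2.0, pair.image_532.shape)
        chains = extract_centerlines(mask, annulus=ann, min_length=20.0)
        assert chains
        cl = smooth_centerline(chains[0])
        profiles = extract_profiles(cl, pair.image_532, spacing=5.0, half_width=34.0)
        bounds = [fwhm_bounds(p) for p in profiles]
        od = optical_density(profiles, bounds, "ratio")

        def bilinear(img, x, y):
            x0, y0 = int(math.floor(x)), int(math.floor(y))
            fx, fy = x - x0, y - y0
            return (
                img[y0, x0] * (1 - fx) * (1 - fy)
                + img[y0, x0 + 1] * fx * (1 - fy)
                + img[y0 + 1, x0] * (1 - fx) * fy
                + img[y0 + 1, x0 + 1] * fx * fy
            )

        per_profile = []
        for p, (left, right) in zip(profiles, bounds):
            wdt = right - left
            if left - 2 * wdt < p.offsets[0] or right + 2 * wdt > p.offsets[-1]:
                continue
            inside, outside = [], []
            for off, x, y in zip(p.offsets, p.coords[0], p.coords[1]):
                val = bilinear(pair.image_532, x, y)
                if left <= off <= right:
                    inside.append(val)
                if left - 2 * wdt <= off <= left - wdt or right + wdt <= off <= right + 2 * wdt:
                    outside.append(val)
            per_profile.append(sum(inside) / len(inside) / (sum(outside) / len(outside)))
        oracle = sum(per_profile) / len(per_profile)
        assert od == pytest.approx(oracle, abs=1e-6)
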