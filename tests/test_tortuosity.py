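"""Centerline extraction/smoothing and the VTI / VII metrics."""

import math

import numpy as np
import pytest
from scipy.integrate import quad

from oxytort.centerline import extract_centerlines, smooth_centerline
from oxytort.errors import TooShortError
from oxytort.synthetic import VesselSpec, make_vessel_path, render_pair
from oxytort.tortuosity import (
    analyze_tortuosity,
    compute_vti,
    count_critical_points,
    count_inflections,
    mean_arc_chord_ratio,
)

from conftest import sinusoid_fixture_spec


def _sinusoid_points(k=2, A=10.0, L=200.0, n=400, angle_deg=0.0, offset=(0.0, 0.0)):
    t = np.linspace(0.0, L, n)
    y = A * np.sin(2 * np.pi * k * t / L)
    ang = math.radians(angle_deg)
    x_r = offset[0] + t * math.cos(ang) - y * math.sin(ang)
    y_r = offset[1] + t * math.sin(ang) + y * math.cos(ang)
    return np.column_stack([x_r, y_r])


def _straight_points(n=100, angle_deg=17.0):
    t = np.linspace(0.0, 150.0, n)
    ang = math.radians(angle_deg)
    return np.column_stack([t * math.cos(ang), t * math.sin(ang)])


class TestExtractCenterlines:
    def test_straight_bar_yields_single_axis_chain(self):
        mask = np.zeros((60, 140), bool)
        mask[26:34, 20:120] = True  # 100 x 8 bar, axis at y = 29.5
        chains = extract_centerlines(mask, min_length=20.0)
        assert len(chains) == 1
        assert np.abs(chains[0][:, 1] - 29.5).max() <= 0.5

    def test_y_mask_splits_into_three_chains_avoiding_branch_point(self):
        mask = np.zeros((160, 160), bool)
        mask[78:83, 10:80] = True                      # horizontal arm
        for i in range(70):                            # two diagonal arms
            mask[80 - i // 2 - 2 : 80 - i // 2 + 3, 80 + i] = True
            mask[80 + i // 2 - 2 : 80 + i // 2 + 3, 80 + i] = True
        chains = extract_centerlines(mask, min_length=15.0, trim_ends=2)
        assert len(chains) == 3
        # each chain stays within a single arm: left of the junction, or on
        # the upper/lower diagonal — never spanning two arms
        for c in chains:
            in_left = c[:, 0] < 78.0
            in_upper = (c[:, 0] > 82.0) & (c[:, 1] < 80.0)
            in_lower = (c[:, 0] > 82.0) & (c[:, 1] > 80.0)
            arms = sum(flag.any() for flag in (in_left, in_upper, in_lower))
            assert arms == 1

    def test_rendered_sinusoid_chain_tracks_true_path(self, cfg):
        # moderate amplitude: at high curvature the skeleton of a rendered
        # tube is biased inward by ~kappa*sigma^2/2, which is a property of
        # the image, not of the chain extraction under test
        spec = sinusoid_fixture_spec(cfg, 2)
        spec.amplitude = 6.0
        pair, _ = render_pair([spec], cfg.render, cfg.calibration)
        from oxytort.segmentation import segment_vessels

        mask = segment_vessels(pair.image_532, um_per_px=pair.um_per_px)
        chains = extract_centerlines(mask, min_length=50.0, image=pair.image_532)
        assert len(chains) == 1
        truth = make_vessel_path(spec, 4.0)
        from scipy.spatial import cKDTree

        d_chain, _ = cKDTree(truth).query(chains[0])
        d_truth, _ = cKDTree(chains[0]).query(truth)
        assert d_chain.max() < 1.0
        # skeleton chains are end-trimmed, so truth->chain distance is only
        # checked away from the vessel tips
        interior = (truth[:, 0] > truth[0, 0] + 16) & (truth[:, 0] < truth[-1, 0] - 16)
        assert d_truth[interior].max() < 1.0


class TestSmoothCenterline:
    def test_collinear_points_stay_collinear_with_zero_curvature(self):
        cl = smooth_centerline(_straight_points())
        d = np.diff(cl.points, axis=0)
        cross = d[:-1, 0] * d[1:, 1] - d[:-1, 1] * d[1:, 0]
        assert np.abs(cross).max() < 1e-3
        assert np.abs(cl.kappa).max() < 1e-6
        assert cl.la >= cl.lc > 0

    def test_jittered_sinusoid_rmse_below_noise(self):
        rng = np.random.default_rng(7)
        pts = _sinusoid_points() + rng.normal(0.0, 0.3, (400, 2))
        cl = smooth_centerline(pts)
        truth = _sinusoid_points(n=4000)
        from scipy.spatial import cKDTree

        d, _ = cKDTree(truth).query(cl.points)
        rmse = np.sqrt(np.mean(d**2))
        assert rmse < 0.3

    def test_three_points_rejected(self):
        with pytest.raises(TooShortError):
            smooth_centerline(np.array([[0.0, 0.0], [1.0, 0.0], [2.0, 0.0]]))


class TestCriticalPoints:
    def test_straight_line_has_none(self):
        assert count_critical_points(smooth_centerline(_straight_points())) == 0

    def test_one_sine_period_has_two(self):
        cl = smooth_centerline(_sinusoid_points(k=1))
        assert count_critical_points(cl) == 2

    def test_rigid_transform_preserves_count(self):
        for angle in (0.0, 37.0, 118.0):
            cl = smooth_centerline(_sinusoid_points(k=2, angle_deg=angle, offset=(40.0, -7.0)))
            assert count_critical_points(cl) == 4


class TestInflections:
    def test_straight_line_zero(self):
        assert count_inflections(smooth_centerline(_straight_points()))[0] == 0

    def test_circular_arc_zero(self):
        th = np.linspace(0.0, 0.5 * np.pi, 200)
        cl = smooth_centerline(np.column_stack([100 * np.cos(th), 100 * np.sin(th)]))
        assert count_inflections(cl)[0] == 0

    @pytest.mark.parametrize("k", [1, 2, 3, 4])
    def test_k_period_sinusoid_has_2k_minus_1(self, k):
        cl = smooth_centerline(_sinusoid_points(k=k))
        vii, locations = count_inflections(cl)
        assert vii == 2 * k - 1
        # inflections sit at the sine's zero crossings, s ~ j*LA/(2k)
        expected = cl.la * np.arange(1, 2 * k) / (2 * k)
        assert np.allclose(sorted(locations), expected, atol=0.03 * cl.la)


class TestMeanArcChord:
    def test_straight_line_is_one(self):
        cl = smooth_centerline(_straight_points())
        vii, locs = count_inflections(cl)
        assert mean_arc_chord_ratio(cl, locs) == pytest.approx(1.0, abs=1e-6)

    def test_never_below_one(self):
        for k in (1, 2, 3):
            cl = smooth_centerline(_sinusoid_points(k=k, A=15.0))
            _, locs = count_inflections(cl)
            assert mean_arc_chord_ratio(cl, locs) >= 1.0 - 1e-9

    def test_single_period_matches_quadrature_oracle(self):
        """Oracle: numeric arc-length integral of A sin(2 pi t / L) between
        the analytic inflection point (t = L/2) and the endpoints."""
        A, L = 20.0, 200.0
        w = 2 * np.pi / L

        def speed(t):
            return math.hypot(1.0, A * w * math.cos(w * t))

        arc1, _ = quad(speed, 0.0, L / 2, limit=200)
        chord1 = math.hypot(L / 2, A * math.sin(w * L / 2))
        # the two halves are congruent
        oracle_m = arc1 / chord1
        cl = smooth_centerline(_sinusoid_points(k=1, A=A, L=L, n=2000))
        _, locs = count_inflections(cl)
        assert len(locs) == 1
        m = mean_arc_chord_ratio(cl, locs)
        assert m == pytest.approx(oracle_m, abs=1e-3)


def _finite_difference_oracle(points):
    """Independent VTI computation: dense finite differences, no splines."""
    d = np.diff(points, axis=0)
    seg = np.hypot(d[:, 0], d[:, 1])
    s = np.concatenate([[0.0], np.cumsum(seg)])
    la = s[-1]
    lc = float(np.hypot(*(points[-1] - points[0])))
    chord_ang = math.atan2(points[-1, 1] - points[0, 1], points[-1, 0] - points[0, 0])
    theta = np.unwrap(np.arctan2(d[:, 1], d[:, 0])) - chord_ang
    s_mid = 0.5 * (s[:-1] + s[1:])
    w = np.gradient(s_mid)
    mu = np.average(theta, weights=w)
    sd_theta = float(np.degrees(np.sqrt(np.average((theta - mu) ** 2, weights=w))))
    dyds = np.sin(theta)
    sign = np.where(dyds > 1e-6, 1, np.where(dyds < -1e-6, -1, 0))
    nz = sign[sign != 0]
    n_crit = int(np.sum(nz[:-1] * nz[1:] < 0))
    dtheta = np.diff(theta)
    kappa = dtheta / (0.5 * (seg[1:] + seg[:-1]))
    ks = np.where(kappa > 1e-6, 1, np.where(kappa < -1e-6, -1, 0))
    nzk = np.nonzero(ks)[0]
    flips = [
        (nzk[i], nzk[i + 1])
        for i in range(len(nzk) - 1)
        if ks[nzk[i]] * ks[nzk[i + 1]] < 0
    ]
    cut_s = [0.0] + [0.5 * (s[i + 1] + s[j + 1]) for i, j in flips] + [la]
    ratios = []
    for s0, s1 in zip(cut_s[:-1], cut_s[1:]):
        p0 = np.array([np.interp(s0, s, points[:, 0]), np.interp(s0, s, points[:, 1])])
        p1 = np.array([np.interp(s1, s, points[:, 0]), np.interp(s1, s, points[:, 1])])
        ratios.append((s1 - s0) / float(np.hypot(*(p1 - p0))))
    m = float(np.mean(ratios))
    return {
        "sd_theta": sd_theta,
        "n_critical": n_crit,
        "m_ratio": m,
        "la": la,
        "lc": lc,
        "vti": 0.1 * sd_theta * n_crit * m * la / lc,
    }


class TestVti:
    def test_straight_centerline_gives_exact_zero(self):
        rec = compute_vti(smooth_centerline(_straight_points()))
        assert rec.vti == 0.0
        assert rec.n_critical == 0

    def test_matches_finite_difference_oracle_within_2pct(self):
        pts = _sinusoid_points(k=2, A=12.0, L=220.0, n=600)
        rec = compute_vti(smooth_centerline(pts))
        oracle = _finite_difference_oracle(_sinusoid_points(k=2, A=12.0, L=220.0, n=20000))
        assert rec.n_critical == oracle["n_critical"]
        assert rec.sd_theta == pytest.approx(oracle["sd_theta"], rel=0.02)
        assert rec.m_ratio == pytest.approx(oracle["m_ratio"], rel=0.02)
        assert rec.la / rec.lc == pytest.approx(oracle["la"] / oracle["lc"], rel=0.02)
        assert rec.vti == pytest.approx(oracle["vti"], rel=0.02)

    def test_rigid_invariance_below_1e6_relative(self):
        base = _sinusoid_points(k=2)
        rec0 = compute_vti(smooth_centerline(base))
        ang = math.radians(37.0)
        rot = np.array([[math.cos(ang), -math.sin(ang)], [math.sin(ang), math.cos(ang)]])
        moved = base @ rot.T + np.array([13.0, -45.0])
        rec1 = compute_vti(smooth_centerline(moved))
        assert rec1.n_critical == rec0.n_critical
        assert rec1.vii == rec0.vii
        assert abs(rec1.vti - rec0.vti) / rec0.vti < 1e-6

    def test_scale_invariance(self):
        base = _sinusoid_points(k=2)
        rec0 = compute_vti(smooth_centerline(base))
        rec1 = compute_vti(smooth_centerline(base * 3.0))
        for attr in ("sd_theta", "m_ratio", "vti"):
            assert getattr(rec1, attr) == pytest.approx(getattr(rec0, attr), rel=1e-3)
        assert rec1.n_critical == rec0.n_critical
        assert rec1.la / rec1.lc == pytest.approx(rec0.la / rec0.lc, rel=1e-3)

    def test_vti_nondecreasing_in_amplitude(self):
        vtis = [
            compute_vti(smooth_centerline(_sinusoid_points(k=2, A=a))).vti
            for a in (2.0, 5.0, 8.0, 12.0, 18.0)
        ]
        assert all(b >= a - 1e-9 for a, b in zip(vtis, vtis[1:]))


class TestImagePipeline:
    @pytest.mark.parametrize("k", [1, 2, 3, 4])
    def test_vii_exact_on_noiseless_sinusoid_renders(self, cfg, k):
        spec = sinusoid_fixture_spec(cfg, k)
        pair, _ = render_pair([spec], cfg.render, cfg.calibration)
        table = analyze_tortuosity(pair, cfg)
        assert len(table) == 1
        assert int(table.loc[0, "vii"]) == 2 * k - 1 == spec.inflection_count_true
        assert int(table.loc[0, "n_critical"]) == 2 * k
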