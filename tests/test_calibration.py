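"""Marker assignment, log-linear calibration and mass-axis rebinning."""

import numpy as np
import pytest

from fecgel import (GelError, LadderSpec, assign_marker_masses, correct_bleed,
                    default_mass_grid, detect_bands, estimate_bleed,
                    extract_profile, fit_calibration, profile_to_mass_axis,
                    segment_lanes, subtract_background)
from fecgel.calibration import _assign_marker_masses_bruteforce
from fecgel.lanes import Band, LaneProfile
from tests.conftest import make_gel

LADDER = LadderSpec((250.0, 150.0, 100.0, 75.0, 50.0, 37.0, 25.0))


def band(distance, prominence=100.0):
    return Band(apex_distance=float(distance), height=prominence,
                prominence=float(prominence), area=1.0,
                apex_index=int(distance))


def flat_profile(y):
    y = np.asarray(y, dtype=float)
    return LaneProfile(0, "700nm", np.arange(y.size, dtype=float), y,
                       background_subtracted=True)


class TestAssignMarkerMasses:
    def test_equal_counts_pair_in_order(self):
        bands = [band(d) for d in (30, 55, 80, 110, 150, 200, 260)]
        anchors = assign_marker_masses(bands, LADDER)
        assert anchors == [(30.0, 250.0), (55.0, 150.0), (80.0, 100.0),
                           (110.0, 75.0), (150.0, 50.0), (200.0, 37.0),
                           (260.0, 25.0)]

    def test_spurious_band_dropped_like_bruteforce(self):
        bands = [band(30), band(55), band(70, prominence=8.0), band(80),
                 band(110), band(150), band(200), band(260)]
        assert (assign_marker_masses(bands, LADDER)
                == _assign_marker_masses_bruteforce(bands, LADDER))
        assert all(d != 70.0 for d, _ in assign_marker_masses(bands, LADDER))

    def test_random_surplus_matches_bruteforce(self, rng):
        """Fast top-k selection equals the exhaustive order-preserving
        subset search for random prominences."""
        for _ in range(25):
            n = int(rng.integers(7, 11))
            dists = np.sort(rng.choice(np.arange(20, 300), n, replace=False))
            bands = [band(float(d), prominence=float(rng.integers(1, 1000)))
                     for d in dists]
            assert (assign_marker_masses(bands, LADDER)
                    == _assign_marker_masses_bruteforce(bands, LADDER))

    def test_insufficient_bands(self):
        with pytest.raises(GelError, match="insufficient marker bands"):
            assign_marker_masses([band(d) for d in (30, 60, 90, 120, 150)],
                                 LADDER)


class TestFitCalibration:
    def test_midpoint_is_geometric_mean(self):
        curve = fit_calibration([(10.0, 100.0), (110.0, 10.0)])
        assert curve.mass(60.0) == pytest.approx(10 ** 1.5, rel=1e-12)

    def test_end_segment_extrapolation(self):
        curve = fit_calibration([(10.0, 100.0), (110.0, 10.0)])
        assert curve.mass(160.0) == pytest.approx(10 ** 0.5, rel=1e-12)
        assert curve.is_extrapolated(160.0)
        assert not curve.is_extrapolated(60.0)

    def test_exact_log_linear_law_recovered(self, rng):
        """Anchors sampled from d = a - b*log10(M): the interpolant must
        reproduce the law to machine precision everywhere."""
        a, b = 424.0, 164.0
        masses = np.array([250.0, 150.0, 100.0, 75.0, 50.0, 37.0, 25.0])
        anchors = [(a - b * np.log10(m), m) for m in masses]
        curve = fit_calibration(anchors)
        d = rng.uniform(20.0, 300.0, size=1000)
        expected = 10 ** ((a - d) / b)
        np.testing.assert_allclose(curve.mass(d), expected, rtol=1e-12)

    def test_passes_through_anchors_exactly(self):
        anchors = [(30.0, 250.0), (80.0, 100.0), (150.0, 50.0), (260.0, 25.0)]
        curve = fit_calibration(anchors)
        for d, m in anchors:
            assert curve.mass(d) == pytest.approx(m, rel=1e-14)

    def test_strictly_decreasing(self):
        curve = fit_calibration([(30.0, 250.0), (150.0, 50.0), (260.0, 25.0)])
        d = np.linspace(0.0, 300.0, 500)
        assert np.all(np.diff(curve.mass(d)) < 0)

    def test_non_monotone_anchors_rejected(self):
        with pytest.raises(GelError):
            fit_calibration([(30.0, 250.0), (20.0, 100.0)])
        with pytest.raises(GelError):
            fit_calibration([(30.0, 100.0), (60.0, 250.0)])
        with pytest.raises(GelError, match="at least 2"):
            fit_calibration([(30.0, 100.0)])


class TestProfileToMassAxis:
    CURVE = fit_calibration([(20.0, 250.0), (280.0, 10.0)])

    def test_total_intensity_conserved(self, rng):
        # grid chosen to cover the whole mass span of a 300 px profile
        y = rng.random(300) * 100.0
        grid = default_mass_grid(500, top_kda=330.0, bottom_kda=7.0)
        mp = profile_to_mass_axis(flat_profile(y), self.CURVE, grid)
        assert mp.total == pytest.approx(y.sum(), rel=0.005)

    def test_single_pixel_spike_lands_in_overlapping_cells(self):
        """All intensity of a one-pixel spike lands in the grid cells that
        overlap [mass(d+1), mass(d)), split by direct interval overlap."""
        grid = default_mass_grid(200)
        d = 137
        y = np.zeros(300)
        y[d] = 1000.0
        mp = profile_to_mass_axis(flat_profile(y), self.CURVE, grid)
        lo, hi = self.CURVE.log_mass(d + 1), self.CURVE.log_mass(d)
        centers = np.log10(grid)
        mids = 0.5 * (centers[:-1] + centers[1:])
        edges_hi = np.concatenate([[centers[0] + (centers[0] - mids[0])],
                                   mids])
        edges_lo = np.concatenate([mids,
                                   [centers[-1] - (mids[-1] - centers[-1])]])
        expected = np.array([
            max(0.0, min(hi, eh) - max(lo, el)) / (hi - lo) * 1000.0
            for eh, el in zip(edges_hi, edges_lo)])
        np.testing.assert_allclose(mp.intensities, expected, atol=1e-9)
        assert mp.total == pytest.approx(1000.0, rel=1e-9)

    def test_zero_profile_maps_to_zero(self):
        mp = profile_to_mass_axis(flat_profile(np.zeros(300)), self.CURVE,
                                  default_mass_grid())
        assert np.all(mp.intensities == 0.0)

    def test_rebinning_is_linear(self, rng):
        p = rng.random(300) * 50.0
        q = rng.random(300) * 20.0
        grid = default_mass_grid()
        a, b = 2.5, 0.75
        combo = profile_to_mass_axis(flat_profile(a * p + b * q),
                                     self.CURVE, grid)
        mp = profile_to_mass_axis(flat_profile(p), self.CURVE, grid)
        mq = profile_to_mass_axis(flat_profile(q), self.CURVE, grid)
        np.testing.assert_allclose(combo.intensities,
                                   a * mp.intensities + b * mq.intensities,
                                   rtol=1e-9, atol=1e-9)

    def test_increasing_grid_rejected(self):
        with pytest.raises(GelError, match="strictly decreasing"):
            profile_to_mass_axis(flat_profile(np.ones(100)), self.CURVE,
                                 np.array([10.0, 50.0, 100.0]))


class TestBleedCorrection:
    def test_recovers_simulated_bleed_coefficient(self):
        (img, truth), cfg = make_gel(noise_sigma=8.0, bleed_k=0.15, seed=9)
        geom = truth.geometry
        lanes = segment_lanes(geom, cfg.n_lanes)
        k = estimate_bleed(img, geom, lanes, "700nm", "800nm",
                           marker_lanes=(0,))
        assert k == pytest.approx(0.15, abs=0.03)

    def test_correction_cleans_marker_lane_detection(self):
        """With strong bleed, sample bands contaminate the marker channel;
        after correction the marker lane still yields exactly 7 bands and
        the sample lanes lose their ghosts."""
        (img, truth), cfg = make_gel(noise_sigma=5.0, bleed_k=0.3, seed=10)
        geom = truth.geometry
        lanes = segment_lanes(geom, cfg.n_lanes)
        k = estimate_bleed(img, geom, lanes, "700nm", "800nm", (0,))
        corrected = correct_bleed(img, k, "700nm", "800nm")
        ghosts_before = detect_bands(subtract_background(
            extract_profile(img, geom, lanes[1], "800nm")),
            absolute_prominence=1000.0)
        ghosts_after = detect_bands(subtract_background(
            extract_profile(corrected, geom, lanes[1], "800nm")),
            absolute_prominence=1000.0)
        assert len(ghosts_before) > 0
        assert len(ghosts_after) == 0
        marker = detect_bands(subtract_background(
            extract_profile(corrected, geom, lanes[0], "800nm")), 0.05)
        assert len(marker) == 7


class TestLadderSpec:
    def test_validation(self):
        with pytest.raises(GelError):
            LadderSpec((250.0,))
        with pytest.raises(GelError):
            LadderSpec((100.0, 150.0))
        with pytest.raises(GelError):
            LadderSpec((100.0, -5.0))
        assert len(LadderSpec((250.0, 25.0))) == 2
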