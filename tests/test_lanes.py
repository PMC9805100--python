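"""Lane segmentation, profile extraction, background and band detection."""

import numpy as np
import pytest

from fecgel import (GelError, GelImage, detect_bands, extract_profile,
                    segment_lanes, subtract_background)
from fecgel.image import GelGeometry
from fecgel.lanes import LaneProfile
from tests.conftest import make_gel


def profile(y, subtracted=True, lane=0, channel="700nm"):
    y = np.asarray(y, dtype=float)
    return LaneProfile(lane, channel, np.arange(y.size, dtype=float), y,
                       background_subtracted=subtracted)


def brute_force_prominences(y):
    """Independent topographic-prominence computation by direct search.

    For each strict local maximum, walk left and right to the nearest
    higher ground; the prominence is the peak height minus the higher of
    the two deepest saddles on the way (or the global minimum of the
    traversed stretch when no higher peak exists on that side).
    """
    y = np.asarray(y, dtype=float)
    out = {}
    for i in range(1, y.size - 1):
        if not (y[i] > y[i - 1] and y[i] >= y[i + 1]):
            continue
        if y[i] == y[i + 1]:  # plateau handled by leftmost convention
            j = i
            while j < y.size - 1 and y[j + 1] == y[i]:
                j += 1
            if j == y.size - 1 or y[j + 1] > y[i]:
                continue
        saddles = []
        for sl in (slice(i, None, -1), slice(i, None, 1)):
            seg = y[sl]
            higher = np.nonzero(seg > y[i])[0]
            saddles.append(seg[:higher[0]].min() if higher.size
                           else seg.min())
        out[i] = y[i] - max(saddles)
    return out


class TestSegmentLanes:
    def test_exact_division(self):
        geom = GelGeometry(0, 150, 10, 100)
        lanes = segment_lanes(geom, 10)
        assert [l.width for l in lanes] == [15] * 10
        assert lanes[0].left_col == 0 and lanes[-1].right_col == 150
        for a, b in zip(lanes, lanes[1:]):
            assert a.right_col == b.left_col

    def test_remainder_distributed_from_left(self):
        geom = GelGeometry(0, 152, 10, 100)
        widths = [l.width for l in segment_lanes(geom, 10)]
        assert widths == [16, 16, 15, 15, 15, 15, 15, 15, 15, 15]
        assert sum(widths) == 152

    def test_too_many_lanes(self):
        geom = GelGeometry(0, 5, 10, 100)
        with pytest.raises(GelError, match="exceed gel width"):
            segment_lanes(geom, 6)

    def test_true_lane_centers_inside_assigned_lanes(self, clean_gel):
        img, truth, cfg = clean_gel
        geom = truth.geometry
        lanes = segment_lanes(geom, cfg.n_lanes)
        for i, (left, right) in enumerate(truth.lane_bounds):
            centre = 0.5 * (left + right)
            assert lanes[i].left_col <= centre < lanes[i].right_col


class TestExtractProfile:
    def test_constant_field(self):
        img = GelImage(np.ones((1, 120, 100)), ("700nm",))
        geom = GelGeometry(0, 100, 20, 110)
        lanes = segment_lanes(geom, 5)  # width 20... use lane of width 15?
        p = extract_profile(img, geom, lanes[0], "700nm")
        assert np.all(p.intensities == lanes[0].width)
        assert p.intensities.size == geom.n_distances
        assert not p.background_subtracted

    def test_gaussian_band_integral_closed_form(self):
        """A per-column Gaussian band of amplitude A integrates to
        A * sigma * sqrt(2*pi) * lane_width within 1 %."""
        amplitude, sigma, width = 250.0, 4.0, 15
        rows = np.arange(200, dtype=float)
        column = amplitude * np.exp(-0.5 * ((rows - 90.0) / sigma) ** 2)
        px = np.tile(column[:, None], (1, width))
        img = GelImage(px[np.newaxis], ("700nm",))
        geom = GelGeometry(0, width, 0, 200)
        p = extract_profile(img, geom, segment_lanes(geom, 1)[0], "700nm")
        expected = amplitude * sigma * np.sqrt(2 * np.pi) * width
        assert p.total == pytest.approx(expected, rel=0.01)

    def test_unknown_channel(self, clean_gel):
        img, truth, cfg = clean_gel
        geom = truth.geometry
        lane = segment_lanes(geom, cfg.n_lanes)[0]
        with pytest.raises(GelError, match="unknown channel"):
            extract_profile(img, geom, lane, "900nm")

    def test_lane_totals_partition_gel_intensity_exactly(self, clean_gel):
        """Equal-width lanes partition the gel columns, so the sum of all
        lane-profile totals equals the gel-region total exactly."""
        img, truth, cfg = clean_gel
        geom = truth.geometry
        lanes = segment_lanes(geom, cfg.n_lanes)
        for ch in img.channels:
            region = img.channel(ch)[geom.resolving_top_row:geom.bottom_row,
                                     geom.left_col:geom.right_col]
            total = sum(extract_profile(img, geom, l, ch).total
                        for l in lanes)
            assert total == pytest.approx(region.sum(), rel=1e-12)


class TestSubtractBackground:
    def test_constant_profile_vanishes(self):
        out = subtract_background(profile(np.full(200, 37.0),
                                          subtracted=False))
        assert np.all(out.intensities == 0.0)
        assert out.background_subtracted

    def test_gaussian_peak_on_offset_preserved(self):
        d = np.arange(300, dtype=float)
        y = 100.0 + 500.0 * np.exp(-0.5 * ((d - 150.0) / 3.0) ** 2)
        out = subtract_background(profile(y, subtracted=False), window=51)
        assert out.intensities.max() == pytest.approx(500.0, rel=0.02)

    def test_idempotent_on_zero_baseline(self):
        d = np.arange(300, dtype=float)
        y = 500.0 * np.exp(-0.5 * ((d - 150.0) / 3.0) ** 2)
        once = subtract_background(profile(y, subtracted=False), window=51)
        twice = subtract_background(once, window=51)
        np.testing.assert_allclose(twice.intensities, once.intensities,
                                   atol=1e-9)

    def test_window_validation(self):
        with pytest.raises(GelError, match=">= 3"):
            subtract_background(profile(np.ones(100), subtracted=False),
                                window=2)
        with pytest.raises(GelError, match="exceeds profile length"):
            subtract_background(profile(np.ones(40), subtracted=False),
                                window=51)


class TestDetectBands:
    def test_lone_gaussian_peak(self):
        d = np.arange(300, dtype=float)
        y = 400.0 * np.exp(-0.5 * ((d - 120.0) / 3.0) ** 2)
        bands = detect_bands(profile(y))
        assert len(bands) == 1
        assert bands[0].apex_distance == pytest.approx(120.0, abs=0.01)
        assert bands[0].prominence <= bands[0].height
        assert bands[0].area > 0

    def test_absolute_threshold_matches_bruteforce(self):
        """Only the peak whose exhaustively-computed prominence clears an
        absolute threshold of 50 survives."""
        d = np.arange(60, dtype=float)
        y = (100.0 * np.exp(-0.5 * ((d - 20.0) / 2.0) ** 2)
             + 10.0 * np.exp(-0.5 * ((d - 45.0) / 2.0) ** 2))
        ref = brute_force_prominences(y)
        expected = sorted(i for i, p in ref.items() if p >= 50.0)
        got = detect_bands(profile(y), absolute_prominence=50.0)
        assert [b.apex_index for b in got] == expected == [20]

    def test_prominences_match_bruteforce_on_random_profiles(self, rng):
        """find_peaks-based prominences equal the independent direct-search
        values on rough random profiles."""
        for _ in range(20):
            y = np.round(rng.random(80) * 100.0)
            ref = brute_force_prominences(y)
            got = detect_bands(profile(y), absolute_prominence=1e-9)
            for band in got:
                assert band.prominence == pytest.approx(
                    ref[band.apex_index], abs=1e-9)

    def test_simulator_marker_lane_bands(self):
        """All 7 ladder bands found within 2 px of truth at SNR ~20."""
        (img, truth), cfg = make_gel(noise_sigma=20.0, seed=7)
        geom = truth.geometry
        lane = segment_lanes(geom, cfg.n_lanes)[0]
        p = subtract_background(extract_profile(img, geom, lane, "800nm"))
        bands = detect_bands(p, min_prominence=0.05)
        assert len(bands) == 7
        true_d = sorted(tb.distance_px for tb in truth.bands
                        if tb.channel == "800nm")
        for band, td in zip(bands, true_d):
            assert band.apex_distance == pytest.approx(td, abs=2.0)

    def test_scaling_invariance(self, rng):
        y = np.abs(rng.normal(0, 1, 200)).cumsum() % 50
        a = detect_bands(profile(y), min_prominence=0.2)
        b = detect_bands(profile(y * 123.4), min_prominence=0.2)
        assert [x.apex_index for x in a] == [x.apex_index for x in b]

    def test_band_count_monotone_in_threshold(self, rng):
        y = np.round(rng.random(150) * 100.0)
        counts = [len(detect_bands(profile(y), min_prominence=t))
                  for t in (0.01, 0.05, 0.2, 0.5, 0.9)]
        assert counts == sorted(counts, reverse=True)

    def test_plateau_apex_is_leftmost_sample(self):
        y = np.array([0, 1, 5, 5, 5, 1, 0], dtype=float)
        bands = detect_bands(profile(y), min_prominence=0.5)
        assert len(bands) == 1
        assert bands[0].apex_distance == 2.0

    def test_requires_background_subtraction(self):
        with pytest.raises(GelError, match="background-subtracted"):
            detect_bands(profile(np.ones(10), subtracted=False))

    def test_empty_profile_returns_no_bands(self):
        assert detect_bands(profile(np.zeros(50))) == []
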