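"""Sliding-rate quantification: zone definition, motile-fraction counting,
window-selection slope fits and control normalization."""

import numpy as np
import pandas as pd
import pytest

import mtquant as mq
from mtquant.prep import MaskStack
from mtquant.sliding import EmptyMaskError, _ols


def flood_fill_from_border(mask):
    """Oracle: fill holes by BFS from the image border over the complement."""
    from collections import deque

    h, w = mask.shape
    outside = np.zeros_like(mask, dtype=bool)
    queue = deque()
    for r in range(h):
        for c in (0, w - 1):
            if not mask[r, c] and not outside[r, c]:
                outside[r, c] = True
                queue.append((r, c))
    for c in range(w):
        for r in (0, h - 1):
            if not mask[r, c] and not outside[r, c]:
                outside[r, c] = True
                queue.append((r, c))
    while queue:
        r, c = queue.popleft()
        for dr, dc in ((1, 0), (-1, 0), (0, 1), (0, -1)):
            rr, cc = r + dr, c + dc
            if 0 <= rr < h and 0 <= cc < w and not mask[rr, cc] \
                    and not outside[rr, cc]:
                outside[rr, cc] = True
                queue.append((rr, cc))
    return ~outside


def enumerate_window_fit(times, fraction, min_points=5, r2_threshold=0.9):
    """Oracle: enumerate windows starting at t=0 with polyfit-based OLS."""
    n = len(times)
    best = None
    candidates = []
    for hi in range(min_points - 1, n):
        x, y = times[:hi + 1], fraction[:hi + 1]
        slope, intercept = np.polyfit(x, y, 1)
        resid = y - (slope * x + intercept)
        ss_tot = ((y - y.mean()) ** 2).sum()
        r2 = 1.0 - resid @ resid / ss_tot if ss_tot > 0 else 1.0
        candidates.append((hi, slope, r2))
    qualifying = [c for c in candidates if c[2] >= r2_threshold]
    if qualifying:
        return max(qualifying, key=lambda c: c[0])
    return max(candidates, key=lambda c: c[2])


class TestDefineInitialZone:
    def test_all_true_mask_gives_whole_frame(self):
        zone = mq.define_initial_zone(np.ones((10, 10), bool))
        assert zone.mask.all()

    def test_filled_disc_maps_to_itself(self):
        mask = np.zeros((40, 40), bool)
        rr, cc = np.ogrid[:40, :40]
        disc = (rr - 20) ** 2 + (cc - 20) ** 2 <= 100
        zone = mq.define_initial_zone(disc)
        assert (zone.mask & disc).sum() == disc.sum()

    def test_annulus_fills_to_disc(self):
        mask = np.zeros((50, 50), bool)
        rr, cc = np.ogrid[:50, :50]
        d2 = (rr - 25) ** 2 + (cc - 25) ** 2
        annulus = (d2 <= 144) & (d2 >= 64)
        zone = mq.define_initial_zone(annulus)
        np.testing.assert_array_equal(zone.mask,
                                      flood_fill_from_border(annulus))

    def test_user_roi_disc(self):
        zone = mq.define_initial_zone(np.zeros((30, 30), bool),
                                      mode="user_roi", center=(15, 15),
                                      radius=5)
        assert zone.mask[15, 15]
        assert not zone.mask[15, 25]
        assert zone.provenance["mode"] == "user_roi"

    def test_empty_mask_rejected(self):
        with pytest.raises(EmptyMaskError, match="no conversion"):
            mq.define_initial_zone(np.zeros((10, 10), bool))


class TestMotileFraction:
    def _zone(self, shape=(10, 10)):
        mask = np.zeros(shape, bool)
        mask[:, :5] = True
        return mq.ConversionZone(mask=mask, provenance={})

    def test_all_inside_zero(self):
        zone = self._zone()
        m = np.zeros((10, 10), bool)
        m[2:4, 1:4] = True
        assert mq.motile_fraction(m, zone) == 0.0

    def test_all_outside_one(self):
        zone = self._zone()
        m = np.zeros((10, 10), bool)
        m[2:4, 6:9] = True
        assert mq.motile_fraction(m, zone) == 1.0

    def test_partial_counts(self):
        zone = self._zone()
        m = np.zeros((10, 10), bool)
        m[0, :5] = True      # 5 inside
        m[1, 5:8] = True     # 3 outside
        assert mq.motile_fraction(m, zone) == pytest.approx(3 / 8)

    def test_empty_mask_raises(self):
        with pytest.raises(EmptyMaskError):
            mq.motile_fraction(np.zeros((10, 10), bool), self._zone())


class TestMotileFractionSeries:
    def test_translating_block_matches_pixel_counts(self):
        # 4x4 block translating right at 1 px/frame, zone = left half-plane
        T, shape = 6, (12, 24)
        zone_mask = np.zeros(shape, bool)
        zone_mask[:, :8] = True
        zone = mq.ConversionZone(mask=zone_mask, provenance={})
        masks = np.zeros((T,) + shape, bool)
        for t in range(T):
            masks[t, 4:8, 4 + t:8 + t] = True
        series = mq.motile_fraction_series(MaskStack(masks=masks), zone, 1.0)
        for t in range(T):
            outside = masks[t, :, 8:].sum()
            assert series.fraction[t] == pytest.approx(outside / 16)

    def test_flagged_frames_dropped_with_gap(self):
        shape = (8, 8)
        zone = mq.ConversionZone(mask=np.ones(shape, bool), provenance={})
        masks = np.ones((5,) + shape, bool)
        masks[2] = False
        series = mq.motile_fraction_series(MaskStack(masks=masks), zone, 2.0)
        assert series.dropped_frames == [2]
        np.testing.assert_array_equal(series.times, [0, 2, 6, 8])

    def test_too_few_valid_frames_raises(self):
        zone = mq.ConversionZone(mask=np.ones((4, 4), bool), provenance={})
        masks = np.zeros((5, 4, 4), bool)
        masks[0] = masks[1] = True
        with pytest.raises(EmptyMaskError, match="insufficient"):
            mq.motile_fraction_series(MaskStack(masks=masks), zone, 1.0)

    def test_zero_velocity_noiseless_movie_fraction_zero(self):
        p = mq.SlidingSimParams(velocity=0.0, noise_model="none",
                                bleach_rate=0.0, n_frames=5, seed=9)
        sim = mq.simulate_sliding_movie(p)
        est, series = mq.analyze_movie(sim.to_movie())
        np.testing.assert_array_equal(series.fraction, 0.0)
        assert est.slope == 0.0
        assert est.degenerate


class TestFitSlidingRate:
    def _series(self, times, fraction):
        times = np.asarray(times, float)
        fraction = np.asarray(fraction, float)
        return mq.MotileFractionSeries(
            times=times, fraction=fraction,
            pixels_total=np.full(len(times), 100),
            pixels_outside=(fraction * 100).astype(int))

    def test_perfect_line_recovered(self):
        t = np.arange(11.0)
        est = mq.fit_sliding_rate(self._series(t, 0.02 * t))
        assert est.slope == pytest.approx(0.02, abs=1e-12)
        assert est.r_squared == pytest.approx(1.0)
        assert est.fit_window == (0, 10)

    def test_constant_series_degenerate(self):
        est = mq.fit_sliding_rate(self._series(np.arange(6.0),
                                               np.full(6, 0.3)))
        assert est.slope == 0.0
        assert est.r_squared == 1.0
        assert est.degenerate

    def test_plateau_matches_enumeration_oracle(self):
        t = np.arange(11.0)
        y = np.minimum(0.02 * t, 0.10)
        series = self._series(t, y)
        est = mq.fit_sliding_rate(series)
        hi, slope, r2 = enumerate_window_fit(t, y)
        assert est.fit_window == (0, hi)
        assert est.slope == pytest.approx(slope, abs=1e-12)
        assert est.r_squared == pytest.approx(r2, abs=1e-12)

    def test_ols_matches_closed_form(self, rng):
        t = np.arange(8.0)
        y = 0.01 * t + rng.normal(0, 0.005, 8)
        y = np.clip(y, 0, 1)
        est = mq.fit_sliding_rate(self._series(t, y), policy="full")
        slope, intercept = np.polyfit(t, y, 1)
        assert est.slope == pytest.approx(slope, abs=1e-12)
        assert est.intercept == pytest.approx(intercept, abs=1e-12)

    def test_fixed_policy_uses_first_k(self):
        t = np.arange(10.0)
        y = np.minimum(0.02 * t, 0.08)
        est = mq.fit_sliding_rate(self._series(t, y), policy="fixed",
                                  first_k=4)
        assert est.fit_window == (0, 3)
        assert est.slope == pytest.approx(0.02, abs=1e-12)


class TestNormalizeToControl:
    def test_control_mean_exactly_one(self):
        df = pd.DataFrame({
            "group": ["control"] * 4 + ["kd"] * 3,
            "slope": [0.8, 1.1, 1.3, 0.9, 2.0, 2.5, 1.8],
        })
        out = mq.normalize_to_control(df)
        assert out.loc[out.group == "control", "normalized_rate"].mean() == \
            pytest.approx(1.0, abs=1e-15)

    def test_all_equal_rates_normalize_to_one(self):
        df = pd.DataFrame({"group": ["control", "control", "kd"],
                           "slope": [2.0, 2.0, 2.0]})
        out = mq.normalize_to_control(df)
        np.testing.assert_allclose(out.normalized_rate, 1.0)

    def test_simple_ratio(self):
        df = pd.DataFrame({"group": ["control", "control", "kd", "kd"],
                           "slope": [1.0, 1.0, 2.0, 4.0]})
        out = mq.normalize_to_control(df)
        np.testing.assert_allclose(
            out.loc[out.group == "kd", "normalized_rate"], [2.0, 4.0])

    def test_per_batch_normalization(self):
        df = pd.DataFrame({
            "group": ["control", "kd", "control", "kd"],
            "batch": [1, 1, 2, 2],
            "slope": [1.0, 2.0, 4.0, 4.0],
        })
        out = mq.normalize_to_control(df)
        np.testing.assert_allclose(
            out.loc[out.group == "kd", "normalized_rate"], [2.0, 1.0])

    def test_missing_control_raises(self):
        df = pd.DataFrame({"group": ["kd"], "slope": [1.0]})
        with pytest.raises(ValueError, match="control"):
            mq.normalize_to_control(df)

    def test_zero_control_mean_raises(self):
        df = pd.DataFrame({"group": ["control", "control"],
                           "slope": [1.0, -1.0]})
        with pytest.raises(ZeroDivisionError):
            mq.normalize_to_control(df)


class TestParameterRecovery:
    def test_noiseless_recovery_close_to_ground_truth(self):
        p = mq.SlidingSimParams(noise_model="none", seed=21)
        sim = mq.simulate_sliding_movie(p)
        zone = mq.define_initial_zone(sim.stack[0] > 0, mode="user_roi",
                                      center=p.zone_center,
                                      radius=p.zone_radius)
        est, _ = mq.analyze_movie(sim.to_movie(), zone=zone)
        gt = _ols(np.arange(11.0), sim.ground_truth_motile_fraction)[0]
        assert est.slope == pytest.approx(gt, rel=0.25)

    def test_doubling_velocity_doubles_slope(self):
        # paired seeds isolate the velocity effect on identical geometry
        ratios = []
        for seed in range(5):
            slopes = []
            for v in (0.15, 0.30):
                p = mq.SlidingSimParams(velocity=v, noise_model="none",
                                        seed=seed)
                sim = mq.simulate_sliding_movie(p)
                zone = mq.define_initial_zone(
                    sim.stack[0] > 0, mode="user_roi",
                    center=p.zone_center, radius=p.zone_radius)
                est, _ = mq.analyze_movie(sim.to_movie(), zone=zone)
                slopes.append(est.slope)
            ratios.append(slopes[1] / slopes[0])
        assert np.mean(ratios) == pytest.approx(2.0, rel=0.10)
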