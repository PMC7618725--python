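"""Threshold calibration, ternary binarization, spread counts, GAS."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from hypothesis.extra import numpy as hnp

import gaspread as g
from conftest import make_bandpower

BANDS = ("beta", "gamma", "high_gamma")


class TestCalibrateThresholds:
    def test_constant_values_give_degenerate_thresholds(self):
        bps = [make_bandpower(np.full((3, 2, 3, 10), 4.2)) for _ in range(3)]
        th = g.calibrate_thresholds(bps)
        assert np.allclose(th.sd, 0.0)
        assert np.allclose(th.upper, 4.2) and np.allclose(th.lower, 4.2)
        # downstream: strict inequalities -> all states 0
        am = g.binarize_activation(bps[0], th)
        assert np.all(am.state == 0)

    def test_standard_normal_values_give_plus_minus_two(self, rng):
        bps = [make_bandpower(rng.standard_normal((1, 4, 3, 500)))
               for _ in range(10)]
        th = g.calibrate_thresholds(bps)
        se = 3.0 / np.sqrt(10 * 500)  # generous Monte-Carlo band
        assert np.all(np.abs(th.upper - 2.0) < 3 * se + 0.1)
        assert np.all(np.abs(th.lower + 2.0) < 3 * se + 0.1)

    def test_participant_order_irrelevant(self, rng):
        bps = [make_bandpower(rng.normal(size=(2, 3, 3, 20))) for _ in range(4)]
        a = g.calibrate_thresholds(bps)
        b = g.calibrate_thresholds(bps[::-1])
        np.testing.assert_allclose(a.center, b.center)
        np.testing.assert_allclose(a.sd, b.sd)

    def test_single_participant_rejected(self, rng):
        with pytest.raises(ValueError, match="2 HC"):
            g.calibrate_thresholds([make_bandpower(rng.normal(size=(2, 3, 3, 20)))])

    def test_grid_mismatch_rejected(self, rng):
        a = make_bandpower(rng.normal(size=(2, 3, 3, 20)))
        b = make_bandpower(rng.normal(size=(2, 4, 3, 20)))
        with pytest.raises(ValueError, match="match"):
            g.calibrate_thresholds([a, b])

    def test_csv_roundtrip(self, rng, tmp_path):
        from gaspread.io import read_thresholds, write_thresholds
        th = g.calibrate_thresholds(
            [make_bandpower(rng.normal(size=(2, 5, 3, 20))) for _ in range(3)])
        write_thresholds(tmp_path / "th.csv", th)
        back = read_thresholds(tmp_path / "th.csv")
        np.testing.assert_allclose(back.center, th.center)
        np.testing.assert_allclose(back.upper, th.upper)
        assert back.band_names == th.band_names


class TestBinarize:
    def make_thresholds(self, n_regions=2, center=0.0, sd=1.0):
        return g.ThresholdTable(center=np.full((n_regions, 3), center),
                                sd=np.full((n_regions, 3), sd),
                                band_names=BANDS)

    def test_strict_inequality_at_boundary(self):
        th = self.make_thresholds()
        v = np.zeros((1, 2, 3, 4))
        v[0, 0, 0, 0] = 2.0    # exactly upper -> 0
        v[0, 0, 0, 1] = 2.0001  # above -> +1
        v[0, 1, 2, 2] = -2.0   # exactly lower -> 0
        v[0, 1, 2, 3] = -2.1   # below -> -1
        am = g.binarize_activation(make_bandpower(v), th)
        assert am.state[0, 0, 0, 0] == 0
        assert am.state[0, 0, 0, 1] == 1
        assert am.state[0, 1, 2, 2] == 0
        assert am.state[0, 1, 2, 3] == -1

    def test_gaussian_noise_tail_rates_match_phi_of_two(self, rng):
        """HC scored on their own calibration: each tail ~ Phi(-2) = 2.28%."""
        bps = [make_bandpower(rng.standard_normal((1, 20, 3, 60)))
               for _ in range(15)]
        th = g.calibrate_thresholds(bps)
        states = np.concatenate(
            [g.binarize_activation(bp, th, statistic="trial_mean").state
             for bp in bps])
        up = (states == 1).mean() * 100
        lo = (states == -1).mean() * 100
        assert abs(up - 2.28) < 1.0
        assert abs(lo - 2.28) < 1.0

    def test_planted_burst_detected_in_place(self, rng):
        """A strong planted excursion flips exactly its own cells to +1."""
        base = rng.standard_normal((4, 6, 3, 60)) * 0.1
        v = base.copy()
        v[:, 3, 1, 25:35] += 50.0
        th = self.make_thresholds(n_regions=6)
        am = g.binarize_activation(make_bandpower(v), th)
        assert np.all(am.state[:, 3, 1, 25:35] == 1)
        untouched = am.state.copy()
        untouched[:, 3, 1, 25:35] = 0
        assert np.all(untouched == 0)  # nothing else crosses +-2 at sd 0.1

    def test_nonfinite_rejected(self):
        v = np.zeros((1, 2, 3, 4)); v[0, 0, 0, 0] = np.nan
        with pytest.raises(ValueError, match="finite"):
            g.binarize_activation(make_bandpower(v), self.make_thresholds())


class TestSpread:
    def test_all_zero_states(self):
        am = g.ActivationMap(state=np.zeros((3, 5, 3, 8), dtype=np.int8),
                             band_names=BANDS,
                             bin_edges=-1 + 0.1 * np.arange(9))
        s = g.spread_timeseries(am)
        assert np.all(s.activated_count == 0) and np.all(s.deactivated_count == 0)

    def test_saturation_counts_all_regions(self):
        state = np.zeros((2, 52, 3, 6), dtype=np.int8)
        state[:, :, 1, 3] = 1
        am = g.ActivationMap(state=state, band_names=BANDS,
                             bin_edges=0.1 * np.arange(7))
        s = g.spread_timeseries(am)
        assert s.activated_count[1, 3] == 52

    def test_trial_average_is_arithmetic_mean(self):
        state = np.zeros((60, 12, 3, 1), dtype=np.int8)
        state[:30, :10, 0, 0] = 1  # 30 trials with 10 regions, 30 with none
        am = g.ActivationMap(state=state, band_names=BANDS,
                             bin_edges=np.array([0.0, 0.1]))
        s = g.spread_timeseries(am)
        assert s.activated_count[0, 0] == pytest.approx(5.0)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(hnp.arrays(np.int8, (4, 3, 2, 5), elements=st.integers(-1, 1)))
    def test_matches_exhaustive_hand_count(self, state):
        """Counts agree with a direct per-trial enumeration on toy arrays,
        and states partition the regions at every trial x band x bin."""
        am = g.ActivationMap(state=state, band_names=("gamma", "high_gamma"),
                             bin_edges=0.1 * np.arange(6))
        s = g.spread_timeseries(am)
        n_trials, n_regions, n_bands, n_bins = state.shape
        for bi in range(n_bands):
            for k in range(n_bins):
                plus = sum((state[tr, :, bi, k] == 1).sum()
                           for tr in range(n_trials)) / n_trials
                minus = sum((state[tr, :, bi, k] == -1).sum()
                            for tr in range(n_trials)) / n_trials
                neither = sum((state[tr, :, bi, k] == 0).sum()
                              for tr in range(n_trials)) / n_trials
                assert s.activated_count[bi, k] == pytest.approx(plus)
                assert s.deactivated_count[bi, k] == pytest.approx(minus)
                assert plus + minus + neither == pytest.approx(n_regions)

    def test_raising_multiplier_never_increases_counts(self, rng):
        bps = [make_bandpower(rng.standard_normal((3, 6, 3, 40)))
               for _ in range(4)]
        counts = []
        for mult in (2.0, 3.0):
            th = g.calibrate_thresholds(bps, sd_multiplier=mult)
            s = g.spread_timeseries(g.binarize_activation(bps[0], th))
            counts.append(s.activated_count)
        assert np.all(counts[1] <= counts[0])


class TestGAS:
    def make_spread(self, activated, t_start=-1.0):
        n_bins = activated.shape[1]
        return g.SpreadSeries(activated_count=activated,
                              deactivated_count=np.zeros_like(activated),
                              band_names=("gamma",),
                              bin_edges=t_start + 0.1 * np.arange(n_bins + 1))

    def test_constant_count_passes_through(self):
        s = self.make_spread(np.full((1, 60), 7.0))
        assert g.compute_gas(s).gas == pytest.approx(7.0)

    def test_window_mean_of_split_signal(self):
        a = np.zeros((1, 60))
        centers = s_centers = -1.0 + 0.1 * np.arange(60) + 0.05
        a[0, (centers >= 1) & (centers <= 2)] = 20.0
        s = self.make_spread(a)
        assert g.compute_gas(s).gas == pytest.approx(10.0)

    def test_default_window_selects_twenty_bins(self):
        """Bin-center rule on the -1..5 s epoch: centers 1.05..2.95 s."""
        s = self.make_spread(np.arange(60, dtype=float)[None])
        centers = s.bin_centers()
        expected = [i for i, c in enumerate(centers) if 1.0 <= c <= 3.0]
        assert len(expected) == 20
        assert g.compute_gas(s).gas == pytest.approx(
            np.arange(60)[expected].mean())

    def test_center_exactly_at_endpoint_included(self):
        # grid shifted so a center lands exactly on 1.0 s
        s = self.make_spread(np.ones((1, 60)), t_start=-1.05)
        centers = s.bin_centers()
        assert np.any(np.isclose(centers, 1.0))
        assert g.compute_gas(s).gas == pytest.approx(1.0)

    def test_empty_window_rejected(self):
        s = self.make_spread(np.ones((1, 10)))
        with pytest.raises(ValueError, match="window"):
            g.compute_gas(s, window=(4.0, 5.0))

    def test_gas_bounded_by_region_count(self, rng):
        state = rng.integers(-1, 2, (5, 9, 1, 60)).astype(np.int8)
        am = g.ActivationMap(state=state, band_names=("gamma",),
                             bin_edges=-1 + 0.1 * np.arange(61))
        val = g.compute_gas(g.spread_timeseries(am)).gas
        assert 0 <= val <= 9
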