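"""Diffusion estimator, bound/mobile classification and condition ANOVA."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from sptquant import (SptSimConfig, analyze_tracks, apparent_d, bound_fraction,
                      classify_track, compare_conditions, d_histogram,
                      expected_bound_fraction, noisy_truth_tracks, one_step_msd,
                      simulate_trajectories)
from sptquant.tracking import Track


def make_track(frames, x_um, y_um=None, tid=0):
    y_um = y_um if y_um is not None else [0.0] * len(frames)
    return Track(track_id=tid, frames=list(frames),
                 x_px=[x / 0.096 for x in x_um], y_px=[y / 0.096 for y in y_um],
                 x_um=list(x_um), y_um=list(y_um),
                 gap=[False] * len(frames))


def truth_tracks(cfg):
    """Noisy ground-truth positions as Track objects (one per molecule)."""
    trajectories = simulate_trajectories(cfg)
    noisy = noisy_truth_tracks(trajectories, cfg)
    tracks = []
    for i, pos in enumerate(noisy):
        tracks.append(Track(
            track_id=i, frames=list(range(len(pos))),
            x_px=list(pos[:, 0] / cfg.pixel_size),
            y_px=list(pos[:, 1] / cfg.pixel_size),
            x_um=list(pos[:, 0]), y_um=list(pos[:, 1]),
            gap=[False] * len(pos)))
    return trajectories, tracks


class TestMsdAndD:
    def test_constant_steps_give_exact_msd(self):
        t = make_track(range(5), [0.0, 0.2, 0.4, 0.6, 0.8])
        assert np.isclose(one_step_msd(t), 0.04)

    def test_stationary_track_has_zero_msd(self):
        t = make_track(range(4), [0.5] * 4)
        assert one_step_msd(t) == 0.0

    def test_gap_spanning_steps_are_excluded(self):
        # jump of 2 frames between 0.4 and 9.9 must not enter the mean
        t = make_track([0, 1, 2, 4], [0.0, 0.2, 0.4, 9.9])
        assert np.isclose(one_step_msd(t), 0.04)

    def test_gap_only_track_rejected(self):
        t = make_track([0, 2, 4], [0.0, 0.2, 0.4])
        with pytest.raises(ValueError, match="single-frame"):
            one_step_msd(t)

    def test_apparent_d_direct_substitution(self):
        assert apparent_d(0.04, 0.02) == pytest.approx(0.5)
        assert apparent_d(0.0, 0.02) == 0.0
        assert apparent_d(0.024, 0.02) == pytest.approx(0.3)

    def test_nonpositive_dt_rejected(self):
        with pytest.raises(ValueError):
            apparent_d(0.04, 0.0)

    def test_brownian_ensemble_msd_matches_4_d_dt(self):
        cfg = SptSimConfig(n_frames=11, image_size=256, n_molecules=5000,
                           f_bound=0.0, d_mobile=0.5, loc_sigma=0.0,
                           k_off_frame=0.0, k_on_frame=0.0, seed=12)
        _, tracks = truth_tracks(cfg)
        msds = np.array([one_step_msd(t) for t in tracks])
        se = msds.std() / np.sqrt(len(msds))
        assert abs(msds.mean() - 0.04) < 3 * se


class TestClassification:
    def test_threshold_is_inclusive_for_bound(self):
        assert classify_track(0.3) == "bound"
        assert classify_track(0.3000001) == "mobile"
        assert classify_track(0.0) == "bound"

    def test_negative_d_rejected(self):
        with pytest.raises(ValueError):
            classify_track(-0.1)

    def test_bound_fraction_simple_counts(self):
        df = pd.DataFrame({"label": ["bound"] * 2 + ["mobile"] * 3})
        assert bound_fraction(df) == pytest.approx(0.4)
        assert bound_fraction(pd.DataFrame({"label": ["bound"]})) == 1.0

    def test_bound_fraction_empty_rejected(self):
        with pytest.raises(ValueError):
            bound_fraction(pd.DataFrame({"label": []}))

    def test_mixture_recovery_matches_chi2_closed_form(self):
        from oracles import chi2_mixture_bound_fraction
        cfg = SptSimConfig(n_frames=10, image_size=256, n_molecules=4000,
                           f_bound=0.4, d_bound=0.02, d_mobile=0.5,
                           loc_sigma=0.03, k_off_frame=0.0, k_on_frame=0.0,
                           seed=13)
        _, tracks = truth_tracks(cfg)
        per_track = analyze_tracks(tracks, cfg.frame_interval)
        frac = bound_fraction(per_track)
        expected = chi2_mixture_bound_fraction(0.4, 0.02, 0.5, 9, 0.03, 0.02)
        assert expected == pytest.approx(
            expected_bound_fraction(0.4, 0.02, 0.5, 9, 0.03, 0.02))
        se = np.sqrt(expected * (1 - expected) / 4000)
        assert abs(frac - expected) < 4 * se

    def test_bound_fraction_invariant_under_relabeling_and_unit_roundtrip(self):
        cfg = SptSimConfig(n_frames=8, image_size=128, n_molecules=200,
                           f_bound=0.4, seed=14)
        _, tracks = truth_tracks(cfg)
        per_track = analyze_tracks(tracks, cfg.frame_interval)
        shuffled = list(reversed(tracks))
        for i, t in enumerate(shuffled):
            t.track_id = 1000 + i
        assert bound_fraction(analyze_tracks(shuffled, cfg.frame_interval)) \
            == bound_fraction(per_track)
        # um -> px -> um round trip must not move anyone across the threshold
        for t in tracks:
            t.x_um = [x * cfg.pixel_size for x in t.x_px]
            t.y_um = [y * cfg.pixel_size for y in t.y_px]
        assert bound_fraction(analyze_tracks(tracks, cfg.frame_interval)) \
            == bound_fraction(per_track)


class TestHistogram:
    def test_single_track_mass_in_one_bin(self):
        edges, masses = d_histogram([0.52])
        assert masses.sum() == pytest.approx(1.0)
        assert masses[np.searchsorted(edges, 0.52) - 1] == 1.0

    def test_overflow_bin_collects_large_d(self):
        edges, masses = d_histogram([5.0], bin_edges=[0.0, 1.0, 2.0])
        assert masses[-1] == 1.0

    def test_pure_mobile_population_modes_at_d_mobile(self):
        cfg = SptSimConfig(n_frames=21, image_size=256, n_molecules=3000,
                           f_bound=0.0, d_mobile=0.5, loc_sigma=0.0,
                           k_off_frame=0.0, k_on_frame=0.0, seed=15)
        _, tracks = truth_tracks(cfg)
        per_track = analyze_tracks(tracks, cfg.frame_interval)
        edges, masses = d_histogram(per_track["d_app"])
        mode = masses[:-1].argmax()
        assert edges[mode] <= 0.5 <= edges[mode + 1]

    def test_bad_inputs_rejected(self):
        with pytest.raises(ValueError):
            d_histogram([])
        with pytest.raises(ValueError):
            d_histogram([0.1], bin_edges=[0.0, 0.0, 1.0])


class TestCompareConditions:
    def test_identical_groups_give_f_zero_p_one(self):
        res = compare_conditions({"a": [0.3, 0.3], "b": [0.3, 0.3]})
        assert res.f_stat == 0.0 and res.p_value == 1.0

    def test_separated_constant_groups_highly_significant(self):
        res = compare_conditions({"a": [0.2, 0.2, 0.2], "b": [0.5, 0.5, 0.5]})
        assert res.p_value < 1e-6
        assert res.group_means == {"a": pytest.approx(0.2),
                                   "b": pytest.approx(0.5)}

    def test_f_statistic_matches_textbook_formula(self):
        groups = {"a": [0.21, 0.24, 0.20], "b": [0.50, 0.47, 0.52],
                  "c": [0.33, 0.30, 0.35]}
        res = compare_conditions(groups)
        arrs = [np.array(v) for v in groups.values()]
        grand = np.concatenate(arrs).mean()
        msb = sum(len(a) * (a.mean() - grand) ** 2 for a in arrs) / (3 - 1)
        msw = sum(((a - a.mean()) ** 2).sum() for a in arrs) / (9 - 3)
        assert res.f_stat == pytest.approx(msb / msw)
        assert res.df_between == 2 and res.df_within == 6
        assert res.p_value == pytest.approx(stats.f.sf(msb / msw, 2, 6))

    def test_type_i_error_rate_under_the_null(self, rng):
        hits = 0
        n_rep = 1000
        for _ in range(n_rep):
            g = {k: list(rng.normal(0.3, 0.05, 4)) for k in "abc"}
            if compare_conditions(g).p_value <= 0.05:
                hits += 1
        se = np.sqrt(0.05 * 0.95 / n_rep)
        assert abs(hits / n_rep - 0.05) < 3.5 * se

    def test_undersized_designs_rejected(self):
        with pytest.raises(ValueError):
            compare_conditions({"a": [0.1, 0.2]})
        with pytest.raises(ValueError, match="cells"):
            compare_conditions({"a": [0.1, 0.2], "b": [0.3]})


class TestCalibration:
    def test_localization_noise_inflates_d_by_sigma_squared_over_dt(self):
        cfg = SptSimConfig(n_frames=21, image_size=256, n_molecules=3000,
                           f_bound=0.0, d_mobile=0.5, loc_sigma=0.03,
                           k_off_frame=0.0, k_on_frame=0.0, seed=16)
        _, tracks = truth_tracks(cfg)
        per_track = analyze_tracks(tracks, cfg.frame_interval)
        d_eff = 0.5 + 0.03 ** 2 / 0.02
        se = per_track["d_app"].std() / np.sqrt(len(per_track))
        assert abs(per_track["d_app"].mean() - d_eff) < 3 * se

    def test_noise_free_estimator_is_unbiased(self):
        cfg = SptSimConfig(n_frames=21, image_size=256, n_molecules=3000,
                           f_bound=0.0, d_mobile=0.5, loc_sigma=0.0,
                           k_off_frame=0.0, k_on_frame=0.0, seed=17)
        _, tracks = truth_tracks(cfg)
        per_track = analyze_tracks(tracks, cfg.frame_interval)
        se = per_track["d_app"].std() / np.sqrt(len(per_track))
        assert abs(per_track["d_app"].mean() - 0.5) < 3 * se
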