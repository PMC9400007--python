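import numpy as np
import pytest

from resptrack.lattice import build_lattice
from resptrack.signal_io import SampledSignal, frame_signal
from resptrack.tracking import (
    TrackingConfig,
    TrackingError,
    TrajectoryPath,
    estimate_breathing_rate,
    kmeans_classifier_correction,
    lags_to_rates,
    merge_subpaths,
    naive_maxima_selection,
    split_into_subpaths,
    voting_classifier_correction,
)

from conftest import make_lattice, make_sine


def path_from_lags(lags, amp=0.9):
    lags = np.asarray(lags, dtype=int)
    return TrajectoryPath(np.arange(lags.size), lags, np.full(lags.size, amp))


class TestNaiveSelection:
    def test_high_amplitude_peak_beats_near_central_peak(self):
        """A low spurious peak close to the central maximum loses to the true
        fundamental peak because amplitude distance dominates."""
        lat = make_lattice([{120: 0.1, 500: 0.9}])
        path = naive_maxima_selection(lat)
        assert path.lags.tolist() == [500]

    def test_single_in_band_maximum_chosen(self):
        lat = make_lattice([[700], [700], [700]])
        assert naive_maxima_selection(lat).lags.tolist() == [700] * 3

    def test_out_of_band_maxima_ignored(self):
        lat = make_lattice([{50: 0.99, 500: 0.8}])  # 50 lags = 120 breaths/min
        assert naive_maxima_selection(lat).lags.tolist() == [500]

    def test_clean_15bpm_selects_400(self, sine_15bpm_300s):
        lat = build_lattice(frame_signal(sine_15bpm_300s, 4096, 0.85))
        path = naive_maxima_selection(lat)
        assert np.all(np.abs(path.lags - 400) <= 1)

    def test_empty_frame_copies_previous(self):
        lat = make_lattice([[500], [], [500]])
        path = naive_maxima_selection(lat)
        assert path.lags.tolist() == [500, 500, 500]
        assert path.flags[1] == "F"

    def test_empty_first_frame_is_error(self):
        lat = make_lattice([[], [500]])
        with pytest.raises(TrackingError):
            naive_maxima_selection(lat)


class TestVotingClassifier:
    def test_doubling_after_stable_history_corrected(self):
        lat = make_lattice([[400, 800]] * 5 + [{401: 0.9, 800: 0.9}])
        path = path_from_lags([400, 400, 400, 400, 400, 800])
        out = voting_classifier_correction(path, lat)
        assert out.lags[-1] == 401
        assert "V" in out.flags[-1]

    def test_below_ratio_unchanged(self):
        lat = make_lattice([[400, 430]] * 6)
        path = path_from_lags([400, 400, 400, 400, 400, 430])
        out = voting_classifier_correction(path, lat)
        assert out.lags[-1] == 430

    def test_four_of_five_votes_trigger(self):
        """With predecessors [400,400,800,400,400] a current 800 collects four
        up-votes (the 800 predecessor contributes none) — enough to fire."""
        lat = make_lattice([[400, 800]] * 6)
        path = path_from_lags([400, 400, 800, 400, 400, 800])
        out = voting_classifier_correction(path, lat)
        assert out.lags[-1] == 400

    def test_halving_corrected_in_both_mode(self):
        """An octave error proper — the lag collapsing to half, i.e. a doubled
        rate readout — is repaired by the symmetric rule."""
        lat = make_lattice([[200, 400]] * 6)
        path = path_from_lags([400, 400, 400, 400, 400, 200])
        out = voting_classifier_correction(path, lat, direction="both")
        assert out.lags[-1] == 400
        out_up_only = voting_classifier_correction(path, lat, direction="up")
        assert out_up_only.lags[-1] == 200

    def test_warmup_frames_untouched(self):
        lat = make_lattice([[400, 800]] * 3)
        path = path_from_lags([400, 400, 800])
        out = voting_classifier_correction(path, lat)
        assert out.lags[-1] == 800  # only 2 predecessors < 3 votes needed


class TestKmeansCorrection:
    def test_isolated_octave_jump_repaired(self):
        lat = make_lattice([[400, 800]] * 6)
        path = path_from_lags([400, 400, 400, 800, 400, 400])
        out = kmeans_classifier_correction(path, lat, seed=0)
        assert out.lags.tolist() == [400] * 6
        assert "K" in out.flags[3]

    def test_constant_path_unchanged(self):
        lat = make_lattice([[400, 800]] * 6)
        path = path_from_lags([400] * 6)
        out = kmeans_classifier_correction(path, lat, seed=0)
        assert out.lags.tolist() == [400] * 6

    def test_short_path_returned_unchanged(self):
        lat = make_lattice([[400, 800]] * 3)
        path = path_from_lags([400, 800, 400])
        out = kmeans_classifier_correction(path, lat, seed=0)
        assert out.lags.tolist() == [400, 800, 400]

    def test_adjacent_outliers_both_repaired(self):
        lags = [400] * 40
        lags[20] = 810
        lags[21] = 820
        lat = make_lattice([[400, 810, 820]] * 40)
        out = kmeans_classifier_correction(path_from_lags(lags), lat, seed=0)
        assert np.all(out.lags == 400)
        # audit: every repaired point is now its predecessor's nearest maximum
        for i in range(1, 40):
            maxima = lat.maxima[i]
            nearest = maxima[np.argmin(np.abs(maxima - out.lags[i - 1]))]
            assert out.lags[i] == nearest

    def test_idempotent_on_own_output(self):
        lags = [400] * 30
        lags[10] = 800
        lat = make_lattice([[400, 800]] * 30)
        once = kmeans_classifier_correction(path_from_lags(lags), lat, seed=0)
        twice = kmeans_classifier_correction(once, lat, seed=0)
        assert np.array_equal(once.lags, twice.lags)


class TestSubPaths:
    def test_nearest_neighbour_path_is_single_subpath(self):
        lat = make_lattice([[400, 800]] * 5)
        subs = split_into_subpaths(path_from_lags([400] * 5), lat)
        assert len(subs) == 1
        assert subs[0].lags.tolist() == [400] * 5

    def test_two_non_nearest_transitions_give_three_subpaths(self):
        lat = make_lattice([[400, 800]] * 6)
        subs = split_into_subpaths(path_from_lags([400, 400, 800, 800, 400, 400]), lat)
        assert len(subs) == 3
        assert [len(s) for s in subs] == [2, 2, 2]

    def test_cut_count_matches_brute_force_audit(self):
        rng = np.random.default_rng(42)
        maxima = [[300, 500, 900]] * 20
        lat = make_lattice(maxima)
        lags = rng.choice([300, 500, 900], size=20)
        path = path_from_lags(lags)
        subs = split_into_subpaths(path, lat)
        expected_cuts = 0
        for i in range(19):
            m = np.array(maxima[i + 1])
            nearest = m[np.argmin(np.abs(m - lags[i]))]
            if lags[i + 1] != nearest:
                expected_cuts += 1
        assert len(subs) == expected_cuts + 1

    def test_single_subpath_merge_is_identity(self):
        lat = make_lattice([[400, 800]] * 5)
        path = path_from_lags([400] * 5)
        merged = merge_subpaths(split_into_subpaths(path, lat), lat)
        assert merged.lags.tolist() == [400] * 5

    def test_merge_reroutes_harmonic_ridge_excursion(self):
        """A sub-path stranded on the half-period ridge is replaced by the
        nearest-neighbour alternative along the fundamental ridge."""
        maxima = [{400: 0.9, 200: 0.5}] * 10
        lat = make_lattice(maxima)
        lags = [400] * 10
        for i in (4, 5, 6):
            lags[i] = 200
        amps = [0.9] * 10
        for i in (4, 5, 6):
            amps[i] = 0.5
        path = TrajectoryPath(np.arange(10), np.array(lags), np.array(amps))
        merged = merge_subpaths(split_into_subpaths(path, lat), lat)
        assert merged.lags.tolist() == [400] * 10

    def test_merge_never_longer_than_concatenation(self):
        rng = np.random.default_rng(3)
        maxima = [[250, 400, 800]] * 30
        lat = make_lattice(maxima)
        lags = rng.choice([250, 400, 800], size=30)
        path = path_from_lags(lags)
        subs = split_into_subpaths(path, lat)
        merged = merge_subpaths(subs, lat)

        def total_len(p):
            pts = np.column_stack(
                [p.frames / max(len(p) - 1, 1), p.lags / lat.frame_length, p.amps]
            )
            return np.sum(np.linalg.norm(np.diff(pts, axis=0), axis=1))

        assert total_len(merged) <= total_len(path) + 1e-12


class TestRates:
    @pytest.mark.parametrize(
        "lag,expected",
        [(500, 12.0), (400, 15.0), (509, 11.79)],
    )
    def test_lag_to_bpm_conversion(self, lag, expected):
        lat = make_lattice([[lag]])
        series = lags_to_rates(path_from_lags([lag]), lat)
        assert series.rates[0] == pytest.approx(expected, abs=0.005)

    def test_times_follow_frame_centers(self):
        lat = make_lattice([[500], [500]], hop=614)
        series = lags_to_rates(path_from_lags([500, 500]), lat)
        assert series.times[0] == pytest.approx((4095 / 2) / 100.0)
        assert series.times[1] - series.times[0] == pytest.approx(6.14)


class TestEndToEnd:
    def test_clean_12bpm_recovered(self, sine_12bpm_300s):
        series = estimate_breathing_rate(sine_12bpm_300s)
        assert np.median(series.rates) == pytest.approx(12.0, abs=0.2)

    def test_naive_equals_proposed_on_clean_signal(self, sine_12bpm_300s):
        proposed = estimate_breathing_rate(sine_12bpm_300s, TrackingConfig(variant="proposed"))
        naive = estimate_breathing_rate(sine_12bpm_300s, TrackingConfig(variant="naive"))
        assert np.median(proposed.rates) == np.median(naive.rates)

    def test_signal_shorter_than_frame_errors(self):
        sig = make_sine(0.2, 30.0, 100.0)
        with pytest.raises(TrackingError):
            estimate_breathing_rate(sig)

    def test_deterministic_given_seed(self, sine_12bpm_300s):
        a = estimate_breathing_rate(sine_12bpm_300s, TrackingConfig(seed=5))
        b = estimate_breathing_rate(sine_12bpm_300s, TrackingConfig(seed=5))
        assert np.array_equal(a.rates, b.rates)

    def test_rates_in_physiologic_band(self, sine_15bpm_300s):
        series = estimate_breathing_rate(sine_15bpm_300s)
        assert np.all((series.rates >= 4.0) & (series.rates <= 60.0))
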