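"""Symbolic stimulus construction: grounds, figures, gaps, TMR."""

import numpy as np
import pytest

from figground import (
    FormantTrack,
    apply_tmr,
    assemble_detection_pair,
    assemble_detection_stimulus,
    assemble_discrimination_pair,
    erb_number,
    make_coherent_roving_figure,
    make_complex_roving_figure,
    make_same_frequency_figure,
    sample_ground,
)
from figground.stimulus import ConstraintError


class TestGround:
    def test_tone_count_per_chord_in_5_to_15(self, grid, rng):
        els = sample_ground(40, grid, rng)
        counts = np.zeros(40, int)
        for e in els:
            counts[e.chord_start] += 1
        assert counts.min() >= 5 and counts.max() <= 15

    def test_frequencies_are_grid_members(self, grid, rng):
        els = sample_ground(200, grid, rng)
        freqs = {e.frequency for e in els}
        assert freqs <= set(grid.frequencies.tolist())
        assert min(freqs) >= 179.0 and max(freqs) <= 7246.0

    def test_seeded_determinism(self, grid):
        a = sample_ground(5, grid, np.random.default_rng(9))
        b = sample_ground(5, grid, np.random.default_rng(9))
        assert a == b


class TestSameFrequencyFigure:
    @pytest.mark.parametrize("seed", range(25))
    def test_erb_separation_and_constancy(self, grid, seed):
        tracks = make_same_frequency_figure(6, grid, np.random.default_rng(seed))
        freqs = [t[0] for t in tracks]
        for t, f in zip(tracks, freqs):
            assert np.all(t == f)  # constant over chords
        e = [erb_number(f) for f in freqs]
        seps = [abs(e[0] - e[1]), abs(e[0] - e[2]), abs(e[1] - e[2])]
        assert min(seps) > 1.0

    def test_candidate_triple_1000_1100_would_be_rejected(self):
        # 1000 and 1100 Hz differ by ~0.73 cams: inadmissible as components
        assert abs(erb_number(1100.0) - erb_number(1000.0)) < 1.0

    def test_impossible_constraint_raises(self, grid, rng):
        from figground.grid import build_frequency_grid

        tiny = build_frequency_grid(1000.0, 1050.0, 24)  # all within ~0.4 cams
        with pytest.raises(ConstraintError):
            make_same_frequency_figure(6, tiny, rng, max_attempts=50)


class TestRovingFigures:
    def test_constant_track_is_fixed_point_of_coherent_construction(self):
        track = FormantTrack(f1=[500.0] * 5, f2=[1500.0] * 5, f3=[2500.0] * 5)
        c1, c2, c3 = make_coherent_roving_figure(track)
        np.testing.assert_allclose(c1, 500.0)
        np.testing.assert_allclose(c2, 1500.0)  # R12 = 3
        np.testing.assert_allclose(c3, 2500.0)  # R23 = 5/3

    def test_two_bin_hand_arithmetic(self):
        track = FormantTrack(f1=[400.0, 500.0], f2=[1200.0, 1250.0], f3=[2400.0, 2500.0])
        _, c2, _ = make_coherent_roving_figure(track)
        # R12 = mean(3, 2.5) = 2.75
        np.testing.assert_allclose(c2, [1100.0, 1375.0])

    def test_component_ratio_constant_across_bins(self, fixture_track):
        c1, c2, c3 = make_coherent_roving_figure(fixture_track)
        np.testing.assert_allclose(c2 / c1, (c2 / c1)[0], rtol=1e-12)
        np.testing.assert_allclose(c3 / c2, (c3 / c2)[0], rtol=1e-12)

    def test_linear_offset_variant(self):
        track = FormantTrack(f1=[400.0, 500.0], f2=[1200.0, 1250.0], f3=[2400.0, 2500.0])
        _, c2, _ = make_coherent_roving_figure(track, method="linear_offset")
        np.testing.assert_allclose(c2, [400.0 + 775.0, 500.0 + 775.0])

    def test_complex_is_identity_on_formants(self, fixture_track):
        c1, c2, c3 = make_complex_roving_figure(fixture_track)
        np.testing.assert_array_equal(c1, fixture_track.f1)
        np.testing.assert_array_equal(c2, fixture_track.f2)
        np.testing.assert_array_equal(c3, fixture_track.f3)
        assert len(c1) == 42

    def test_constructions_coincide_on_constant_formants(self):
        track = FormantTrack(f1=[500.0] * 4, f2=[1500.0] * 4, f3=[2500.0] * 4)
        np.testing.assert_allclose(
            make_coherent_roving_figure(track), make_complex_roving_figure(track)
        )


class TestDetectionStimulus:
    def test_geometry(self, rng):
        stim = assemble_detection_stimulus(True, rng)
        assert stim.n_chords == 40
        assert stim.duration_ms == 2000.0
        assert stim.figure_n_chords == 6
        assert 14 <= stim.figure_onset_chord <= 19  # chords 15-20, 1-based

    @pytest.mark.parametrize("seed", range(20))
    def test_matched_pair_conserves_tone_count(self, seed):
        present, absent = assemble_detection_pair(np.random.default_rng(seed))
        assert present.tone_chord_count() == absent.tone_chord_count()
        assert present.elements_with_role("ground") == absent.elements_with_role("ground")

    def test_decoys_are_not_a_constant_track(self):
        # chord-wise redrawn decoys: across many seeds, never three constant tracks
        for seed in range(200):
            absent = assemble_detection_stimulus(False, np.random.default_rng(seed))
            decoys = absent.elements_with_role("decoy")
            by_chord = {}
            for e in decoys:
                by_chord.setdefault(e.chord_start, set()).add(e.frequency)
            freq_sets = list(by_chord.values())
            if any(fs != freq_sets[0] for fs in freq_sets):
                break
        else:
            pytest.fail("decoy frequencies were identical across chords for 200 seeds")


class TestDiscriminationPair:
    def test_background_geometry_and_figure_length(self, rng):
        first, second = assemble_discrimination_pair("same_frequency", 0.0, 1, rng)
        for s in (first, second):
            assert s.n_chords == 70
            assert s.duration_ms == 3500.0
            assert s.figure_n_chords == 42
            assert 0 <= s.figure_onset_chord <= 70 - 42
        assert first.gap.location == "figure"
        assert second.gap.location == "ground"

    def test_gap_interval_2_swaps_roles(self, rng):
        first, second = assemble_discrimination_pair("same_frequency", 0.0, 2, rng)
        assert first.gap.location == "ground"
        assert second.gap.location == "figure"

    def test_figure_gap_is_interior_and_empty_of_figure(self, rng):
        first, _ = assemble_discrimination_pair("same_frequency", 0.0, 1, rng)
        gap = first.gap
        assert gap.n_chords == 6
        assert gap.onset_chord > first.figure_onset_chord
        assert gap.onset_chord + 6 < first.figure_onset_chord + first.figure_n_chords
        fig_chords = {e.chord_start for e in first.elements_with_role("figure")}
        assert fig_chords.isdisjoint(gap.span())
        # ground is untouched in the figure-gap stimulus
        assert np.all(first.ground_counts_per_chord() >= 5)

    def test_ground_gap_removes_three_tones_per_chord(self, rng):
        for _ in range(10):
            _, second = assemble_discrimination_pair("same_frequency", 0.0, 1, rng)
            counts = second.ground_counts_per_chord()
            gap = second.gap
            for chord in gap.span():
                assert 2 <= counts[chord] <= 12  # 5..15 minus 3
            outside = np.delete(counts, list(gap.span()))
            assert outside.min() >= 5
            # the window overlaps the figure span
            fig = range(second.figure_onset_chord,
                        second.figure_onset_chord + second.figure_n_chords)
            assert set(gap.span()) & set(fig)

    def test_roving_tasks_use_track_and_share_figure_between_intervals(
        self, rng, fixture_track
    ):
        first, second = assemble_discrimination_pair(
            "complex_roving", 6.0, 1, rng, track=fixture_track
        )
        assert first.figure_n_chords == 42
        np.testing.assert_array_equal(
            first.figure_component_tracks[0], second.figure_component_tracks[0]
        )
        assert first.figure_onset_chord == second.figure_onset_chord

    def test_roving_without_track_raises(self, rng):
        with pytest.raises(ValueError, match="FormantTrack"):
            assemble_discrimination_pair("coherent_roving", 0.0, 1, rng)


class TestApplyTmr:
    @pytest.mark.parametrize(
        "tmr,ratio", [(0.0, 1.0), (6.0, 10 ** 0.3), (-20.0, 0.1)]
    )
    def test_amplitude_ratio(self, rng, tmr, ratio):
        stim = assemble_detection_stimulus(True, rng)
        scaled = apply_tmr(stim, tmr)
        fig_amp = {e.amplitude for e in scaled.elements_with_role("figure")}
        gnd_amp = {e.amplitude for e in scaled.elements_with_role("ground")}
        assert gnd_amp == {1.0}
        assert len(fig_amp) == 1
        assert fig_amp.pop() == pytest.approx(ratio)
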