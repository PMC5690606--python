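import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from glassdev.stimgen import (
    BLANK,
    PINWHEEL_OFF,
    PINWHEEL_ON,
    GlassPatternSpec,
    InvalidSpecError,
    StimulusSchedule,
    build_palindromic_schedule,
    build_pinwheel_schedule,
    generate_glass_pattern,
    pinwheel_fundamental_frequency,
    render_sequence,
)


class TestGlassPatternSpec:
    def test_defaults_match_stimulus_parameters(self):
        spec = GlassPatternSpec()
        assert spec.field_width == 30.0
        assert spec.field_height == 23.0
        assert spec.dot_density == 10.0
        assert spec.dipole_separation == pytest.approx(0.414)

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"dot_density": 0.0},
            {"dot_density": -1.0},
            {"dipole_separation": 0.0},
            {"coherence": 1.5},
            {"coherence": -0.1},
            {"pattern_class": "spiral"},
        ],
    )
    def test_invalid_spec_rejected(self, kwargs):
        with pytest.raises(InvalidSpecError):
            GlassPatternSpec(**kwargs)


class TestGenerateGlassPattern:
    def test_dipole_count_is_half_dot_budget(self):
        # construction-count oracle: density * area / 2
        field = generate_glass_pattern(GlassPatternSpec(seed=1))
        assert field.n_dipoles == round(10.0 * 30.0 * 23.0 / 2)
        assert field.n_dipoles == 3450
        assert field.n_dots == 6900

    def test_separations_exact(self):
        field = generate_glass_pattern(GlassPatternSpec(seed=2))
        assert np.max(np.abs(field.separations - 0.414)) < 1e-9

    def test_concentric_orientations_tangential(self):
        field = generate_glass_pattern(
            GlassPatternSpec(pattern_class="concentric", coherence=1.0, seed=3)
        )
        mid = field.midpoints
        theta = np.degrees(np.arctan2(mid[:, 1], mid[:, 0]))
        diff = (field.orientations - (theta + 90.0)) % 180.0
        diff = np.minimum(diff, 180.0 - diff)
        assert np.max(diff) < 1e-9

    def test_radial_orientations_along_radius(self):
        field = generate_glass_pattern(
            GlassPatternSpec(pattern_class="radial", coherence=1.0, seed=4)
        )
        mid = field.midpoints
        theta = np.degrees(np.arctan2(mid[:, 1], mid[:, 0]))
        diff = (field.orientations - theta) % 180.0
        diff = np.minimum(diff, 180.0 - diff)
        assert np.max(diff) < 1e-9

    def test_random_orientations_uniform(self):
        # Rayleigh-style circular uniformity on axial data (doubled angles),
        # repeated over seeds: reject at alpha=0.01 in at most 5/100 runs.
        rejections = 0
        for seed in range(100):
            field = generate_glass_pattern(
                GlassPatternSpec(pattern_class="random", seed=seed)
            )
            ang = np.radians(field.orientations * 2.0)
            n = ang.size
            r = np.hypot(np.cos(ang).sum(), np.sin(ang).sum()) / n
            z = n * r**2
            p = np.exp(-z)  # Rayleigh-test approximation
            if p < 0.01:
                rejections += 1
        assert rejections <= 5

    def test_determinism(self):
        spec = GlassPatternSpec(seed=99)
        a = generate_glass_pattern(spec)
        b = generate_glass_pattern(spec)
        np.testing.assert_array_equal(a.dots, b.dots)
        np.testing.assert_array_equal(a.orientations, b.orientations)

    @given(coherence=st.floats(0.1, 0.9), seed=st.integers(0, 1000))
    @settings(max_examples=20, deadline=None)
    def test_coherence_fraction_within_binomial_error(self, coherence, seed):
        spec = GlassPatternSpec(coherence=coherence, seed=seed)
        field = generate_glass_pattern(spec)
        rule = field.rule_orientations()
        diff = (field.orientations - rule) % 180.0
        diff = np.minimum(diff, 180.0 - diff)
        frac = float(np.mean(diff < 1e-6))
        n = field.n_dipoles
        tol = 5 * np.sqrt(coherence * (1 - coherence) / n)
        assert abs(frac - coherence) < tol

    @given(seed=st.integers(0, 10_000), sep=st.floats(0.05, 2.0))
    @settings(max_examples=25, deadline=None)
    def test_separation_conserved_across_seeds(self, seed, sep):
        spec = GlassPatternSpec(dipole_separation=sep, dot_density=2.0, seed=seed)
        field = generate_glass_pattern(spec)
        assert np.max(np.abs(field.separations - sep)) < 1e-9


class TestRenderSequence:
    def test_dynamic_one_second_is_thirty_frames(self):
        fields, ts = render_sequence(GlassPatternSpec(dot_density=1.0), "dynamic", 1.0)
        assert abs(len(fields) - round(1.0 / 0.033)) <= 1
        assert ts[1] - ts[0] == pytest.approx(0.033)

    def test_static_three_seconds_three_distinct_radial_fields(self):
        spec = GlassPatternSpec(pattern_class="radial", dot_density=1.0, seed=5)
        fields, _ = render_sequence(spec, "static", 3.0)
        assert len(fields) == 3
        assert not np.array_equal(fields[0].dots, fields[1].dots)
        for f in fields:
            theta = np.degrees(np.arctan2(f.midpoints[:, 1], f.midpoints[:, 0]))
            diff = (f.orientations - theta) % 180.0
            assert np.max(np.minimum(diff, 180.0 - diff)) < 1e-9

    def test_short_static_duration_single_frame(self):
        fields, _ = render_sequence(GlassPatternSpec(dot_density=1.0), "static", 0.5)
        assert len(fields) == 1

    def test_unknown_mode(self):
        with pytest.raises(ValueError, match="mode"):
            render_sequence(GlassPatternSpec(), "strobe", 1.0)

    def test_every_frame_keeps_separation(self):
        spec = GlassPatternSpec(dot_density=1.0, seed=11)
        fields, _ = render_sequence(spec, "dynamic", 0.2)
        for f in fields:
            assert np.max(np.abs(f.separations - spec.dipole_separation)) < 1e-9


class TestPalindromicSchedule:
    def test_three_condition_cycle_layout_and_total(self):
        sched = build_palindromic_schedule(["A", "B", "C"], 48.0, 24.0, 1)
        labels = [ev.trial_type for ev in sched.events]
        assert labels == [
            BLANK, "A", BLANK, "B", BLANK, "C", BLANK,
            "C", BLANK, "B", BLANK, "A", BLANK,
        ]
        assert sched.total_duration == pytest.approx(7 * 24 + 6 * 48)

    def test_single_condition(self):
        sched = build_palindromic_schedule(["A"], 36.0, 36.0, 1)
        assert [ev.trial_type for ev in sched.events] == [BLANK, "A", BLANK, "A", BLANK]
        assert sched.total_duration == pytest.approx(180.0)

    def test_two_cycles_share_boundary_blanks(self):
        sched = build_palindromic_schedule(["A", "B"], 40.0, 30.0, 2)
        labels = [ev.trial_type for ev in sched.events]
        assert labels[0] == BLANK and labels[-1] == BLANK
        blocks = [l for l in labels if l != BLANK]
        assert blocks == ["A", "B", "B", "A"] * 2
        assert labels.count(BLANK) == len(blocks) + 1

    def test_onsets_strictly_increasing_and_contiguous(self):
        sched = build_palindromic_schedule(["A", "B", "C"], 44.0, 28.0, 3)
        onsets = [ev.onset for ev in sched.events]
        assert all(b > a for a, b in zip(onsets, onsets[1:]))

    @given(
        n_conditions=st.integers(1, 6),
        block=st.floats(36.0, 48.0),
        blank=st.floats(24.0, 36.0),
        n_cycles=st.integers(1, 4),
    )
    @settings(max_examples=30, deadline=None)
    def test_palindrome_property(self, n_conditions, block, blank, n_cycles):
        conds = [f"c{i}" for i in range(n_conditions)]
        sched = build_palindromic_schedule(conds, block, blank, n_cycles)
        blocks = [ev.trial_type for ev in sched.events if ev.trial_type != BLANK]
        per_cycle = blocks[: 2 * n_conditions]
        assert per_cycle == per_cycle[::-1]
        # arithmetic oracle for the total duration
        n_blocks = 2 * n_conditions * n_cycles
        assert sched.total_duration == pytest.approx(
            n_blocks * block + (n_blocks + 1) * blank
        )

    def test_out_of_range_durations_warn(self):
        with pytest.warns(UserWarning):
            build_palindromic_schedule(["A"], 60.0, 30.0, 1)
        with pytest.warns(UserWarning):
            build_palindromic_schedule(["A"], 40.0, 10.0, 1)

    def test_empty_conditions_error(self):
        with pytest.raises(ValueError):
            build_palindromic_schedule([], 40.0, 30.0, 1)


class TestPinwheelSchedule:
    def test_960_seconds_ten_cycles(self):
        sched = build_pinwheel_schedule(960.0)
        on = sched.events_of(PINWHEEL_ON)
        off = sched.events_of(PINWHEEL_OFF)
        assert len(on) == 10 and len(off) == 10

    def test_minimum_single_cycle(self):
        sched = build_pinwheel_schedule(96.0)
        assert [ev.trial_type for ev in sched.events] == [PINWHEEL_ON, PINWHEEL_OFF]

    def test_too_short_raises(self):
        with pytest.raises(ValueError):
            build_pinwheel_schedule(90.0)

    def test_fundamental_frequency(self):
        assert pinwheel_fundamental_frequency() == pytest.approx(1 / 1.6)
        assert pinwheel_fundamental_frequency() == pytest.approx(0.625)


class TestScheduleIO:
    def test_tsv_round_trip(self, tmp_path):
        sched = build_palindromic_schedule(["A", "B"], 42.0, 30.0, 2)
        path = tmp_path / "events.tsv"
        sched.to_tsv(path)
        header = path.read_text().splitlines()[0]
        assert header == "onset\tduration\ttrial_type"
        back = StimulusSchedule.from_tsv(path)
        assert [ev.trial_type for ev in back.events] == [
            ev.trial_type for ev in sched.events
        ]
        assert back.total_duration == pytest.approx(sched.total_duration)

    def test_non_contiguous_events_rejected(self):
        from glassdev.stimgen import ScheduleEvent

        with pytest.raises(ValueError, match="contiguous"):
            StimulusSchedule(
                events=[ScheduleEvent(0, 10, "A"), ScheduleEvent(15, 10, "B")]
            )
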