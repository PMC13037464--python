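"""Landmark detection, redox classification and snapshot I/O."""

import math
import warnings

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from redoxniche import (
    DepthProfile,
    FormatError,
    LandmarkWarning,
    ValidationError,
    WaterColumnSnapshot,
    classify_redox,
    detect_interface,
    find_depletion_depth,
    find_onset_depth,
    generate_snapshot,
    population_in_window,
    read_snapshot,
    write_snapshot,
)
from redoxniche.synthetic import INTERFACE_EPSILON, SyntheticLakeParams


def o2_prof(depths, values, limit=0.1):
    return DepthProfile("o2", depths, values, limit)


# ---------------------------------------------------------------------------
# snapshot I/O
# ---------------------------------------------------------------------------

class TestSnapshotIO:
    def test_read_simple_table(self, tmp_path):
        p = tmp_path / "snap.tsv"
        p.write_text("depth_m\to2_uM\n10\t100\n20\t50\n30\t0.5\n")
        snap = read_snapshot(p)
        assert set(snap.profiles) == {"o2"}
        assert len(snap["o2"]) == 3
        np.testing.assert_allclose(snap["o2"].values, [100, 50, 0.5])

    def test_duplicate_depth_names_depth(self, tmp_path):
        p = tmp_path / "snap.tsv"
        p.write_text("depth_m\to2_uM\n10\t100\n20\t50\n20\t40\n")
        with pytest.raises(ValidationError, match="20"):
            read_snapshot(p)

    def test_unordered_rows_equal_sorted(self, tmp_path):
        a = tmp_path / "a.tsv"
        b = tmp_path / "b.tsv"
        a.write_text("depth_m\to2_uM\n30\t0.5\n10\t100\n20\t50\n")
        b.write_text("depth_m\to2_uM\n10\t100\n20\t50\n30\t0.5\n")
        sa, sb = read_snapshot(a), read_snapshot(b)
        np.testing.assert_array_equal(sa["o2"].depths, sb["o2"].depths)
        np.testing.assert_array_equal(sa["o2"].values, sb["o2"].values)

    def test_unknown_column_is_format_error(self, tmp_path):
        p = tmp_path / "snap.tsv"
        p.write_text("depth_m\to2_mgL\n10\t1\n20\t2\n")
        with pytest.raises(FormatError, match="o2_mgL"):
            read_snapshot(p)

    def test_write_read_roundtrip(self, tmp_path, quiet_snapshot):
        p = tmp_path / "snap.tsv"
        write_snapshot(quiet_snapshot, p)
        back = read_snapshot(p)
        for var, prof in quiet_snapshot.profiles.items():
            np.testing.assert_allclose(
                back[var].values, prof.values, rtol=1e-9, atol=1e-12
            )

    def test_negative_values_become_below_detection_zeros(self, tmp_path):
        p = tmp_path / "snap.tsv"
        p.write_text("depth_m\tno3_uM\n10\t5\n20\t-0.02\n30\t1\n")
        snap = read_snapshot(p)
        assert snap["no3"].values[1] == 0.0
        assert snap["no3"].below_detection[1]


# ---------------------------------------------------------------------------
# interface detection
# ---------------------------------------------------------------------------

class TestDetectInterface:
    def test_constructed_plateau(self):
        prof = o2_prof([100, 110, 120, 130, 140, 150], [100, 50, 10, 0.5, 0.5, 0.5])
        assert detect_interface(prof, 0.1) == 130

    def test_no_plateau_returns_deepest_with_warning(self):
        prof = o2_prof([10, 20, 30, 40], [100, 50, 20, 5])
        with pytest.warns(LandmarkWarning):
            assert detect_interface(prof, 0.1) == 40

    def test_all_constant_returns_shallowest_with_warning(self):
        prof = o2_prof([10, 20, 30], [0.5, 0.5, 0.5])
        with pytest.warns(LandmarkWarning):
            assert detect_interface(prof, 0.1) == 10

    def test_logistic_profile_matches_hand_rule(self):
        # independent oracle: evaluate the logistic closed form on the grid
        # and apply the plateau rule by hand
        params = SyntheticLakeParams(
            oxycline_depth=130.0, o2_floor=0.5, no3_depletion_depth=160.0,
            sulfide_onset_depth=200.0, peak_depth=150.0,
            noise_sd_fraction=0.0, seed=1,
        )
        grid = params.grid()
        span = params.o2_surface - params.o2_floor
        centre = params.oxycline_depth - params.oxycline_width * math.log(
            span / INTERFACE_EPSILON - 1.0
        )
        vals = params.o2_floor + span / (
            1.0 + np.exp((grid - centre) / params.oxycline_width)
        )
        tol = 0.1
        qualifies = vals <= vals.min() + tol
        expected = grid[np.nonzero(~qualifies)[0][-1] + 1]

        snap = generate_snapshot(params)
        detected = detect_interface(snap["o2"], tol)
        assert detected == expected
        assert abs(detected - 130.0) <= params.grid_step

    @given(shift=st.floats(-50, 500), extra=st.integers(0, 5))
    def test_invariant_to_translation_and_oxic_padding(self, shift, extra):
        depths = np.array([100.0, 110, 120, 130, 140, 150])
        values = np.array([100.0, 50, 10, 0.5, 0.5, 0.5])
        base = detect_interface(o2_prof(depths, values), 0.1)
        pad_d = depths[0] - 10 * np.arange(extra, 0, -1)
        pad_v = np.full(extra, 300.0)
        moved = detect_interface(
            o2_prof(np.concatenate([pad_d, depths]) + shift,
                    np.concatenate([pad_v, values])),
            0.1,
        )
        assert moved == pytest.approx(base + shift)


# ---------------------------------------------------------------------------
# depletion and onset
# ---------------------------------------------------------------------------

class TestDepletionOnset:
    def test_depletion_example(self):
        prof = DepthProfile("no3", [150, 160, 170, 180, 190], [5, 2, 0.5, 0.05, 0.02], 0.05)
        assert find_depletion_depth(prof, 0.1) == 180

    def test_never_depleted(self):
        prof = DepthProfile("no3", [150, 160, 170], [5, 2, 1])
        assert find_depletion_depth(prof, 0.1) is None

    def test_dip_and_recover_uses_final_crossing(self):
        prof = DepthProfile(
            "no3", [150, 160, 170, 180, 185, 190], [5, 0.05, 2, 1, 0.05, 0.02]
        )
        assert find_depletion_depth(prof, 0.1) == 185

    def test_onset_field_shape(self):
        # sulfide detected from 115 m, 3 uM there rising to 12 uM at depth
        prof = DepthProfile("h2s", [90, 100, 115, 150, 250], [0, 0, 3, 8, 12], 0.1)
        assert find_onset_depth(prof, 1.0) == 115

    def test_onset_absent_when_all_zero(self):
        prof = DepthProfile("h2s", [90, 100, 115], [0, 0, 0], 0.1)
        assert find_onset_depth(prof, 1.0) is None

    def test_onset_threshold_zero_needs_detected_signal(self):
        prof = DepthProfile("h2s", [90, 100, 115], [0, 0, 0], 0.1)
        assert find_onset_depth(prof, 0.0) is None

    def test_empty_profile_rejected_at_construction(self):
        with pytest.raises(ValidationError):
            DepthProfile("no3", [], [])


# ---------------------------------------------------------------------------
# classification and the niche window
# ---------------------------------------------------------------------------

class TestClassifyRedox:
    def test_synthetic_window_matches_generator_landmarks(self, quiet_snapshot):
        # generator: interface 85 m, nitrate depletion 110 m, sulfide onset 110 m
        cls = classify_redox(quiet_snapshot)
        assert cls.niche_window is not None
        top, bottom = cls.niche_window
        step = quiet_snapshot.ground_truth.grid_step
        assert abs(top - 85.0) <= step
        assert abs(bottom - 110.0) <= step
        assert top >= cls.interface_depth

    def test_window_extends_to_bottom_without_sulfide_or_depletion(self):
        depths = np.arange(0, 101, 10.0)
        o2 = np.where(depths < 50, 200.0, 0.5)
        no3 = np.full_like(depths, 5.0)
        snap = WaterColumnSnapshot(
            "t", "", {
                "o2": DepthProfile("o2", depths, o2, 0.1),
                "no3": DepthProfile("no3", depths, no3, 0.05),
            },
        )
        cls = classify_redox(snap)
        assert cls.niche_window == (50.0, 100.0)

    def test_fully_oxic_column_has_no_window(self):
        snap = WaterColumnSnapshot(
            "t", "", {"o2": o2_prof([10, 20, 30, 40], [300, 250, 200, 150])}
        )
        cls = classify_redox(snap)
        assert cls.niche_window is None
        assert set(cls.per_depth_class) == {"oxic"}

    def test_labels_partition_the_grid(self, quiet_snapshot):
        cls = classify_redox(quiet_snapshot)
        allowed = {"oxic", "anoxic_nitrate_replete", "anoxic_nitrate_depleted", "euxinic"}
        assert set(cls.per_depth_class) <= allowed
        assert len(cls.per_depth_class) == len(cls.depths)

    def test_missing_o2_profile_is_error(self):
        snap = WaterColumnSnapshot(
            "t", "", {"no3": DepthProfile("no3", [1, 2], [1, 1])}
        )
        with pytest.raises(ValidationError, match="o2"):
            classify_redox(snap)

    def test_window_bounded_by_landmarks(self, quiet_snapshot):
        cls = classify_redox(quiet_snapshot)
        bounds = [
            d for d in (cls.no3_depletion_depth, cls.sulfide_onset_depth)
            if d is not None
        ]
        assert cls.niche_window[1] <= min(bounds)


class TestPopulationInWindow:
    @staticmethod
    def _cls(window):
        from types import SimpleNamespace

        return SimpleNamespace(niche_window=window)

    def test_all_mass_at_single_depth_inside_window(self):
        prof = DepthProfile("abundance", [80, 90, 100, 110, 120], [0, 0, 500, 0, 0])
        frac = population_in_window(prof, self._cls((85.0, 115.0)))
        assert frac == pytest.approx(1.0)

    def test_absent_window_gives_zero(self):
        prof = DepthProfile("abundance", [80, 90, 100], [0, 10, 0])
        assert population_in_window(prof, self._cls(None)) == 0.0

    def test_zero_total_abundance_is_undefined(self):
        prof = DepthProfile("abundance", [80, 90, 100], [0, 0, 0])
        assert population_in_window(prof, self._cls((80.0, 100.0))) is None

    def test_gaussian_peak_within_three_widths(self):
        # >= 99% of a Gaussian's mass lies within +-3 sigma
        z = np.arange(0, 200.5, 0.5)
        vals = 1000 * np.exp(-0.5 * ((z - 100) / 5.0) ** 2)
        prof = DepthProfile("abundance", z, vals)
        frac = population_in_window(prof, self._cls((85.0, 115.0)))
        assert frac >= 0.99

    @given(scale=st.floats(1e-3, 1e6))
    def test_invariant_under_positive_scaling(self, scale):
        z = np.arange(0, 101, 5.0)
        vals = np.exp(-0.5 * ((z - 50) / 10.0) ** 2)
        a = population_in_window(
            DepthProfile("abundance", z, vals), self._cls((40.0, 70.0))
        )
        b = population_in_window(
            DepthProfile("abundance", z, vals * scale), self._cls((40.0, 70.0))
        )
        assert a == pytest.approx(b, rel=1e-9)


def test_landmark_recovery_on_noise_free_defaults(quiet_snapshot):
    from redoxniche import recover_landmarks

    lm = recover_landmarks(quiet_snapshot)
    truth = quiet_snapshot.ground_truth
    step = truth.grid_step
    assert abs(lm.interface_depth - truth.oxycline_depth) <= step
    assert abs(lm.no3_depletion_depth - truth.no3_depletion_depth) <= step
    assert abs(lm.sulfide_onset_depth - truth.sulfide_onset_depth) <= step
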