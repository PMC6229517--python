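import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from eshval import (
    BP_BANDS,
    ESH_IP2_PART1,
    ESH_IP2_PART2,
    HR_BANDS,
    BandCounts,
    BandScheme,
    GeneratorConfig,
    classify_bands,
    generate_study,
    grade_part1,
    grade_part2,
    grade_part3,
    pair_study,
    profile_subjects,
    validate_device,
)
from eshval.pairing import ComparisonRecord

from conftest import make_session


def record(abs_diff, subject_id="S1", metric="sbp", test_label="BP2"):
    return ComparisonRecord(
        subject_id=subject_id,
        test_label=test_label,
        chosen_reference_label={"BP2": "BP1", "BP4": "BP3", "BP6": "BP5"}[test_label],
        metric=metric,
        signed_difference=float(abs_diff),
        absolute_difference=float(abs_diff),
        test_value=120.0 + abs_diff,
        reference_value=120.0,
    )


def records_from_diffs(diffs, metric="sbp"):
    """One subject per 3 diffs, labels BP2/BP4/BP6 cycling."""
    labels = ["BP2", "BP4", "BP6"]
    return [
        record(d, subject_id=f"S{i // 3}", metric=metric, test_label=labels[i % 3])
        for i, d in enumerate(diffs)
    ]


class TestClassifyBands:
    def test_worked_example(self):
        """Diffs {0,5,7,12,16} vs (5,10,15): within-counts 2, 3, 4 of 5."""
        counts = classify_bands(records_from_diffs([0, 5, 7, 12, 16]), BP_BANDS)
        assert counts.achieved == (2, 3, 4)
        assert counts.n_total == 5

    def test_boundary_is_inclusive_by_default(self):
        counts = classify_bands(records_from_diffs([5, 10, 15]), BP_BANDS)
        assert counts.achieved == (1, 2, 3)
        strict = classify_bands(
            records_from_diffs([5, 10, 15]), BP_BANDS, inclusive=False
        )
        assert strict.achieved == (0, 1, 2)

    def test_all_zero_diffs_fill_every_band(self):
        counts = classify_bands(records_from_diffs([0] * 6), BP_BANDS)
        assert counts.achieved == (6, 6, 6)

    def test_mixed_metrics_rejected(self):
        recs = [record(1, metric="sbp"), record(1, metric="dbp")]
        with pytest.raises(ValueError, match="metric"):
            classify_bands(recs, BP_BANDS)

    @given(
        diffs=st.lists(st.floats(0, 40), min_size=1, max_size=30),
        widen=st.floats(0.1, 10),
    )
    @settings(derandomize=True, max_examples=100)
    def test_monotone_in_thresholds(self, diffs, widen):
        """Counts are nested, and widening a band never shrinks its count."""
        recs = records_from_diffs(diffs)
        counts = classify_bands(recs, BP_BANDS)
        assert counts.n_within1 <= counts.n_within2 <= counts.n_within3
        wider = BandScheme(BP_BANDS.band1 + widen, BP_BANDS.band2 + widen,
                           BP_BANDS.band3 + widen)
        assert classify_bands(recs, wider).n_within1 >= counts.n_within1


class TestGradePart1:
    @pytest.mark.parametrize(
        "achieved,expected",
        [
            # published worked examples: all graded Pass
            ((71, 95, 98), True),   # SBP: 71 < 73 but other two meet two_of
            ((84, 91, 98), True),   # DBP
            ((90, 94, 98), True),   # HR (same requirement counts)
            # all-of floor violated even though two_of is satisfied twice
            ((64, 99, 99), False),
            # only one band meets the two_of minimum
            ((72, 86, 99), False),
            ((73, 87, 96), True),   # exactly at the two_of minima
            ((65, 81, 93), False),  # all_of floor alone is not enough
        ],
    )
    def test_grading_rule(self, achieved, expected):
        counts = BandCounts(99, *achieved)
        assert grade_part1(counts, ESH_IP2_PART1) is expected


class TestProfileSubjects:
    def test_worked_example(self):
        """Diffs {2,5,9} with band1=5: two of three within (inclusive)."""
        profiles = profile_subjects(records_from_diffs([2, 5, 9]), BP_BANDS)
        assert profiles[0].n_of_3_within_band1 == 2

    @pytest.mark.parametrize("diffs,expected", [([0, 0, 0], 3), ([6, 7, 8], 0)])
    def test_extremes(self, diffs, expected):
        profiles = profile_subjects(records_from_diffs(diffs), BP_BANDS)
        assert all(p.n_of_3_within_band1 == expected for p in profiles)

    def test_wrong_comparison_count_rejected(self):
        with pytest.raises(ValueError, match="exactly 3"):
            profile_subjects(records_from_diffs([1, 2]), BP_BANDS)


class TestGradePart2:
    @pytest.mark.parametrize(
        "n_two,n_zero,expected",
        [
            (27, 0, True),   # published SBP subject counts
            (30, 0, True),   # published DBP subject counts
            (31, 1, True),   # published HR subject counts
            (23, 0, False),  # one subject short of the >=24 quota
            (24, 4, False),  # too many subjects with no close comparison
            (24, 3, True),   # exactly at both limits
        ],
    )
    def test_grading_rule(self, n_two, n_zero, expected):
        # build 33 profiles realizing the requested counts
        diffs = []
        for i in range(33):
            if i < n_zero:
                diffs += [9, 9, 9]
            elif i < n_zero + n_two:
                diffs += [1, 1, 9]
            else:
                diffs += [1, 9, 9]
        profiles = profile_subjects(records_from_diffs(diffs), BP_BANDS)
        result = grade_part2(profiles, ESH_IP2_PART2)
        assert (result.n_two_of_three, result.n_zero_of_three) == (n_two, n_zero)
        assert result.passed is expected

    def test_three_of_three_counts_toward_quota(self):
        """'2/3' means at least two of three, so 3/3 subjects count."""
        diffs = [0, 0, 0] * 33
        profiles = profile_subjects(records_from_diffs(diffs), BP_BANDS)
        result = grade_part2(profiles)
        assert result.n_two_of_three == 33

    def test_warns_off_protocol_size(self):
        profiles = profile_subjects(records_from_diffs([1, 1, 1]), BP_BANDS)
        with pytest.warns(UserWarning, match="33"):
            grade_part2(profiles)


class TestGradePart3:
    @pytest.mark.parametrize(
        "p1,p2,expected",
        [(True, True, True), (True, False, False),
         (False, True, False), (False, False, False)],
    )
    def test_conjunction(self, p1, p2, expected):
        assert grade_part3(p1, p2) is expected


class TestValidateDevice:
    def test_zero_error_device_passes_everything(self, zero_error_config):
        study = generate_study(zero_error_config)
        for metric in ("sbp", "dbp", "hr"):
            report = validate_device(study, metric)
            assert report.part1_pass and report.part2_pass and report.part3_pass
            assert report.band_counts.achieved == (99, 99, 99)
            assert report.mean_signed_difference == 0

    def test_constant_large_bias_fails_part1(self, zero_error_config):
        biased = dataclasses.replace(
            zero_error_config,
            sbp=dataclasses.replace(zero_error_config.sbp, device_bias=20.0),
        )
        report = validate_device(generate_study(biased), "sbp")
        assert report.band_counts.achieved == (0, 0, 0)
        assert not report.part1_pass and not report.part3_pass

    def test_hr_uses_bpm_bands(self, default_study):
        assert validate_device(default_study, "hr").scheme == HR_BANDS
        assert validate_device(default_study, "sbp").scheme == BP_BANDS

    def test_report_internal_consistency(self, default_study):
        for metric in ("sbp", "dbp", "hr"):
            r = validate_device(default_study, metric)
            assert r.part3_pass == (r.part1_pass and r.part2_pass)
            c = r.band_counts
            assert 0 <= c.n_within1 <= c.n_within2 <= c.n_within3 <= c.n_total == 99
            assert len(r.subject_profiles) == 33

    def test_off_protocol_size_warns(self):
        sessions = [make_session(f"S{i}") for i in range(5)]
        with pytest.warns(UserWarning, match="99"):
            validate_device(sessions, "sbp")

    def test_grading_monotone_under_improvement(self):
        """Shrinking any absolute difference never flips a pass to a fail."""
        rng = np.random.default_rng(42)
        for _ in range(20):
            diffs = rng.integers(0, 20, size=33 * 3).astype(float)
            recs = records_from_diffs(diffs)
            base_p1 = grade_part1(classify_bands(recs, BP_BANDS))
            base_p2 = grade_part2(profile_subjects(recs, BP_BANDS)).passed
            j = int(rng.integers(len(diffs)))
            improved = diffs.copy()
            improved[j] = max(0.0, improved[j] - float(rng.integers(1, 10)))
            recs2 = records_from_diffs(improved)
            new_p1 = grade_part1(classify_bands(recs2, BP_BANDS))
            new_p2 = grade_part2(profile_subjects(recs2, BP_BANDS)).passed
            assert new_p1 >= base_p1
            assert new_p2 >= base_p2


class TestRequirementConstants:
    def test_scheme_validation(self):
        with pytest.raises(ValueError):
            BandScheme(10, 5, 15)
        with pytest.raises(ValueError):
            BandScheme(0, 5, 15)

    def test_band_count_monotonicity_enforced(self):
        with pytest.raises(ValueError):
            BandCounts(n_total=99, n_within1=50, n_within2=40, n_within3=60)
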