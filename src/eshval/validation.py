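"""Band classification and ESH-IP2 part 1/2/3 grading.

The protocol grades a device in three parts, computed over the 99
device-reference comparisons of a 33-subject study:

* **Part 1** (measurement level): the counts of absolute differences within
  5, 10 and 15 mm Hg must meet at least two of the "two of" minima
  (73/87/96) and all of the "all of" minima (65/81/93).
* **Part 2** (subject level): at least 24 of 33 subjects must have >= 2 of
  their 3 comparisons within the narrowest band, and at most 3 subjects may
  have none within it.
* **Part 3**: pass iff parts 1 and 2 both pass.

Heart rate uses the same requirement counts with narrower bands of
3, 5 and 8 bpm — an extension of the protocol, which itself covers only
blood pressure. "Within x" is read inclusively (absolute difference <= x);
a strict-inequality switch exists for sensitivity checks.

Requirement constants are stored as the printed absolute counts, valid for
99 comparisons over 33 subjects; the engine warns (but proceeds) when the
study size differs, since the printed counts are then not meaningful quotas.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .pairing import ComparisonRecord, pair_study
from .session_model import MeasurementSession
from .summary_stats import difference_summary

__all__ = [
    "BandScheme",
    "BandCounts",
    "Part1Requirements",
    "Part2Requirements",
    "Part2Result",
    "SubjectBandProfile",
    "ValidationReport",
    "BP_BANDS",
    "HR_BANDS",
    "ESH_IP2_PART1",
    "ESH_IP2_PART2",
    "scheme_for_metric",
    "classify_bands",
    "grade_part1",
    "profile_subjects",
    "grade_part2",
    "grade_part3",
    "validate_device",
]


@dataclass(frozen=True)
class BandScheme:
    """Three nested absolute-difference thresholds (units of the metric)."""

    band1: float
    band2: float
    band3: float

    def __post_init__(self) -> None:
        if not (0 < self.band1 < self.band2 < self.band3):
            raise ValueError(
                f"bands must satisfy 0 < band1 < band2 < band3, got "
                f"({self.band1}, {self.band2}, {self.band3})"
            )

    @property
    def thresholds(self) -> tuple[float, float, float]:
        return (self.band1, self.band2, self.band3)


#: Blood-pressure bands, mm Hg.
BP_BANDS = BandScheme(5, 10, 15)
#: Heart-rate bands, bpm (narrower than the BP bands, on the HR scale).
HR_BANDS = BandScheme(3, 5, 8)


def scheme_for_metric(metric: str) -> BandScheme:
    return HR_BANDS if metric == "hr" else BP_BANDS


@dataclass(frozen=True)
class BandCounts:
    """Counts of comparisons within each band (cumulative, so monotone)."""

    n_total: int
    n_within1: int
    n_within2: int
    n_within3: int

    def __post_init__(self) -> None:
        if not (0 <= self.n_within1 <= self.n_within2 <= self.n_within3 <= self.n_total):
            raise ValueError(
                f"band counts must be monotone within total: {self}"
            )

    @property
    def achieved(self) -> tuple[int, int, int]:
        return (self.n_within1, self.n_within2, self.n_within3)


@dataclass(frozen=True)
class Part1Requirements:
    """Measurement-level minima: two of ``two_of`` and all of ``all_of``."""

    two_of: tuple[int, int, int] = (73, 87, 96)
    all_of: tuple[int, int, int] = (65, 81, 93)

    def __post_init__(self) -> None:
        if any(t < a for t, a in zip(self.two_of, self.all_of)):
            raise ValueError("each two_of minimum must be >= its all_of minimum")


@dataclass(frozen=True)
class Part2Requirements:
    """Subject-level quota: >=24 subjects with 2/3 in band 1, <=3 with 0/3."""

    min_subjects_two_of_three: int = 24
    max_subjects_zero_of_three: int = 3

    def __post_init__(self) -> None:
        if self.min_subjects_two_of_three < 0 or self.max_subjects_zero_of_three < 0:
            raise ValueError("part-2 requirements must be nonnegative")


ESH_IP2_PART1 = Part1Requirements()
ESH_IP2_PART2 = Part2Requirements()

#: Study size the printed requirement counts are defined for.
PROTOCOL_N_SUBJECTS = 33
PROTOCOL_N_COMPARISONS = 99


@dataclass(frozen=True)
class SubjectBandProfile:
    """How many of a subject's 3 comparisons fall within the narrowest band."""

    subject_id: str
    n_of_3_within_band1: int

    def __post_init__(self) -> None:
        if self.n_of_3_within_band1 not in (0, 1, 2, 3):
            raise ValueError("n_of_3_within_band1 must be in {0,1,2,3}")


@dataclass(frozen=True)
class Part2Result:
    n_two_of_three: int
    n_zero_of_three: int
    passed: bool


def _check_single_metric(records: Sequence[ComparisonRecord]) -> str:
    metrics = {r.metric for r in records}
    if len(metrics) != 1:
        raise ValueError(f"records must share one metric, got {sorted(metrics)}")
    return metrics.pop()


def classify_bands(
    records: Sequence[ComparisonRecord],
    scheme: BandScheme,
    inclusive: bool = True,
) -> BandCounts:
    """Count absolute differences within each band threshold.

    ``inclusive`` (the default) counts a difference exactly on a threshold
    as within it.
    """
    if not records:
        raise ValueError("cannot classify an empty record collection")
    _check_single_metric(records)
    diffs = np.array([r.absolute_difference for r in records])
    op = np.less_equal if inclusive else np.less
    n1, n2, n3 = (int(op(diffs, t).sum()) for t in scheme.thresholds)
    return BandCounts(n_total=len(records), n_within1=n1, n_within2=n2, n_within3=n3)


def grade_part1(counts: BandCounts, req: Part1Requirements = ESH_IP2_PART1) -> bool:
    """Part-1 verdict: two of the two_of minima met AND all all_of minima met."""
    achieved = counts.achieved
    n_two_of = sum(a >= m for a, m in zip(achieved, req.two_of))
    all_of_ok = all(a >= m for a, m in zip(achieved, req.all_of))
    return n_two_of >= 2 and all_of_ok


def profile_subjects(
    records: Sequence[ComparisonRecord],
    scheme: BandScheme,
    inclusive: bool = True,
) -> list[SubjectBandProfile]:
    """Per-subject count of comparisons (of exactly 3) within the first band."""
    if not records:
        raise ValueError("cannot profile an empty record collection")
    _check_single_metric(records)
    by_subject: dict[str, list[float]] = {}
    for r in records:
        by_subject.setdefault(r.subject_id, []).append(r.absolute_difference)
    bad = {sid: len(d) for sid, d in by_subject.items() if len(d) != 3}
    if bad:
        raise ValueError(f"subjects without exactly 3 comparisons: {bad}")
    within = (
        (lambda d: d <= scheme.band1) if inclusive else (lambda d: d < scheme.band1)
    )
    return [
        SubjectBandProfile(subject_id=sid, n_of_3_within_band1=sum(map(within, diffs)))
        for sid, diffs in by_subject.items()
    ]


def grade_part2(
    profiles: Sequence[SubjectBandProfile],
    req: Part2Requirements = ESH_IP2_PART2,
) -> Part2Result:
    """Part-2 verdict from subject profiles.

    "2/3" counts subjects with *at least* two of three comparisons in the
    narrowest band (so 3/3 subjects count too); "0/3" counts subjects with
    none in it.
    """
    if len(profiles) != PROTOCOL_N_SUBJECTS:
        warnings.warn(
            f"part-2 requirement counts are defined for {PROTOCOL_N_SUBJECTS} "
            f"subjects; got {len(profiles)}",
            stacklevel=2,
        )
    n_two = sum(p.n_of_3_within_band1 >= 2 for p in profiles)
    n_zero = sum(p.n_of_3_within_band1 == 0 for p in profiles)
    passed = (
        n_two >= req.min_subjects_two_of_three
        and n_zero <= req.max_subjects_zero_of_three
    )
    return Part2Result(n_two_of_three=n_two, n_zero_of_three=n_zero, passed=passed)


def grade_part3(part1_pass: bool, part2_pass: bool) -> bool:
    """Overall verdict: pass iff parts 1 and 2 both pass."""
    return part1_pass and part2_pass


@dataclass(frozen=True)
class ValidationReport:
    """Full per-metric validation outcome with the numbers behind it."""

    metric: str
    scheme: BandScheme
    part1_requirements: Part1Requirements
    part2_requirements: Part2Requirements
    band_counts: BandCounts
    part1_pass: bool
    subject_profiles: tuple[SubjectBandProfile, ...]
    n_subjects_two_of_three: int
    n_subjects_zero_of_three: int
    part2_pass: bool
    part3_pass: bool
    mean_signed_difference: float
    sd_signed_difference: float
    mean_absolute_difference: float
    sd_absolute_difference: float
    options: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.part3_pass != (self.part1_pass and self.part2_pass):
            raise ValueError("part3_pass must equal part1_pass AND part2_pass")


def validate_device(
    sessions: Iterable[MeasurementSession],
    metric: str,
    scheme: BandScheme | None = None,
    part1_requirements: Part1Requirements = ESH_IP2_PART1,
    part2_requirements: Part2Requirements = ESH_IP2_PART2,
    joint_flank_choice: bool = False,
    inclusive: bool = True,
) -> ValidationReport:
    """Run the full pipeline for one metric: pair, classify, grade, summarize.

    BP metrics use the (5, 10, 15) mm Hg scheme, heart rate (3, 5, 8) bpm,
    unless ``scheme`` overrides. Warns when the study is not the protocol's
    33 subjects / 99 comparisons, because the requirement constants are
    absolute counts printed for that size.
    """
    sessions = list(sessions)
    if scheme is None:
        scheme = scheme_for_metric(metric)
    records = pair_study(sessions, metric, joint_flank_choice=joint_flank_choice)
    if len(records) != PROTOCOL_N_COMPARISONS:
        warnings.warn(
            f"part-1 requirement counts are defined for "
            f"{PROTOCOL_N_COMPARISONS} comparisons; got {len(records)}",
            stacklevel=2,
        )
    counts = classify_bands(records, scheme, inclusive=inclusive)
    part1 = grade_part1(counts, part1_requirements)
    profiles = profile_subjects(records, scheme, inclusive=inclusive)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # session-count warning already issued above
        part2 = grade_part2(profiles, part2_requirements)
    summary = difference_summary(records)
    return ValidationReport(
        metric=metric,
        scheme=scheme,
        part1_requirements=part1_requirements,
        part2_requirements=part2_requirements,
        band_counts=counts,
        part1_pass=part1,
        subject_profiles=tuple(profiles),
        n_subjects_two_of_three=part2.n_two_of_three,
        n_subjects_zero_of_three=part2.n_zero_of_three,
        part2_pass=part2.passed,
        part3_pass=grade_part3(part1, part2.passed),
        mean_signed_difference=summary.mean_signed,
        sd_signed_difference=summary.sd_signed,
        mean_absolute_difference=summary.mean_absolute,
        sd_absolute_difference=summary.sd_absolute,
        options={
            "joint_flank_choice": joint_flank_choice,
            "inclusive_bands": inclusive,
            "tie_break": "preceding_flank",
        },
    )
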