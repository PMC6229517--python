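"""Favorable-comparison pairing of test readings to flanking references.

Each test reading (BP2, BP4, BP6) sits between two reference readings:
BP2 between BP1 and BP3, BP4 between BP3 and BP5, BP6 between BP5 and BP7.
The protocol compares every test reading against both flanks and keeps,
per comparison, whichever difference is more favorable to the device —
the one smaller in absolute value. Ties break to the preceding (earlier)
reference reading, a deterministic, time-ordered choice.

Differences are oriented test minus reference. By default the favorable
flank is chosen independently per metric (SBP, DBP and HR may each pick a
different flank for the same test reading); ``joint_flank_choice`` instead
forces one flank shared by SBP and DBP, for sensitivity analysis.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from .session_model import METRICS, MeasurementSession, SessionError

__all__ = [
    "TEST_TO_FLANKS",
    "ComparisonRecord",
    "pair_session",
    "pair_study",
    "write_records",
]

#: Flanking reference labels for each test reading, in time order.
TEST_TO_FLANKS: dict[str, tuple[str, str]] = {
    "BP2": ("BP1", "BP3"),
    "BP4": ("BP3", "BP5"),
    "BP6": ("BP5", "BP7"),
}


@dataclass(frozen=True)
class ComparisonRecord:
    """One test reading paired with its chosen flanking reference.

    ``signed_difference`` is test minus reference; ``absolute_difference``
    its magnitude. ``test_value`` and ``reference_value`` carry the raw
    readings so downstream Bland-Altman analysis uses the same chosen flank
    as the grading.
    """

    subject_id: str
    test_label: str
    chosen_reference_label: str
    metric: str
    signed_difference: float
    absolute_difference: float
    test_value: float
    reference_value: float

    def __post_init__(self) -> None:
        if self.test_label not in TEST_TO_FLANKS:
            raise ValueError(f"invalid test label {self.test_label!r}")
        if self.chosen_reference_label not in TEST_TO_FLANKS[self.test_label]:
            raise ValueError(
                f"{self.chosen_reference_label!r} does not flank {self.test_label!r}"
            )
        if self.metric not in METRICS:
            raise ValueError(f"unknown metric {self.metric!r}")
        if abs(self.absolute_difference - abs(self.signed_difference)) > 1e-12:
            raise ValueError("absolute_difference must equal |signed_difference|")


def _choose_flank(
    session: MeasurementSession,
    test_label: str,
    metric: str,
    joint_flank_choice: bool,
) -> str:
    """Pick the favorable flank for one test reading.

    Per-metric mode minimizes the absolute difference for that metric alone.
    Joint mode (SBP/DBP only) minimizes the summed absolute SBP+DBP
    difference so both pressures share one flank. Ties go to the earlier
    flank in both modes.
    """
    early, late = TEST_TO_FLANKS[test_label]
    if joint_flank_choice and metric in ("sbp", "dbp"):
        crit = lambda flank: sum(
            abs(session.reading(test_label).value(m) - session.reading(flank).value(m))
            for m in ("sbp", "dbp")
        )
    else:
        crit = lambda flank: abs(
            session.reading(test_label).value(metric)
            - session.reading(flank).value(metric)
        )
    return early if crit(early) <= crit(late) else late


def pair_session(
    session: MeasurementSession,
    metric: str,
    joint_flank_choice: bool = False,
) -> list[ComparisonRecord]:
    """Return the three comparison records for one complete session."""
    if metric not in METRICS:
        raise ValueError(f"unknown metric {metric!r}; expected one of {METRICS}")
    session.require_complete()
    records = []
    for test_label in TEST_TO_FLANKS:
        chosen = _choose_flank(session, test_label, metric, joint_flank_choice)
        test_value = session.reading(test_label).value(metric)
        reference_value = session.reading(chosen).value(metric)
        diff = test_value - reference_value
        records.append(
            ComparisonRecord(
                subject_id=session.subject.subject_id,
                test_label=test_label,
                chosen_reference_label=chosen,
                metric=metric,
                signed_difference=diff,
                absolute_difference=abs(diff),
                test_value=test_value,
                reference_value=reference_value,
            )
        )
    return records


def pair_study(
    sessions: Iterable[MeasurementSession],
    metric: str,
    joint_flank_choice: bool = False,
) -> list[ComparisonRecord]:
    """Pair every session; 33 sessions yield the protocol's 99 records."""
    sessions = list(sessions)
    incomplete = [s.subject.subject_id for s in sessions if not s.is_complete]
    if incomplete:
        raise SessionError(f"incomplete sessions for subjects: {incomplete}")
    records: list[ComparisonRecord] = []
    for session in sessions:
        records.extend(pair_session(session, metric, joint_flank_choice))
    return records


def write_records(records: Sequence[ComparisonRecord], path: str | Path) -> None:
    """Export comparison records as CSV."""
    with Path(path).open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(
            [
                "subject_id",
                "test_label",
                "chosen_reference_label",
                "metric",
                "signed_difference",
                "absolute_difference",
            ]
        )
        for r in records:
            writer.writerow(
                [
                    r.subject_id,
                    r.test_label,
                    r.chosen_reference_label,
                    r.metric,
                    r.signed_difference,
                    r.absolute_difference,
                ]
            )
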