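"""Subjects, readings and nine-reading measurement sessions.

The ESH-IP2 protocol records nine consecutive blood-pressure readings per
subject on the same arm, alternating between the reference (standard) device
and the test device:

    BPA  entry reading, reference device
    BPB  device-detection reading, test device
    BP1  reference      BP2  test
    BP3  reference      BP4  test
    BP5  reference      BP6  test
    BP7  reference

BPA and BPB serve only to classify the subject at entry and to confirm the
test device detects a signal; the validation analysis uses BP1..BP7 only.
This module provides typed containers for those sessions plus CSV ingest and
egress, and the Quetelet body-mass-index helper used for eligibility.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

__all__ = [
    "LABELS",
    "ANALYSIS_LABELS",
    "REFERENCE_LABELS",
    "TEST_LABELS",
    "Subject",
    "Reading",
    "MeasurementSession",
    "SessionError",
    "role_for_label",
    "body_mass_index",
    "read_sessions",
    "write_sessions",
]

#: Protocol order of the nine reading slots.
LABELS: tuple[str, ...] = (
    "BPA", "BPB", "BP1", "BP2", "BP3", "BP4", "BP5", "BP6", "BP7",
)

#: Reference-device labels (standard device).
REFERENCE_LABELS = frozenset({"BPA", "BP1", "BP3", "BP5", "BP7"})

#: Test-device labels.
TEST_LABELS = frozenset({"BPB", "BP2", "BP4", "BP6"})

#: Labels that enter the validation analysis (entry/detection readings excluded).
ANALYSIS_LABELS: tuple[str, ...] = ("BP1", "BP2", "BP3", "BP4", "BP5", "BP6", "BP7")

#: Metrics recorded per reading.
METRICS: tuple[str, ...] = ("sbp", "dbp", "hr")

_COVARIATE_COLUMNS = ("age", "sex", "weight", "height", "arm_circumference")


class SessionError(ValueError):
    """Structural problem with a measurement session or its serialized form."""


def role_for_label(label: str) -> str:
    """Return ``"reference"`` or ``"test"`` for a protocol reading label."""
    if label in REFERENCE_LABELS:
        return "reference"
    if label in TEST_LABELS:
        return "test"
    raise SessionError(f"unknown reading label: {label!r}")


def body_mass_index(weight: float, height: float) -> float:
    """Quetelet's index: weight in kilograms over height in meters, squared.

    Obesity is conventionally BMI >= 30 kg/m^2, which is the inclusion
    boundary for the population this package's generator emulates.
    """
    if weight <= 0 or height <= 0:
        raise ValueError(
            f"weight and height must be positive, got weight={weight}, height={height}"
        )
    return weight / height**2


@dataclass(frozen=True)
class Subject:
    """A study participant. All covariates are optional.

    Units: age in years, weight in kilograms, height in meters,
    arm circumference in millimeters.
    """

    subject_id: str
    age: float | None = None
    sex: Literal["male", "female"] | None = None
    weight: float | None = None
    height: float | None = None
    arm_circumference: float | None = None

    def __post_init__(self) -> None:
        if not self.subject_id:
            raise SessionError("subject_id must be a non-empty string")
        if self.weight is not None and self.weight <= 0:
            raise SessionError(f"subject {self.subject_id}: weight must be > 0")
        if self.height is not None and self.height <= 0:
            raise SessionError(f"subject {self.subject_id}: height must be > 0")
        if self.sex is not None and self.sex not in ("male", "female"):
            raise SessionError(f"subject {self.subject_id}: sex must be male/female")

    @property
    def bmi(self) -> float | None:
        """BMI in kg/m^2, or None when weight or height is missing."""
        if self.weight is None or self.height is None:
            return None
        return body_mass_index(self.weight, self.height)


@dataclass(frozen=True)
class Reading:
    """One cuff reading: label, pressures in mm Hg, heart rate in bpm.

    The device role is determined by the label (reference vs test slots
    alternate in the protocol), so it is derived, never stored.
    """

    label: str
    sbp: float
    dbp: float
    hr: float

    def __post_init__(self) -> None:
        role_for_label(self.label)  # raises on unknown label
        if not (self.sbp > self.dbp > 0):
            raise SessionError(
                f"reading {self.label}: require sbp > dbp > 0, got "
                f"sbp={self.sbp}, dbp={self.dbp}"
            )
        if self.hr <= 0:
            raise SessionError(f"reading {self.label}: hr must be > 0, got {self.hr}")

    @property
    def role(self) -> str:
        return role_for_label(self.label)

    @property
    def in_analysis(self) -> bool:
        """True for BP1..BP7; BPA/BPB are entry readings, excluded downstream."""
        return self.label in ANALYSIS_LABELS

    def value(self, metric: str) -> float:
        if metric not in METRICS:
            raise ValueError(f"unknown metric {metric!r}; expected one of {METRICS}")
        return getattr(self, metric)


@dataclass(frozen=True)
class MeasurementSession:
    """One subject's ordered readings.

    A *complete* session has exactly nine readings, one per protocol label,
    in protocol order. Incomplete sessions can exist in permissive workflows
    but are rejected by the validation engine.
    """

    subject: Subject
    readings: tuple[Reading, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        object.__setattr__(self, "readings", tuple(self.readings))
        labels = [r.label for r in self.readings]
        if len(set(labels)) != len(labels):
            dupes = sorted({l for l in labels if labels.count(l) > 1})
            raise SessionError(
                f"subject {self.subject.subject_id}: duplicate labels {dupes}"
            )
        order = [LABELS.index(l) for l in labels]
        if order != sorted(order):
            raise SessionError(
                f"subject {self.subject.subject_id}: readings out of protocol order"
            )

    @property
    def is_complete(self) -> bool:
        return tuple(r.label for r in self.readings) == LABELS

    def require_complete(self) -> None:
        if not self.is_complete:
            have = {r.label for r in self.readings}
            missing = [l for l in LABELS if l not in have]
            raise SessionError(
                f"subject {self.subject.subject_id}: incomplete session, "
                f"missing {missing}"
            )

    def reading(self, label: str) -> Reading:
        for r in self.readings:
            if r.label == label:
                return r
        raise SessionError(
            f"subject {self.subject.subject_id}: no reading labeled {label}"
        )


_REQUIRED_COLUMNS = ("subject_id", "label", "sbp", "dbp", "hr")


def _parse_float(text: str, column: str, row_num: int) -> float:
    try:
        return float(text)
    except ValueError:
        raise SessionError(f"row {row_num}: column {column!r} is not numeric: {text!r}")


def read_sessions(
    path: str | Path,
    strictness: Literal["strict", "permissive"] = "strict",
    height_unit: Literal["m", "cm"] = "m",
) -> list[MeasurementSession]:
    """Read measurement sessions from a long-format CSV.

    One row per reading with columns ``subject_id,label,sbp,dbp,hr`` and
    optional subject covariates (``age,sex,weight,height,arm_circumference``).
    Clinical tables often report height in centimeters; pass
    ``height_unit="cm"`` to convert to meters on ingest.

    In ``strict`` mode every session must be complete (all nine labels);
    ``permissive`` mode returns incomplete sessions as-is, leaving exclusion
    to the caller — the validation engine itself always requires complete
    sessions because the protocol counts are defined over exactly three
    comparisons per subject.
    """
    path = Path(path)
    if strictness not in ("strict", "permissive"):
        raise ValueError(f"strictness must be 'strict' or 'permissive', got {strictness!r}")
    with path.open(newline="", encoding="utf-8") as fh:
        # '#'-prefixed header comments carry provenance (e.g. generator seed)
        rows = [r for r in csv.reader(fh) if r and not r[0].startswith("#")]
    if not rows:
        raise SessionError(f"{path}: empty file")
    header = [h.strip() for h in rows[0]]
    missing = [c for c in _REQUIRED_COLUMNS if c not in header]
    if missing:
        raise SessionError(f"{path}: missing required columns {missing}")
    col = {name: header.index(name) for name in header}
    has_cov = [c for c in _COVARIATE_COLUMNS if c in col]

    per_subject: dict[str, list[Reading]] = {}
    subjects: dict[str, Subject] = {}
    seen_pairs: set[tuple[str, str]] = set()
    for row_num, row in enumerate(rows[1:], start=2):
        if len(row) != len(header):
            raise SessionError(f"row {row_num}: expected {len(header)} fields, got {len(row)}")
        sid = row[col["subject_id"]].strip()
        label = row[col["label"]].strip()
        if label not in LABELS:
            raise SessionError(f"row {row_num}: unknown label {label!r}")
        if (sid, label) in seen_pairs:
            raise SessionError(f"row {row_num}: duplicate reading ({sid}, {label})")
        seen_pairs.add((sid, label))
        reading = Reading(
            label=label,
            sbp=_parse_float(row[col["sbp"]], "sbp", row_num),
            dbp=_parse_float(row[col["dbp"]], "dbp", row_num),
            hr=_parse_float(row[col["hr"]], "hr", row_num),
        )
        per_subject.setdefault(sid, []).append(reading)
        if sid not in subjects:
            cov: dict[str, object] = {}
            for c in has_cov:
                raw = row[col[c]].strip()
                if raw == "":
                    continue
                if c == "sex":
                    cov[c] = raw
                else:
                    cov[c] = _parse_float(raw, c, row_num)
            if height_unit == "cm" and "height" in cov:
                cov["height"] = float(cov["height"]) / 100.0
            subjects[sid] = Subject(subject_id=sid, **cov)  # type: ignore[arg-type]

    sessions = []
    for sid, readings in per_subject.items():
        readings.sort(key=lambda r: LABELS.index(r.label))
        session = MeasurementSession(subject=subjects[sid], readings=tuple(readings))
        if strictness == "strict":
            session.require_complete()
        sessions.append(session)
    return sessions


def write_sessions(
    sessions: Iterable[MeasurementSession],
    path: str | Path,
    header_comment: str | None = None,
) -> None:
    """Write sessions to CSV such that :func:`read_sessions` inverts it.

    Covariate columns are included whenever any subject carries one.
    ``header_comment`` (e.g. a generator seed) is written as a ``#`` line.
    """
    sessions = list(sessions)
    used_cov = [
        c for c in _COVARIATE_COLUMNS
        if any(getattr(s.subject, c) is not None for s in sessions)
    ]
    header = list(_REQUIRED_COLUMNS) + used_cov
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        writer = csv.writer(fh)
        writer.writerow(header)
        for session in sessions:
            subj = session.subject
            cov_values = [
                "" if getattr(subj, c) is None else getattr(subj, c) for c in used_cov
            ]
            for r in session.readings:
                writer.writerow(
                    [subj.subject_id, r.label, _fmt(r.sbp), _fmt(r.dbp), _fmt(r.hr)]
                    + [v if isinstance(v, str) else _fmt(v) for v in cov_values]
                )


def _fmt(x: float) -> str:
    # integers round-trip without a trailing ".0"; floats keep full repr
    return str(int(x)) if float(x).is_integer() else repr(float(x))
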