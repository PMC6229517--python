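"""Study-level reports: JSON serialization and protocol-style text tables.

A :class:`StudyReport` bundles per-metric validation reports with study
metadata and the engine options that produced them (tie-breaking, band
inclusivity, flank mode) — the protocol's favorable-comparison sentence is
ambiguous enough that option provenance belongs in every report.

The public functions here are the package's batch entry points:
:func:`validate_study` runs the whole pipeline on in-memory sessions,
:func:`validate_csv` on a CSV file (writing JSON and text outputs), and
:func:`simulate_to_csv` writes a generated study with its seed recorded in
a header comment.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from .session_model import MeasurementSession, read_sessions, write_sessions
from .synthetic import GeneratorConfig, generate_study
from .validation import (
    BandCounts,
    BandScheme,
    Part1Requirements,
    Part2Requirements,
    SubjectBandProfile,
    ValidationReport,
    validate_device,
)

__all__ = [
    "StudyReport",
    "validate_study",
    "validate_csv",
    "simulate_to_csv",
    "render_tables",
]


@dataclass(frozen=True)
class StudyReport:
    """Per-metric validation reports plus study metadata."""

    n_subjects: int
    reports: dict[str, ValidationReport]
    metadata: dict = field(default_factory=dict)

    @property
    def all_pass(self) -> bool:
        return all(r.part3_pass for r in self.reports.values())

    def to_dict(self) -> dict:
        return {
            "n_subjects": self.n_subjects,
            "metadata": self.metadata,
            "reports": {m: asdict(r) for m, r in self.reports.items()},
        }

    def to_json(self, indent: int = 2) -> str:
        return json.dumps(self.to_dict(), indent=indent)

    @classmethod
    def from_dict(cls, data: dict) -> "StudyReport":
        reports = {}
        for metric, rd in data["reports"].items():
            rd = dict(rd)
            rd["scheme"] = BandScheme(**rd["scheme"])
            rd["part1_requirements"] = Part1Requirements(
                two_of=tuple(rd["part1_requirements"]["two_of"]),
                all_of=tuple(rd["part1_requirements"]["all_of"]),
            )
            rd["part2_requirements"] = Part2Requirements(**rd["part2_requirements"])
            rd["band_counts"] = BandCounts(**rd["band_counts"])
            rd["subject_profiles"] = tuple(
                SubjectBandProfile(**p) for p in rd["subject_profiles"]
            )
            reports[metric] = ValidationReport(**rd)
        return cls(
            n_subjects=data["n_subjects"],
            reports=reports,
            metadata=data.get("metadata", {}),
        )

    @classmethod
    def from_json(cls, text: str) -> "StudyReport":
        return cls.from_dict(json.loads(text))


def validate_study(
    sessions: Iterable[MeasurementSession],
    metrics: Sequence[str] = ("sbp", "dbp", "hr"),
    joint_flank_choice: bool = False,
    inclusive: bool = True,
    metadata: dict | None = None,
) -> StudyReport:
    """Validate a study for every requested metric."""
    sessions = list(sessions)
    reports = {
        m: validate_device(
            sessions, m, joint_flank_choice=joint_flank_choice, inclusive=inclusive
        )
        for m in metrics
    }
    meta = {
        "n_subjects": len(sessions),
        "joint_flank_choice": joint_flank_choice,
        "inclusive_bands": inclusive,
        "tie_break": "preceding_flank",
    }
    if metadata:
        meta.update(metadata)
    return StudyReport(n_subjects=len(sessions), reports=reports, metadata=meta)


def validate_csv(
    input_path: str | Path,
    metrics: Sequence[str] = ("sbp", "dbp", "hr"),
    out_dir: str | Path | None = None,
    joint_flank_choice: bool = False,
    inclusive: bool = True,
) -> StudyReport:
    """Validate a CSV study; optionally write JSON and text reports.

    With ``out_dir`` set, writes ``report.json`` and ``report.txt`` there.
    Protocol failure is an outcome, not an error: inspect
    ``StudyReport.all_pass``. Malformed input raises.
    """
    sessions = read_sessions(input_path, strictness="strict")
    report = validate_study(
        sessions,
        metrics,
        joint_flank_choice=joint_flank_choice,
        inclusive=inclusive,
        metadata={"input_path": str(input_path)},
    )
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        (out_dir / "report.json").write_text(report.to_json())
        (out_dir / "report.txt").write_text(render_tables(report))
    return report


def simulate_to_csv(config: GeneratorConfig, out_path: str | Path) -> list[MeasurementSession]:
    """Generate a study and write it as CSV, recording the seed in a comment."""
    sessions = generate_study(config)
    write_sessions(
        sessions,
        out_path,
        header_comment=f"synthetic study; seed={config.seed}; "
        f"n_subjects={config.n_subjects}",
    )
    return sessions


_METRIC_TITLES = {
    "sbp": "Systolic blood pressure",
    "dbp": "Diastolic blood pressure",
    "hr": "Heart rate",
}


def _unit(metric: str) -> str:
    return "bpm" if metric == "hr" else "mm Hg"


def _pf(flag: bool) -> str:
    return "Pass" if flag else "Fail"


def render_tables(report: StudyReport) -> str:
    """Render fixed-width text tables in the protocol's reporting layout.

    One block per metric: part-1 rows ("Two of", "All of", achieved counts,
    grade, mean (SD)), then part-2/part-3 rows with the subject quotas.
    A report with no metrics renders the header only.
    """
    lines = [
        "ESH-IP2 validation report",
        f"Subjects: {report.n_subjects}",
        "",
    ]
    for metric, r in report.reports.items():
        title = _METRIC_TITLES.get(metric, metric)
        unit = _unit(metric)
        b1, b2, b3 = r.scheme.thresholds
        band_hdr = "".join(f"{f'<={_fmt_band(b)} {unit}':>12}" for b in (b1, b2, b3))
        lines += [
            f"== {title} ==",
            "Part 1" + " " * 14 + band_hdr + f"{'Grade 1':>10}{'Mean (SD)':>14}",
            "  Pass requirements",
            "    Two of      "
            + "".join(f"{m:>12}" for m in r.part1_requirements.two_of),
            "    All of      "
            + "".join(f"{m:>12}" for m in r.part1_requirements.all_of),
            "  Achieved      "
            + "".join(f"{c:>12}" for c in r.band_counts.achieved)
            + f"{_pf(r.part1_pass):>10}"
            + f"{r.mean_signed_difference:>8.2f} ({r.sd_signed_difference:.2f})",
            "",
            f"Part 2{'':>14}{f'2/3 <={_fmt_band(b1)}':>12}{f'0/3 <={_fmt_band(b1)}':>12}"
            + f"{'Grade 2':>10}{'Grade 3':>10}",
            "  Pass requirements"
            + f"{'>=' + str(r.part2_requirements.min_subjects_two_of_three):>9}"
            + f"{'<=' + str(r.part2_requirements.max_subjects_zero_of_three):>12}",
            "  Achieved      "
            + f"{r.n_subjects_two_of_three:>12}{r.n_subjects_zero_of_three:>12}"
            + f"{_pf(r.part2_pass):>10}{_pf(r.part3_pass):>10}",
            f"  Part 3: {_pf(r.part3_pass)}",
            "",
        ]
    return "\n".join(lines)


def _fmt_band(b: float) -> str:
    return str(int(b)) if float(b).is_integer() else str(b)
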