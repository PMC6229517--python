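"""Difference summaries and Bland-Altman method-comparison statistics.

The Bland-Altman analysis plots, for each device/reference pair, the signed
difference (test minus reference) against the pair mean, and summarizes
agreement by the bias (mean difference) and the limits of agreement
bias +/- 1.96 x SD of the differences. The reference value used for each
pair is the same favorably chosen flank the grading uses, so the figure and
the verdict describe the same comparisons.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass
from pathlib import Path
from typing import NamedTuple, Sequence

import numpy as np

from .pairing import ComparisonRecord

__all__ = [
    "DifferenceSummary",
    "BlandAltmanResult",
    "difference_summary",
    "bland_altman",
    "export_bland_altman",
]

#: Conventional 95% limits-of-agreement multiplier.
DEFAULT_LOA_MULTIPLIER = 1.96


class DifferenceSummary(NamedTuple):
    mean_signed: float
    sd_signed: float
    mean_absolute: float
    sd_absolute: float


def difference_summary(records: Sequence[ComparisonRecord]) -> DifferenceSummary:
    """Sample mean and SD (n-1 denominator) of signed and absolute differences.

    Both conventions are reported because published summaries rarely state
    whether "mean difference" was taken before or after dropping the sign.
    """
    if not records:
        raise ValueError("cannot summarize an empty record collection")
    metrics = {r.metric for r in records}
    if len(metrics) != 1:
        raise ValueError(f"records must share one metric, got {sorted(metrics)}")
    if len(records) < 2:
        raise ValueError("need at least 2 records for a sample SD")
    signed = np.array([r.signed_difference for r in records])
    absolute = np.abs(signed)
    return DifferenceSummary(
        mean_signed=float(signed.mean()),
        sd_signed=float(signed.std(ddof=1)),
        mean_absolute=float(absolute.mean()),
        sd_absolute=float(absolute.std(ddof=1)),
    )


@dataclass(frozen=True)
class BlandAltmanResult:
    """Pairs of (pair mean, signed difference) plus bias and agreement limits."""

    metric: str
    pair_means: tuple[float, ...]
    signed_differences: tuple[float, ...]
    bias: float
    sd_difference: float
    loa_low: float
    loa_high: float
    loa_multiplier: float = DEFAULT_LOA_MULTIPLIER

    def __post_init__(self) -> None:
        if len(self.pair_means) != len(self.signed_differences):
            raise ValueError("pair_means and signed_differences must align")
        if not (self.loa_low <= self.bias <= self.loa_high):
            raise ValueError("limits of agreement must bracket the bias")

    @property
    def n_pairs(self) -> int:
        return len(self.pair_means)


def bland_altman(
    records: Sequence[ComparisonRecord],
    test_values: Sequence[float] | None = None,
    reference_values: Sequence[float] | None = None,
    loa_multiplier: float = DEFAULT_LOA_MULTIPLIER,
) -> BlandAltmanResult:
    """Bland-Altman statistics for one metric's comparison records.

    By default the test and reference values stored on the records (the
    chosen flank's reading) are used; explicit value sequences, aligned with
    the records, may override them.
    """
    if not records:
        raise ValueError("cannot analyze an empty record collection")
    metric = records[0].metric
    if any(r.metric != metric for r in records):
        raise ValueError("records must share one metric")
    if test_values is None:
        test_values = [r.test_value for r in records]
    if reference_values is None:
        reference_values = [r.reference_value for r in records]
    if len(test_values) != len(records) or len(reference_values) != len(records):
        raise ValueError(
            f"value sequences must align with the {len(records)} records"
        )
    test = np.asarray(test_values, dtype=float)
    ref = np.asarray(reference_values, dtype=float)
    diffs = test - ref
    means = (test + ref) / 2.0
    bias = float(diffs.mean())
    sd = float(diffs.std(ddof=1)) if len(diffs) > 1 else 0.0
    half_width = loa_multiplier * sd
    return BlandAltmanResult(
        metric=metric,
        pair_means=tuple(float(m) for m in means),
        signed_differences=tuple(float(d) for d in diffs),
        bias=bias,
        sd_difference=sd,
        loa_low=bias - half_width,
        loa_high=bias + half_width,
        loa_multiplier=loa_multiplier,
    )


def export_bland_altman(result: BlandAltmanResult, path: str | Path) -> Path:
    """Write plot data as CSV with a JSON sidecar of bias/SD/limits.

    The CSV holds one (pair_mean, signed_difference) row per comparison;
    the sidecar (same stem, ``.json``) records the summary statistics and
    the flank convention, enough to regenerate a standard agreement plot.
    Returns the sidecar path.
    """
    if result.n_pairs == 0:
        raise ValueError("refusing to export an empty result")
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["pair_mean", "signed_difference"])
        for m, d in zip(result.pair_means, result.signed_differences):
            writer.writerow([m, d])
    sidecar = path.with_suffix(".json")
    sidecar.write_text(
        json.dumps(
            {
                "metric": result.metric,
                "n_pairs": result.n_pairs,
                "bias": result.bias,
                "sd_difference": result.sd_difference,
                "loa_low": result.loa_low,
                "loa_high": result.loa_high,
                "loa_multiplier": result.loa_multiplier,
                "reference_convention": "favorable_flank",
            },
            indent=2,
        )
    )
    return sidecar
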