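"""Seeded generator of synthetic nine-reading validation studies.

No raw readings from real validation studies are bundled; instead this
module emulates them. Each subject gets a latent true trajectory over the
nine reading slots — a baseline draw from the population distribution plus
a random walk, since consecutive readings 30-60 s apart are correlated but
not identical (the walk is what makes the favorable-flank choice
non-trivial). Reference readings observe the trajectory plus reference
noise; test readings add a configurable device bias and device noise.
Values are rounded to integers by default, matching oscillometric displays.

Population defaults describe an obese hypertensive-leaning cohort:
SBP 140.64 (16.38) mm Hg and DBP 77.12 (8.51) mm Hg; the heart-rate
baseline of 72 (8) bpm is a conventional resting value, invented here.
An optional stratified mode draws entry SBP from low/medium/high recruitment
ranges instead of the normal baseline; the quotas are a generic three-way
split, not a specific protocol table.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path
from typing import NamedTuple

import numpy as np
import yaml

from .session_model import LABELS, MeasurementSession, Reading, Subject
from .validation import validate_device

__all__ = [
    "MetricModel",
    "GeneratorConfig",
    "PassProbability",
    "generate_study",
    "pass_probability",
]

_RESAMPLE_LIMIT = 1000

#: Generic entry-SBP recruitment ranges (mm Hg) for the stratified mode.
_ENTRY_SBP_RANGES = ((90.0, 129.0), (130.0, 160.0), (161.0, 180.0))


@dataclass(frozen=True)
class MetricModel:
    """Error model for one metric, all in the metric's units.

    ``mean``/``sd``: population distribution of the subject baseline.
    ``drift_sd``: SD of the per-slot random-walk step of the latent value.
    ``device_bias``: additive shift of every test-device reading.
    ``device_noise_sd``/``reference_noise_sd``: measurement noise SDs.
    """

    mean: float
    sd: float
    drift_sd: float
    device_bias: float = 0.0
    device_noise_sd: float = 0.0
    reference_noise_sd: float = 0.0

    def __post_init__(self) -> None:
        for name in ("sd", "drift_sd", "device_noise_sd", "reference_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


def _default_sbp() -> MetricModel:
    return MetricModel(mean=140.64, sd=16.38, drift_sd=2.0,
                       device_noise_sd=3.0, reference_noise_sd=3.0)


def _default_dbp() -> MetricModel:
    return MetricModel(mean=77.12, sd=8.51, drift_sd=1.5,
                       device_noise_sd=2.5, reference_noise_sd=2.5)


def _default_hr() -> MetricModel:
    return MetricModel(mean=72.0, sd=8.0, drift_sd=1.0,
                       device_noise_sd=1.5, reference_noise_sd=1.5)


@dataclass(frozen=True)
class GeneratorConfig:
    """Full description of a synthetic study.

    Defaults emulate a 33-subject protocol study of a well-behaved device:
    no bias, a few mm Hg of combined measurement noise, mild within-session
    drift, integer display rounding.
    """

    n_subjects: int = 33
    seed: int = 0
    sbp: MetricModel = field(default_factory=_default_sbp)
    dbp: MetricModel = field(default_factory=_default_dbp)
    hr: MetricModel = field(default_factory=_default_hr)
    rounding: str = "integer"  # "integer" | "none"
    stratify_entry_sbp: bool = False

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if self.rounding not in ("integer", "none"):
            raise ValueError("rounding must be 'integer' or 'none'")

    def metric_model(self, metric: str) -> MetricModel:
        return getattr(self, metric)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "GeneratorConfig":
        data = dict(data)
        for m in ("sbp", "dbp", "hr"):
            if m in data and isinstance(data[m], dict):
                data[m] = MetricModel(**data[m])
        return cls(**data)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "GeneratorConfig":
        with Path(path).open(encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    def to_json(self) -> str:
        return json.dumps(self.to_dict())


def _round(values: np.ndarray, mode: str) -> np.ndarray:
    return np.rint(values) if mode == "integer" else values


def _draw_baseline(model: MetricModel, rng: np.random.Generator,
                   stratum: tuple[float, float] | None) -> float:
    if stratum is None:
        return rng.normal(model.mean, model.sd)
    low, high = stratum
    return rng.uniform(low, high)


def _subject_trajectories(
    config: GeneratorConfig,
    rng: np.random.Generator,
    stratum: tuple[float, float] | None,
) -> dict[str, np.ndarray]:
    """Latent per-metric values over the 9 slots: baseline + random walk."""
    n = len(LABELS)
    out = {}
    for metric in ("sbp", "dbp", "hr"):
        model = config.metric_model(metric)
        baseline = _draw_baseline(
            model, rng, stratum if metric == "sbp" else None
        )
        steps = rng.normal(0.0, model.drift_sd, size=n - 1) if model.drift_sd > 0 \
            else np.zeros(n - 1)
        out[metric] = baseline + np.concatenate([[0.0], np.cumsum(steps)])
    return out


def _observe(
    trajectories: dict[str, np.ndarray],
    config: GeneratorConfig,
    rng: np.random.Generator,
) -> dict[str, np.ndarray] | None:
    """Apply role-dependent bias/noise and rounding; None if physiologically invalid."""
    observed = {}
    for metric in ("sbp", "dbp", "hr"):
        model = config.metric_model(metric)
        values = trajectories[metric].copy()
        for i, label in enumerate(LABELS):
            if label in ("BPB", "BP2", "BP4", "BP6"):  # test device slots
                values[i] += model.device_bias
                if model.device_noise_sd > 0:
                    values[i] += rng.normal(0.0, model.device_noise_sd)
            else:
                if model.reference_noise_sd > 0:
                    values[i] += rng.normal(0.0, model.reference_noise_sd)
        observed[metric] = _round(values, config.rounding)
    ok = np.all(observed["sbp"] > observed["dbp"]) and np.all(
        observed["dbp"] > 0
    ) and np.all(observed["hr"] > 0)
    return observed if ok else None


def _generate_subject_covariates(
    sid: str, rng: np.random.Generator
) -> Subject:
    """Plausible obese-cohort covariates (BMI >= 30 enforced)."""
    sex = "male" if rng.random() < 14 / 33 else "female"
    age = float(np.clip(np.rint(rng.normal(60.0, 15.0)), 25, 95))
    height = float(rng.normal(1.675, 0.07))
    height = min(max(height, 1.45), 2.00)
    bmi = 30.0 + rng.gamma(shape=2.0, scale=1.2)  # right-skewed above threshold
    weight = round(bmi * height**2, 1)
    arm = float(np.rint(rng.normal(321.0, 35.0)))
    return Subject(
        subject_id=sid,
        age=age,
        sex=sex,
        weight=weight,
        height=round(height, 2),
        arm_circumference=arm,
    )


def generate_study(config: GeneratorConfig) -> list[MeasurementSession]:
    """Generate one reproducible study of ``n_subjects`` complete sessions.

    A subject whose observed readings violate sbp > dbp > 0 or hr > 0 is
    redrawn in full; pathological configs (e.g. DBP mean above SBP mean with
    tiny SDs) exhaust the resampling limit and raise.
    """
    rng = np.random.default_rng(config.seed)
    sessions = []
    for i in range(config.n_subjects):
        sid = f"S{i + 1:03d}"
        stratum = (
            _ENTRY_SBP_RANGES[i % len(_ENTRY_SBP_RANGES)]
            if config.stratify_entry_sbp
            else None
        )
        subject = _generate_subject_covariates(sid, rng)
        observed = None
        for _ in range(_RESAMPLE_LIMIT):
            trajectories = _subject_trajectories(config, rng, stratum)
            observed = _observe(trajectories, config, rng)
            if observed is not None:
                break
        if observed is None:
            raise RuntimeError(
                f"could not draw a physiologically valid session for {sid} in "
                f"{_RESAMPLE_LIMIT} attempts; check the metric models"
            )
        readings = tuple(
            Reading(
                label=label,
                sbp=float(observed["sbp"][j]),
                dbp=float(observed["dbp"][j]),
                hr=float(observed["hr"][j]),
            )
            for j, label in enumerate(LABELS)
        )
        sessions.append(MeasurementSession(subject=subject, readings=readings))
    return sessions


class PassProbability(NamedTuple):
    estimate: float
    standard_error: float
    n_replicates: int


def pass_probability(
    config: GeneratorConfig,
    n_replicates: int,
    metric: str,
) -> PassProbability:
    """Monte-Carlo part-3 pass probability under the configured error model.

    Each replicate regenerates a full study from an independent child seed
    and runs the complete grading pipeline. The attached standard error is
    the binomial sqrt(p(1-p)/n).
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    children = np.random.SeedSequence(config.seed).spawn(n_replicates)
    n_pass = 0
    import warnings as _warnings

    for child in children:
        child_seed = int(child.generate_state(1)[0] % (2**31))
        study = generate_study(replace(config, seed=child_seed))
        with _warnings.catch_warnings():
            _warnings.simplefilter("ignore")
            report = validate_device(study, metric)
        n_pass += report.part3_pass
    p = n_pass / n_replicates
    se = math.sqrt(p * (1 - p) / n_replicates)
    return PassProbability(estimate=p, standard_error=se, n_replicates=n_replicates)
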