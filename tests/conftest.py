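import pytest

from eshval import GeneratorConfig, MeasurementSession, Reading, Subject, generate_study
from eshval.session_model import LABELS


def make_session(
    subject_id: str = "S001",
    sbp=None,
    dbp=None,
    hr=None,
) -> MeasurementSession:
    """Build a complete session from per-slot value lists (protocol order)."""
    sbp = sbp if sbp is not None else [120.0] * 9
    dbp = dbp if dbp is not None else [80.0] * 9
    hr = hr if hr is not None else [70.0] * 9
    readings = tuple(
        Reading(label=label, sbp=sbp[i], dbp=dbp[i], hr=hr[i])
        for i, label in enumerate(LABELS)
    )
    return MeasurementSession(subject=Subject(subject_id=subject_id), readings=readings)


@pytest.fixture
def default_study():
    """A 33-subject synthetic study from the default well-behaved device."""
    return generate_study(GeneratorConfig(seed=20260918))


@pytest.fixture
def zero_error_config():
    cfg = GeneratorConfig(seed=7)
    import dataclasses

    def quiet(model):
        return dataclasses.replace(
            model, drift_sd=0.0, device_bias=0.0,
            device_noise_sd=0.0, reference_noise_sd=0.0,
        )

    return dataclasses.replace(
        cfg, sbp=quiet(cfg.sbp), dbp=quiet(cfg.dbp), hr=quiet(cfg.hr)
    )
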