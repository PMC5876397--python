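import pytest
from hypothesis import HealthCheck, settings

from placentrans import (
    DoseSpec,
    InsertGeometry,
    SamplingSchedule,
    TranslocationSeries,
)

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def geometry() -> InsertGeometry:
    return InsertGeometry.transwell_12mm()


@pytest.fixture
def fluor_schedule() -> SamplingSchedule:
    return SamplingSchedule.fluorescence_24h()


@pytest.fixture
def dose(geometry) -> DoseSpec:
    return DoseSpec.from_concentration(0.01, geometry, "probe")


def make_series(
    concentrations,
    geometry=None,
    schedule=None,
    dose=None,
    condition="control",
    regime="static",
    replicate_id="r1",
):
    """Convenience constructor for a well-formed series."""
    geometry = geometry or InsertGeometry.transwell_12mm()
    if schedule is None:
        n = len(concentrations)
        times = tuple(float(i) for i in range(n))
        schedule = SamplingSchedule(times, 0.05)
    dose = dose or DoseSpec.from_concentration(0.01, geometry, "probe")
    return TranslocationSeries(
        geometry=geometry,
        schedule=schedule,
        dose=dose,
        concentrations_mg_ml=tuple(concentrations),
        condition=condition,
        regime=regime,
        replicate_id=replicate_id,
    )
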