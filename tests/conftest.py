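import numpy as np
import pytest

from aerosolwatch import (
    AnalysisConfig,
    AggregateSeries,
    EventAnnotation,
    ParticleFrame,
    ProcedureRecord,
    SyntheticConfig,
    generate_study,
)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def constant_frame():
    """90 intervals of constant counts [1,2,3,4,5,6] across the six channels."""
    n = 90
    return ParticleFrame(
        timestamps=np.arange(n) * 7.0,
        counts=np.tile(np.array([1, 2, 3, 4, 5, 6]), (n, 1)),
    )


@pytest.fixture
def flat_series():
    """Constant aggregate series: aerosol 10/interval, droplet 2/interval, 30 min."""
    n = 260
    return AggregateSeries(
        timestamps=np.arange(n) * 7.0,
        aerosol_counts=np.full(n, 10),
        droplet_counts=np.full(n, 2),
    )


@pytest.fixture
def small_study():
    """Reduced synthetic study used by pipeline-level tests."""
    cfg = SyntheticConfig(n_egd=6, n_cytosponge=5, seed=7)
    return generate_study(cfg)


@pytest.fixture
def analysis_config():
    return AnalysisConfig(n_boot=1000)


def make_record(start=600.0, end=1200.0, arm="Cytosponge", annotations=(), **kw):
    return ProcedureRecord(
        procedure_id=kw.pop("procedure_id", "P1"),
        arm=arm,
        procedure_start_s=start,
        procedure_end_s=end,
        annotations=[EventAnnotation(time_s=t, label=lab) for t, lab in annotations],
        **kw,
    )
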