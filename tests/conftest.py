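import numpy as np
import pytest

from prenatal_enamel import (
    EDJInterval,
    PrismSegment,
    ToothRecord,
    load_velia_table1,
)


@pytest.fixture(scope="session")
def table1():
    return load_velia_table1()


@pytest.fixture
def simple_record():
    """Two-segment, four-interval tooth with exact arithmetic values."""
    segments = [
        PrismSegment("A", 1, 100.0, [25.0, 25.0]),
        PrismSegment("A", 2, 150.0, [30.0, 32.0]),
    ]
    intervals = [
        EDJInterval("A", 1, 600.0, 10.0, 0.0, 0.30),
        EDJInterval("A", 2, 500.0, 12.0, 0.30, 0.55),
        EDJInterval("A", 3, 500.0, 15.0, 0.55, 0.80),
        EDJInterval("A", 4, 400.0, 18.0, 0.80, 1.00),
    ]
    return ToothRecord(
        id="A",
        arch="upper",
        nl_present=False,
        segments=segments,
        edj_intervals=intervals,
        edj_total_um=2000.0,
        crown_area_mm2=5.0,
    )


@pytest.fixture
def collinear_points():
    """Noiseless constant-DSR points: count = length / 4."""
    rng = np.random.default_rng(11)
    x = rng.uniform(50.0, 200.0, 60)
    return np.column_stack([x, x / 4.0])
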