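import numpy as np
import pandas as pd
import pytest

from wqrisk import (
    AgeGroupParams,
    MeasurementTable,
    ParameterRegistry,
    RatingCurve,
    default_curves,
    default_exposure,
    default_registry,
)
from wqrisk.wqi import ParameterSpec


@pytest.fixture(scope="session")
def registry():
    return default_registry()


@pytest.fixture(scope="session")
def curves():
    return default_curves()


@pytest.fixture(scope="session")
def exposure():
    return default_exposure()


@pytest.fixture
def linear_curve():
    return RatingCurve("lin", ((0.0, 100.0), (100.0, 0.0)))


@pytest.fixture
def toy_registry():
    """Two-parameter registry with equal weights in both schemes."""
    return ParameterRegistry(
        parameters={
            "a": ParameterSpec("a", nsf_weight=0.5, irwqi_weight=0.5),
            "b": ParameterSpec("b", nsf_weight=0.5, irwqi_weight=0.5),
        }
    )


@pytest.fixture
def toy_table():
    rows = []
    for station in ("1", "2"):
        for period in ("spring", "summer"):
            rows.append({"station": station, "period": period, "parameter": "a",
                         "value": 40.0, "unit": ""})
            rows.append({"station": station, "period": period, "parameter": "b",
                         "value": 60.0, "unit": ""})
    return MeasurementTable(pd.DataFrame(rows))


@pytest.fixture
def children():
    return AgeGroupParams(label="children", ir=1.25, ed=8, ef=345, bw=16.41, rfd=1.6)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
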