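import numpy as np
import pandas as pd
import pytest

from soilrisk.io_model import (
    DistributionSpec,
    ExposureParams,
    SampleTable,
    default_summary_path,
    load_default_config,
    read_summary,
)


@pytest.fixture(scope="session")
def config():
    return load_default_config()


@pytest.fixture(scope="session")
def ref(config):
    return config[0]


@pytest.fixture(scope="session")
def tox(config):
    return config[1]


@pytest.fixture(scope="session")
def expo(config):
    return config[2]


@pytest.fixture(scope="session")
def summary():
    return read_summary(default_summary_path())


@pytest.fixture(scope="session")
def point_expo(expo):
    """Exposure params with every distribution collapsed to its mean."""
    return ExposureParams(params={
        pop: {name: DistributionSpec(family="point", mean=spec.mean_value())
              for name, spec in entries.items()}
        for pop, entries in expo.params.items()
    })


@pytest.fixture
def make_table():
    """Factory for small in-memory sample tables from a column dict."""

    def _make(conc: dict, x=None, y=None, site_id=None):
        n = len(next(iter(conc.values())))
        if site_id is None:
            site_id = [f"S{i+1:02d}" for i in range(n)]
        rng = np.random.default_rng(0)
        if x is None:
            x = rng.uniform(0, 100, n)
        if y is None:
            y = rng.uniform(0, 100, n)
        df = pd.DataFrame({k: np.asarray(v, float) for k, v in conc.items()},
                          index=pd.Index(site_id, name="site_id"))
        return SampleTable(site_id=list(site_id), x=np.asarray(x, float),
                           y=np.asarray(y, float), conc=df)

    return _make
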