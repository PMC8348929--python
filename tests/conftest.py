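import numpy as np
import pytest

from superstat import SyntheticConfig, generate_superstat_series


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def synthetic_60d():
    """Two months of the default superstatistical fixture (seed 0)."""
    cfg = SyntheticConfig(seed=0, duration_days=60)
    series, truth = generate_superstat_series(cfg)
    return cfg, series, truth


@pytest.fixture(scope="session")
def synthetic_120d():
    cfg = SyntheticConfig(seed=2, duration_days=120)
    series, truth = generate_superstat_series(cfg)
    return cfg, series, truth


@pytest.fixture
def csv_factory(tmp_path):
    """Write rows to a CSV and return the path."""

    def write(rows, header="timestamp,value", name="series.csv"):
        path = tmp_path / name
        path.write_text("\n".join([header] + rows) + "\n")
        return path

    return write
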