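import numpy as np
import pandas as pd
import pytest

from camtrap_msom import simulate_community


def make_records(rows):
    """rows: list of (site, kind, species, timestamp-string)."""
    df = pd.DataFrame(rows, columns=["site", "kind", "species", "timestamp"])
    df["timestamp"] = pd.to_datetime(df["timestamp"])
    return df


def make_deployments(sites, start="2017-01-01", days=74):
    start = pd.Timestamp(start)
    return pd.DataFrame({
        "site": list(sites),
        "x": np.arange(len(sites), dtype=float) * 1000.0,
        "y": np.zeros(len(sites)),
        "start": start,
        "end": start + pd.Timedelta(days=days - 1),
    })


@pytest.fixture(scope="session")
def default_survey():
    """One default-scenario community (45 sites, 26 true species)."""
    return simulate_community(seed=7)
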