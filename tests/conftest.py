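import numpy as np
import pandas as pd
import pytest

import aidlog as al
from aidlog.datalog_model import (
    ACOUSTIC_COLUMNS,
    AUDIOGRAM_COLUMNS,
    COLUMNS,
    SPL_COLUMNS,
    _coerce_dtypes,
)


def make_dataset(
    n: int,
    days=30,
    style="BTEa",
    audiogram=40.0,
    spl=None,
    acoustic=(0.30, 0.30, 0.40),
    device_ids=None,
    session_seq=None,
    **columns,
) -> al.Dataset:
    """Construct a small valid Dataset with uniform defaults, overridable
    per column (scalars broadcast; arrays used as-is)."""
    frame = pd.DataFrame(index=range(n))
    frame["device_id"] = device_ids if device_ids is not None else [f"D{i:04d}" for i in range(n)]
    frame["session_seq"] = session_seq if session_seq is not None else np.arange(1, n + 1)
    frame["days_since_last_visit"] = days
    frame["style"] = style
    aud = np.broadcast_to(np.asarray(audiogram, dtype=float), (n, 8)).copy()
    for k, c in enumerate(AUDIOGRAM_COLUMNS):
        frame[c] = aud[:, k]
    spl = np.full(12, 1 / 12) if spl is None else np.asarray(spl, dtype=float)
    spl = np.broadcast_to(spl, (n, 12)).copy()
    for k, c in enumerate(SPL_COLUMNS):
        frame[c] = spl[:, k]
    ac = np.broadcast_to(np.asarray(acoustic, dtype=float), (n, 3)).copy()
    for k, c in enumerate(ACOUSTIC_COLUMNS):
        frame[c] = ac[:, k]
    frame["gain_reduction_noise"] = 1.0
    frame["gain_reduction_quiet"] = 1.0
    frame["fraction_directional"] = 0.5
    frame["mean_input_spl"] = 65.0
    for name, vals in columns.items():
        frame[name] = vals
    return al.Dataset(_coerce_dtypes(frame[list(COLUMNS)]), provenance="constructed")


@pytest.fixture(scope="session")
def sim_small():
    """A small default-condition simulation shared across read-only tests."""
    cfg = al.default_config(n_devices=600, visits_min=1, visits_max=4, seed=101)
    return al.simulate_dataset(cfg)


@pytest.fixture(scope="session")
def sim_multi_visit():
    """Multi-visit simulation for loan/series tests."""
    cfg = al.default_config(n_devices=800, visits_min=2, visits_max=4, seed=202)
    return al.simulate_dataset(cfg)
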