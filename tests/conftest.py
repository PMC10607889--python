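import numpy as np
import pandas as pd
import pytest

from autotiva.patient import RECORD_COLUMNS


def make_record(
    n: int = 1200,
    bis: float = 45.0,
    sqi: float = 99.0,
    tof_count: int = 1,
    sbp: float = 110.0,
    hr: float = 70.0,
) -> pd.DataFrame:
    """Handcrafted flat 1-Hz record covering one surgery of ``n`` seconds."""
    df = pd.DataFrame({c: np.zeros(n) for c in RECORD_COLUMNS})
    df["t_s"] = np.arange(n, dtype=float)
    df["bis"] = bis
    df["sqi"] = sqi
    df["emg"] = 30.0
    df["sbp"] = sbp
    df["hr"] = hr
    df["tof_count"] = tof_count
    df["tof_valid"] = 1
    df["event"] = ""
    df["rationale"] = ""
    df.loc[0, "event"] = "surgery_start"
    return df


@pytest.fixture
def flat_record():
    return make_record()
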