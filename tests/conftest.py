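import numpy as np
import pandas as pd
import pytest

from nascode.synth import SynthConfig, generate_session
from nascode.sequences import build_sequences
from nascode.synth import target_label


@pytest.fixture(scope="session")
def small_session():
    """Planted sequence session, small enough for fast unit tests."""
    cfg = SynthConfig(
        n_units=60, n_trials_per_target=10, peak_jitter_sd_s=0.1,
        incorrect_frac=0.0, seed=11,
    )
    return generate_session(cfg)


@pytest.fixture(scope="session")
def small_seqs(small_session):
    return build_sequences(small_session)


@pytest.fixture(scope="session")
def small_targets(small_session):
    tr = small_session.trials.set_index("trial_id")
    return tr.apply(lambda r: target_label(r.target_row, r.target_col), axis=1)


def make_seqs(arr, trial_ids=None, unit_ids=None) -> pd.DataFrame:
    """Hand-built sequence table: rows = trials, columns = units."""
    arr = np.asarray(arr, dtype=float)
    idx = trial_ids if trial_ids is not None else list(range(arr.shape[0]))
    cols = unit_ids if unit_ids is not None else list(range(arr.shape[1]))
    return pd.DataFrame(arr, index=idx, columns=cols)
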