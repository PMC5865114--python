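import numpy as np
import pandas as pd
import pytest

from gistmem.behavior import SubjectBehavior
from gistmem.simulate import SimulationConfig


def make_trials(rows):
    """Build a trial table from (picture_id, pair_id, type, emotion, response, confidence)."""
    return pd.DataFrame(
        rows,
        columns=["picture_id", "pair_id", "picture_type", "emotion", "response", "confidence"],
    )


def make_pair(pair_id, old_resp, rel_resp, emotion="neutral", old_conf=2, rel_conf=2):
    rows = [
        (f"old_{pair_id}", pair_id, "old", emotion, old_resp,
         old_conf if old_resp == "yes" else None),
        (f"rel_{pair_id}", pair_id, "related", emotion, rel_resp,
         rel_conf if rel_resp == "yes" else None),
    ]
    return rows


@pytest.fixture
def small_config():
    """Light-weight simulation config for fast tests."""
    return SimulationConfig(
        n_per_group=4, n_pairs=10, n_novel=10, n_voxels=30,
        n_scans=160, rng_seed=7,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(123)
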