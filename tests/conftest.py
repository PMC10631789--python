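import itertools

import numpy as np
import pandas as pd
import pytest

from segbias.connectivity import ConnectivityMatrix
from segbias.segregation import Parcellation


@pytest.fixture
def two_net_parcellation():
    """4 nodes in 2 networks: {0,1} -> A, {2,3} -> B."""
    return Parcellation("toy", ["A", "A", "B", "B"])


@pytest.fixture
def worked_example_matrix():
    """Fisher-z weights: 0-1 = 0.6, 2-3 = 0.4, 0-2 = 0.2, others 0."""
    v = np.zeros((4, 4))
    v[0, 1] = v[1, 0] = 0.6
    v[2, 3] = v[3, 2] = 0.4
    v[0, 2] = v[2, 0] = 0.2
    return ConnectivityMatrix(v, state="fisher_z")


def set_partitions(items):
    """All set partitions of a sequence (oracle helper for brute-force tests)."""
    items = list(items)
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for part in set_partitions(rest):
        for i in range(len(part)):
            yield part[:i] + [[first] + part[i]] + part[i + 1:]
        yield [[first]] + part


def trial_frame(rows):
    """Build a trial table from (subject, run_type, cue_kind, cue_value, temp, rating)."""
    return pd.DataFrame(
        rows,
        columns=[
            "subject_id",
            "run_type",
            "cue_kind",
            "cue_value",
            "temperature_c",
            "rating",
        ],
    )
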