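import numpy as np
import pandas as pd
import pytest

from proxgranule import CountMatrix, ROIMeasurement


def make_matrix(bait_rows, control_rows, ids=None) -> CountMatrix:
    """Build a CountMatrix from per-protein bait/control replicate tuples."""
    bait = np.atleast_2d(np.asarray(bait_rows, dtype=float))
    control = np.atleast_2d(np.asarray(control_rows, dtype=float))
    n = bait.shape[0]
    ids = ids or [f"P{i:03d}" for i in range(1, n + 1)]
    samples = [f"bait_{i}" for i in range(1, bait.shape[1] + 1)] + [
        f"control_{i}" for i in range(1, control.shape[1] + 1)
    ]
    counts = pd.DataFrame(np.hstack([bait, control]), index=ids, columns=samples)
    group_of = {s: ("bait" if s.startswith("bait") else "control") for s in samples}
    replicate_of = {s: int(s.rsplit("_", 1)[1]) for s in samples}
    return CountMatrix(counts=counts, group_of=group_of, replicate_of=replicate_of)


@pytest.fixture
def small_matrix() -> CountMatrix:
    return make_matrix(
        bait_rows=[(3, 3, 3), (2, 4, 6), (10, 12, 11), (5, 5, 5)],
        control_rows=[(0, 0, 0), (1, 1, 1), (1, 2, 1), (5, 5, 5)],
        ids=["A", "B", "C", "D"],
    )


@pytest.fixture
def roi_example() -> ROIMeasurement:
    return ROIMeasurement(animal_id="wt_1", rachis=50, edge1=80, edge2=60, background=10)
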