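import numpy as np
import pandas as pd
import pytest

from persistlab.decay import MultiExpModel
from persistlab.lineage import LineageTable

# Published triphasic/biphasic killing-curve parameter sets used as fixtures
# throughout the suite (amplitudes in cells/mL, rates in 1/h).
POST_EXP_PARAMS = ((7.46e6, 1.42e6, 64.1), (9.89, 3.09, 0.508))
POST_EARLY_PARAMS = ((1.46e7, 2.81e5, 17.6), (11.4, 2.27, 0.248))
POST_LATE_PARAMS = ((9.07e6, 4.52e6), (6.14, 0.292))


@pytest.fixture
def post_exp_model():
    a, d = POST_EXP_PARAMS
    return MultiExpModel(amplitudes=a, rates=d)


@pytest.fixture
def post_early_model():
    a, d = POST_EARLY_PARAMS
    return MultiExpModel(amplitudes=a, rates=d)


@pytest.fixture
def post_late_model():
    a, d = POST_LATE_PARAMS
    return MultiExpModel(amplitudes=a, rates=d)


@pytest.fixture
def quarter_hour_times():
    return np.arange(0.0, 6.0 + 1e-9, 0.25)


def _frames(spec):
    """spec: list of (cell_id, [(t, area), ...])"""
    rows = []
    for cid, obs in spec:
        for t, a in obs:
            rows.append((cid, t, a))
    return pd.DataFrame(rows, columns=["cell_id", "t_h", "area_um2"])


@pytest.fixture
def small_table():
    """Hand-built forest observed over [0, 2] h; exposure onset at 2.0 h.

    F1 divides at 1.0 into B and C; B divides at 1.4 into D and E.
    F2 never divides and keeps a constant area (non-growing).
    F3 is lost to tracking at 1.2 h.
    """
    cells = pd.DataFrame(
        [
            ("F1", None, "ch1", 0.0, 1.0, "division", False),
            ("B", "F1", "ch1", 1.0, 1.4, "division", False),
            ("C", "F1", "ch1", 1.0, 2.0, "censored", False),
            ("D", "B", "ch1", 1.4, 2.0, "censored", False),
            ("E", "B", "ch1", 1.4, 2.0, "censored", False),
            ("F2", None, "ch2", 0.0, 2.0, "censored", False),
            ("F3", None, "ch3", 0.0, 1.2, "tracking_lost", False),
        ],
        columns=["cell_id", "parent_id", "chamber_id", "birth_h", "end_h", "fate", "persister"],
    )
    grid = [0.0, 0.5, 1.0, 1.5, 2.0]
    frames = _frames(
        [
            ("F2", [(t, 1.0) for t in grid]),
            ("C", [(1.0, 1.0), (1.5, 1.2), (2.0, 1.5)]),
            ("D", [(1.5, 1.0), (2.0, 1.3)]),
            ("E", [(1.5, 1.0), (2.0, 1.3)]),
            ("F1", [(0.0, 1.0), (0.5, 1.3), (1.0, 1.9)]),
            ("B", [(1.0, 1.0), (1.4, 1.3)]),
        ]
    )
    return LineageTable(cells=cells, frames=frames)


@pytest.fixture
def binary_tree_table():
    """Full binary division tree of depth 3 over [0, 2] h (8 leaves)."""
    rows = [("r", None, "ch", 0.0, 0.5, "division", False)]
    level = ["r"]
    times = {1: (0.5, 1.0), 2: (1.0, 1.5), 3: (1.5, 2.0)}
    for depth in (1, 2, 3):
        birth, end = times[depth]
        nxt = []
        for parent in level:
            for tag in "ab":
                cid = parent + tag
                fate = "division" if depth < 3 else "censored"
                rows.append((cid, parent, "ch", birth, end, fate, False))
                nxt.append(cid)
        level = nxt
    cells = pd.DataFrame(
        rows,
        columns=["cell_id", "parent_id", "chamber_id", "birth_h", "end_h", "fate", "persister"],
    )
    return LineageTable(cells=cells)


def round_sig(x, sig):
    """Round to the given number of significant figures."""
    if x == 0:
        return 0.0
    from math import floor, log10

    return round(x, -int(floor(log10(abs(x)))) + (sig - 1))
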