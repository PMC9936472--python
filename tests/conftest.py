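import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from memoryflow.screen import ScreenMemoryModel
from memoryflow.synthetic import ScreenSimConfig, simulate_screen


def make_transition_counts(rng, n_reps=2, low=5, high=200):
    """Random small strain/wildtype count tables for one window."""
    rows_s, rows_w = [], []
    for rep in range(1, n_reps + 1):
        for tp in ("TPa", "TPb"):
            rows_s.append((tp, rep, int(rng.integers(low, high))))
            rows_w.append((tp, rep, int(rng.integers(low, high))))
    cols = ["timepoint", "replicate", "count"]
    return pd.DataFrame(rows_s, columns=cols), pd.DataFrame(rows_w, columns=cols)


@pytest.fixture(scope="session")
def null_screen_calls():
    """500 null strains (delta = 0) across 25 independent screens.

    Spreading the strains over independent screens lets the shared
    pooled-control noise vary, so the per-window z distribution is the
    marginal null.  The quadrature fit provides the variance check, the
    as-printed fit the combined-Z false-call rate and the empirical
    significance threshold.  Fitted once per session and shared.
    """
    printed, quadrature = [], []
    for rep in range(25):
        cfg = ScreenSimConfig(n_strains=20, seed=20_240 + rep)
        counts, facs, _ = simulate_screen(cfg)
        model = ScreenMemoryModel(counts, facs)
        printed.append(model.fit(se_combine="as_printed").calls)
        quadrature.append(model.fit(se_combine="quadrature").calls)
    return {
        "printed": pd.concat(printed),
        "quadrature": pd.concat(quadrature),
    }
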