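import numpy as np
import pandas as pd
import pytest

import strata_tx as st


@pytest.fixture(scope="session")
def small_cohort():
    """One-stratum cohort with planted effects, shared across read-only tests."""
    config = st.SimConfig(
        n_genes=400,
        strata=(("female", 30, 30),),
        de_fraction_per_stratum=0.05,
        seed=101,
    )
    counts, metadata, truth = st.simulate_cohort(config)
    return config, counts, metadata, truth


@pytest.fixture()
def tiny_counts():
    df = pd.DataFrame(
        [[10, 20], [0, 5], [7, 7]],
        index=["g1", "g2", "g3"],
        columns=["s1", "s2"],
    )
    return st.CountMatrix(df)


@pytest.fixture()
def tiny_metadata():
    df = pd.DataFrame(
        {
            "sex": ["female", "female"],
            "diagnosis": ["CTL", "AD"],
            "Age": [70.0, 80.0],
            "RIN": [7.0, 8.0],
            "PMI": [np.nan, 12.0],
        },
        index=pd.Index(["s1", "s2"], name="sample_id"),
    )
    return st.SampleMetadata(df)


def brute_force_bh(pvalues):
    """Independent step-up BH oracle used by several tests."""
    p = np.asarray(pvalues, dtype=float)
    n = len(p)
    order = np.argsort(p, kind="stable")
    adjusted = np.empty(n)
    running_min = 1.0
    for rank in range(n, 0, -1):
        i = order[rank - 1]
        running_min = min(running_min, p[i] * n / rank)
        adjusted[i] = running_min
    return adjusted


def brute_force_es(values, hit_mask, exponent=1.0, return_extrema=False):
    """Independent running-sum oracle: literal loop over the ranked list.

    With ``return_extrema`` the (maximum, minimum) of the running sum are
    returned as well, so callers can accept either sign when the two
    extrema tie in magnitude to within float rounding.
    """
    values = np.asarray(values, dtype=float)
    hit_mask = np.asarray(hit_mask, dtype=bool)
    n = len(values)
    n_hits = hit_mask.sum()
    weights = np.abs(values) ** exponent
    total = weights[hit_mask].sum()
    running = 0.0
    best = 0.0
    highest = 0.0
    lowest = 0.0
    for i in range(n):
        if hit_mask[i]:
            running += (weights[i] / total) if total > 0 else 1.0 / n_hits
        else:
            running -= 1.0 / (n - n_hits)
        highest = max(highest, running)
        lowest = min(lowest, running)
        if abs(running) > abs(best):
            best = running
    if return_extrema:
        return best, highest, lowest
    return best
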