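import numpy as np
import pandas as pd
import pytest

import safconn as sc


@pytest.fixture(scope="session")
def ribbon5():
    """Default 5-wedges-per-hemisphere ribbon parcellation + true adjacency."""
    return sc.make_ribbon_parcellation(5)


@pytest.fixture(scope="session")
def tract_60_40(ribbon5):
    """60 short U-fibers (L1-L2) + 40 long fibers (L1-L3): known GSCF 0.6."""
    parc, adj = ribbon5
    tract, labels = sc.make_tractogram(
        parc, adj, short_pair_counts={(1, 2): 60}, long_pair_counts={(1, 3): 40}, seed=11
    )
    return tract, labels


@pytest.fixture
def chain4():
    """4-region single-hemisphere chain with the hand-worked W.

    Adjacent pairs 1-2, 2-3, 3-4; symmetric strengths w12=6, w13=2, w14=2.
    """
    ids = [1, 2, 3, 4]
    regions = pd.DataFrame(
        {"id": ids, "name": ["a", "b", "c", "d"], "hemisphere": ["L"] * 4}
    )
    a = np.zeros((4, 4), dtype=int)
    for i, j in [(0, 1), (1, 2), (2, 3)]:
        a[i, j] = a[j, i] = 1
    w = np.zeros((4, 4))
    w[0, 1] = w[1, 0] = 6.0
    w[0, 2] = w[2, 0] = 2.0
    w[0, 3] = w[3, 0] = 2.0
    return (
        pd.DataFrame(w, index=ids, columns=ids),
        pd.DataFrame(a, index=ids, columns=ids),
        regions,
    )


def brute_force_gscf(w: np.ndarray, a: np.ndarray) -> float:
    """Independent double-loop evaluation of the global fraction."""
    num = den = 0.0
    n = len(w)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            den += w[i, j]
            if a[i, j]:
                num += w[i, j]
    return num / den if den > 0 else float("nan")


def brute_force_rscf(w: np.ndarray, a: np.ndarray) -> np.ndarray:
    """Independent row-wise double-loop evaluation of the regional fraction."""
    n = len(w)
    out = np.full(n, np.nan)
    for k in range(n):
        num = den = 0.0
        for j in range(n):
            if j == k:
                continue
            den += w[k, j]
            if a[k, j]:
                num += w[k, j]
        if den > 0:
            out[k] = num / den
    return out


def bh_stepup_oracle(p: np.ndarray) -> np.ndarray:
    """Direct evaluation of the BH step-up formula q_(i) = min_{j>=i} p_(j)*m/j."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q_sorted = np.empty(m)
    running = np.inf
    for rank in range(m, 0, -1):
        running = min(running, p[order[rank - 1]] * m / rank)
        q_sorted[rank - 1] = min(running, 1.0)
    out = np.empty(m)
    out[order] = q_sorted
    return out
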