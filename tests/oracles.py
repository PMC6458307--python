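"""Independent brute-force oracles used by the tests.

These deliberately avoid the library's own implementations (and KD-trees):
plain O(n^2) definitions that can be checked by eye.
"""

import numpy as np


def brute_force_dbscan(points: np.ndarray, eps: float, min_pts: int):
    """Exhaustive density-connectivity DBSCAN semantics.

    Returns (core_labels, core_mask, border_options) where core_labels[i]
    is the cluster of core point i (-1 for non-cores), and border_options
    maps each non-core index to the set of cluster ids it could legally
    join (empty set = necessarily noise).  Border points adjacent to two
    clusters are ambiguous under DBSCAN, so the oracle reports the set.
    """
    n = len(points)
    d = np.linalg.norm(points[:, None, :] - points[None, :, :], axis=-1)
    within = d <= eps
    core = within.sum(axis=1) >= min_pts  # count includes self
    labels = np.full(n, -1, dtype=int)
    cid = 0
    for i in range(n):
        if core[i] and labels[i] == -1:
            stack = [i]
            labels[i] = cid
            while stack:
                j = stack.pop()
                for k in range(n):
                    if core[k] and within[j, k] and labels[k] == -1:
                        labels[k] = cid
                        stack.append(k)
            cid += 1
    border_options = {
        i: {labels[j] for j in range(n) if core[j] and within[i, j]}
        for i in range(n)
        if not core[i]
    }
    return labels, core, border_options


def assert_dbscan_matches_oracle(points, eps, min_pts, got_labels):
    """Check a label vector against the exhaustive oracle (partition-wise)."""
    oracle_labels, core, border_options = brute_force_dbscan(points, eps, min_pts)
    n = len(points)
    mapping: dict[int, int] = {}
    for i in range(n):
        if core[i]:
            assert got_labels[i] != -1, f"core point {i} labelled noise"
            prev = mapping.setdefault(oracle_labels[i], got_labels[i])
            assert prev == got_labels[i], "oracle cluster split by implementation"
    # distinct oracle clusters must stay distinct
    assert len(set(mapping.values())) == len(mapping)
    for i, options in border_options.items():
        if not options:
            assert got_labels[i] == -1, f"noise point {i} was clustered"
        else:
            assert got_labels[i] in {mapping[o] for o in options}, (
                f"border point {i} joined a non-adjacent cluster"
            )
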