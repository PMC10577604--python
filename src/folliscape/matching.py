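"""Greedy ascending-distance one-to-one matching between two point sets.

Used both to score detections against ground truth and to merge positive
centroids across marker planes. Candidate pairs within the radius are
sorted by distance (ties broken by index order, so results are
deterministic) and accepted greedily, each point used at most once.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial.distance import cdist


def greedy_match(a: np.ndarray, b: np.ndarray, radius: float) -> list[tuple[int, int]]:
    """Return [(i, j)] pairs matching a[i] to b[j], each index used once.

    `a` and `b` are (n, 2) coordinate arrays; only pairs closer than
    `radius` are eligible.
    """
    if len(a) == 0 or len(b) == 0:
        return []
    d = cdist(a, b)
    ii, jj = np.nonzero(d <= radius)
    if len(ii) == 0:
        return []
    order = np.lexsort((jj, ii, d[ii, jj]))
    used_a = np.zeros(len(a), dtype=bool)
    used_b = np.zeros(len(b), dtype=bool)
    pairs = []
    for k in order:
        i, j = ii[k], jj[k]
        if not used_a[i] and not used_b[j]:
            used_a[i] = used_b[j] = True
            pairs.append((int(i), int(j)))
    return pairs
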