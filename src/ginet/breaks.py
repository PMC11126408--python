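"""Fisher–Jenks natural-breaks classification.

Exact dynamic-programming optimum of the within-class sum of squared deviations
for 1-D data, as used for importance, centrality and barrier-level grading.
"""
from __future__ import annotations

import numpy as np

MAX_EXACT = 10_000


def jenks_breaks(values, n_classes: int, *, seed: int | None = None) -> np.ndarray:
    """Optimal class break values (upper bounds of the lower ``n_classes - 1`` classes).

    Values are sorted internally.  Above ``MAX_EXACT`` observations a seeded
    subsample of that size is used to locate the breaks; assignment of the full
    data by the returned breaks stays exact.
    """
    v = np.sort(np.asarray(values, dtype=float).ravel())
    if v.size == 0:
        raise ValueError("cannot classify an empty value set")
    if n_classes < 1:
        raise ValueError("n_classes must be >= 1")
    if v.size > MAX_EXACT:
        rng = np.random.default_rng(seed)
        v = np.sort(rng.choice(v, size=MAX_EXACT, replace=False))
    n = v.size
    k = min(n_classes, n)
    if k == 1:
        return np.empty(0)

    csum = np.concatenate([[0.0], np.cumsum(v)])
    csq = np.concatenate([[0.0], np.cumsum(v * v)])

    def ssd(i: np.ndarray, j: int) -> np.ndarray:
        # within-class SSD of v[i:j] (vectorized over start indices i)
        cnt = j - i
        s = csum[j] - csum[i]
        return (csq[j] - csq[i]) - s * s / cnt

    # cost[c, j] = minimal SSD of partitioning v[:j] into c classes
    cost = np.full((k + 1, n + 1), np.inf)
    split = np.zeros((k + 1, n + 1), dtype=int)
    for j in range(1, n + 1):
        cost[1, j] = ssd(np.array([0]), j)[0]
    for c in range(2, k + 1):
        for j in range(c, n + 1):
            starts = np.arange(c - 1, j)
            cand = cost[c - 1, starts] + ssd(starts, j)
            best = int(np.argmin(cand))
            cost[c, j] = cand[best]
            split[c, j] = starts[best]
    # backtrack class boundaries
    bounds = np.empty(k - 1)
    j = n
    for c in range(k, 1, -1):
        s = split[c, j]
        bounds[c - 2] = v[s - 1]  # upper bound of class c-1 (last value before the split)
        j = s
    return bounds


def classify_values(values, n_classes: int, *, seed: int | None = None) -> np.ndarray:
    """Class index (0 = lowest class) for every observation under Jenks breaks."""
    v = np.asarray(values, dtype=float)
    bounds = jenks_breaks(v, n_classes, seed=seed)
    return np.searchsorted(bounds, v, side="left").astype(int)
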