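"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's RANSAC code path: the consensus
search enumerates every candidate subset exhaustively, so it can serve as a
ground truth for small peptide counts.
"""

from __future__ import annotations

import math
from itertools import combinations

import numpy as np


def mad_ref(values) -> float:
    v = np.asarray(values, dtype=float)
    return float(np.median(np.abs(v - np.median(v))))


def origin_slope_ref(x, y) -> float:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    return float((x * y).sum() / (x * x).sum())


def exhaustive_consensus_slope(x, y, frac: float = 0.5) -> tuple[float, np.ndarray]:
    """Best consensus over ALL subsets of size ceil(frac*n).

    Candidate subsets are ranked by (inlier count, r^2 of the subset model on
    its own inliers); the returned slope is the origin-OLS refit on the
    winning inlier set, mirroring the RANSAC contract without any sampling.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    m = max(2, math.ceil(frac * n))
    thr = mad_ref(y)
    best_key = None
    best_mask = None
    for subset in combinations(range(n), m):
        idx = np.array(subset)
        beta = origin_slope_ref(x[idx], y[idx])
        inliers = np.abs(y - beta * x) <= thr
        count = int(inliers.sum())
        if count < 2:
            continue
        yi = y[inliers]
        ss_tot = float(((yi - yi.mean()) ** 2).sum())
        ss_res = float(((yi - beta * x[inliers]) ** 2).sum())
        if ss_tot > 0:
            r2 = 1.0 - ss_res / ss_tot
        else:
            r2 = 1.0 if ss_res == 0 else -math.inf
        key = (count, r2)
        if best_key is None or key > best_key:
            best_key = key
            best_mask = inliers
    if best_mask is None:
        raise RuntimeError("no consensus of at least two inliers exists")
    idx = np.flatnonzero(best_mask)
    return origin_slope_ref(x[idx], y[idx]), best_mask
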