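"""Independent brute-force oracles used by the test suite only."""

from __future__ import annotations

import numpy as np


def brute_force_maximal_segments(x, cutoff: float = 0.0) -> list[tuple[int, int, float]]:
    """All locally maximal scoring segments by exhaustive enumeration.

    A segment (i, j] of prefix sums c is a candidate iff every nonempty
    prefix and suffix of it has positive score (c[i] is the strict minimum
    of c over [i, j] and c[j] the strict maximum); the locally maximal
    segments are the candidates not contained in another candidate.
    Quadratic in length — a check, not an implementation.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    if n == 0:
        return []
    c = np.concatenate(([0.0], np.cumsum(x)))
    idx = np.arange(n + 1)
    rows, cols = idx[:, None], idx[None, :]
    upper = cols > rows
    # E1[i,j] = min c[k] for i < k <= j ; E2[i,j] = max c[k] for i <= k < j
    E1 = np.minimum.accumulate(np.where(upper, c[None, :], np.inf), axis=1)
    E2 = np.maximum.accumulate(
        np.where(upper, c[np.maximum(cols - 1, 0)], -np.inf), axis=1
    )
    valid = upper & (E1 > c[:, None]) & (E2 < c[None, :])
    cand = sorted(map(tuple, np.argwhere(valid)), key=lambda t: (t[0], -t[1]))
    out: list[tuple[int, int, float]] = []
    max_j = -1
    for i, j in cand:  # containment filter: keep segments not inside another
        if j > max_j:
            score = float(c[j] - c[i])
            if score > cutoff:
                out.append((int(i), int(j), score))
            max_j = j
    return sorted(out)
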