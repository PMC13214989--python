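"""End-gap-free alignment kernel.

Dynamic program over (score, -columns, matches) in lexicographic order:
maximize the alignment score (match +1, mismatch -1, gap -2, terminal gaps
free), then minimize the number of counted columns (prefer the ungapped
alignment among co-optimal ones), then maximize matches.  Terminal gap runs
are free and uncounted; internal gap columns cost -2 and are counted.  The
``N`` code (4) never matches.  This tie order makes the identity of a
substitution-only variant exactly (L-k)/L.

The kernel is compiled with numba; classification of thousands of ASVs
against a 106-record library makes a pure-Python DP impractical.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["semi_global_align"]


@njit(cache=True)
def _kernel(a: np.ndarray, b: np.ndarray):  # pragma: no cover - exercised via wrapper
    la = a.shape[0]
    lb = b.shape[0]
    # DP rows for (score, matches, cols); leading gaps are free: row/col 0 = 0.
    ps = np.zeros(lb + 1, dtype=np.int32)
    pm = np.zeros(lb + 1, dtype=np.int32)
    pc = np.zeros(lb + 1, dtype=np.int32)
    cs = np.zeros(lb + 1, dtype=np.int32)
    cm = np.zeros(lb + 1, dtype=np.int32)
    cc = np.zeros(lb + 1, dtype=np.int32)

    best_s = np.int32(0)
    best_m = np.int32(0)
    best_c = np.int32(0)
    # candidates: cells in the last column (j == lb) and last row (i == la);
    # initialise with the empty-core alignment (all terminal gaps).
    have_best = False

    for i in range(1, la + 1):
        cs[0] = 0
        cm[0] = 0
        cc[0] = 0
        ai = a[i - 1]
        for j in range(1, lb + 1):
            eq = 1 if (ai == b[j - 1] and ai < 4) else 0
            # diagonal
            s = ps[j - 1] + (1 if eq == 1 else -1)
            m = pm[j - 1] + eq
            c = pc[j - 1] + 1
            # up: gap in b (consume a)
            s2 = ps[j] - 2
            if s2 > s or (s2 == s and (pc[j] + 1 < c or (pc[j] + 1 == c and pm[j] > m))):
                s = s2
                m = pm[j]
                c = pc[j] + 1
            # left: gap in a (consume b)
            s3 = cs[j - 1] - 2
            if s3 > s or (s3 == s and (cc[j - 1] + 1 < c or (cc[j - 1] + 1 == c and cm[j - 1] > m))):
                s = s3
                m = cm[j - 1]
                c = cc[j - 1] + 1
            cs[j] = s
            cm[j] = m
            cc[j] = c
        # last column cell (i, lb): trailing gaps in b are free
        if (not have_best) or cs[lb] > best_s or (
            cs[lb] == best_s and (cc[lb] < best_c or (cc[lb] == best_c and cm[lb] > best_m))
        ):
            best_s = cs[lb]
            best_m = cm[lb]
            best_c = cc[lb]
            have_best = True
        ps, cs = cs, ps
        pm, cm = cm, pm
        pc, cc = cc, pc
    # last row: trailing gaps in a are free (ps holds row la after the swap)
    for j in range(0, lb + 1):
        if ps[j] > best_s or (
            ps[j] == best_s and (pc[j] < best_c or (pc[j] == best_c and pm[j] > best_m))
        ):
            best_s = ps[j]
            best_m = pm[j]
            best_c = pc[j]
    if best_s < 0:
        # the empty-core alignment (score 0) dominates
        return np.int32(0), np.int32(0), np.int32(0)
    return best_s, best_m, best_c


def semi_global_align(a: np.ndarray, b: np.ndarray) -> tuple[int, int, int]:
    """Return (score, matches, aligned_columns) of the optimal alignment."""
    if a.size == 0 or b.size == 0:
        raise ValueError("cannot align an empty sequence")
    s, m, c = _kernel(a.astype(np.uint8), b.astype(np.uint8))
    return int(s), int(m), int(c)
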