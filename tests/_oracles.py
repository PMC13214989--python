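"""Independent oracles used by the test suite.

Everything here is deliberately written from scratch against the stated
contracts (simple, slow, obviously-correct code paths) and never imports the
implementation internals it is used to check.
"""

from __future__ import annotations

import itertools

MATCH, MISMATCH, GAP = 1, -1, -2


def align_oracle_dp(a: str, b: str) -> tuple[int, int, int]:
    """Pure-Python tuple DP for the end-gap-free alignment contract.

    Maximize (score, -columns, matches) lexicographically; leading gaps free
    via zero initialisation of the first row/column, trailing gaps free via a
    final maximum over the last row and column.  Returns
    (score, matches, columns).
    """
    la, lb = len(a), len(b)
    # cell value: (score, -cols, matches)
    prev = [(0, 0, 0) for _ in range(lb + 1)]
    rows = [prev]
    for i in range(1, la + 1):
        cur = [(0, 0, 0)] + [None] * lb
        for j in range(1, lb + 1):
            eq = a[i - 1] == b[j - 1] and a[i - 1] != "N"
            s, negc, m = prev[j - 1]
            diag = (s + (MATCH if eq else MISMATCH), negc - 1, m + (1 if eq else 0))
            s, negc, m = prev[j]
            up = (s + GAP, negc - 1, m)
            s, negc, m = cur[j - 1]
            left = (s + GAP, negc - 1, m)
            cur[j] = max(diag, up, left)
        rows.append(cur)
        prev = cur
    candidates = [rows[i][lb] for i in range(la + 1)] + rows[la]
    s, negc, m = max(candidates)
    return s, m, -negc


def identity_oracle(a: str, b: str) -> float:
    s, m, c = align_oracle_dp(a, b)
    return 100.0 * m / c if c else 0.0


def align_oracle_enumerate(a: str, b: str) -> tuple[int, int, int]:
    """Brute-force enumeration of every end-gap-free alignment (tiny inputs).

    An alignment is a monotone lattice path whose leading run lies along one
    edge (free, uncounted) and whose trailing run lies along the last row or
    column (free, uncounted); interior gap moves cost -2 and count as
    columns.  Ties resolved as (score, -columns, matches).
    """
    la, lb = len(a), len(b)

    best = (0, 0, 0)  # empty-core alignment

    def walk(i, j, score, matches, cols):
        nonlocal best
        if i == la or j == lb:
            # remaining moves are a trailing run along one edge: free
            best = max(best, (score, -cols, matches))
            return
        eq = a[i] == b[j] and a[i] != "N"
        walk(i + 1, j + 1, score + (MATCH if eq else MISMATCH),
             matches + (1 if eq else 0), cols + 1)
        walk(i + 1, j, score + GAP, matches, cols + 1)
        walk(i, j + 1, score + GAP, matches, cols + 1)

    for i0 in range(la + 1):
        walk(i0, 0, 0, 0, 0)
    for j0 in range(1, lb + 1):
        walk(0, j0, 0, 0, 0)
    s, negc, m = best
    return s, m, -negc


# ---------------------------------------------------------------------------
# Mann-Whitney exact p by full enumeration


def mwu_exact_p_enumeration(x: list[float], y: list[float]) -> float:
    """Two-sided exact Mann-Whitney p via enumeration of all C(n1+n2, n1)
    group assignments of the pooled values (no ties assumed)."""
    pooled = sorted(x + y)
    n1 = len(x)
    n = len(pooled)

    def u_of(idx: tuple[int, ...]) -> int:
        xs = [pooled[i] for i in idx]
        ys = [pooled[i] for i in range(n) if i not in set(idx)]
        return sum(1 for xi in xs for yi in ys if xi > yi)

    u_obs = sum(1 for xi in x for yi in y if xi > yi)
    us = [u_of(idx) for idx in itertools.combinations(range(n), n1)]
    total = len(us)
    lo = sum(1 for u in us if u <= u_obs) / total
    hi = sum(1 for u in us if u >= u_obs) / total
    return min(1.0, 2.0 * min(lo, hi))


# ---------------------------------------------------------------------------
# Benjamini-Hochberg step-up by hand


def bh_oracle(pvals: list[float]) -> list[float]:
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    q = [0.0] * m
    prev = 1.0
    for rank_from_end, i in enumerate(reversed(order)):
        rank = m - rank_from_end
        val = min(prev, pvals[i] * m / rank)
        q[i] = val
        prev = val
    return q


# ---------------------------------------------------------------------------
# PERMANOVA pseudo-F from first principles


def pseudo_f_oracle(d: "list[list[float]]", groups: list) -> float:
    """Pseudo-F computed literally from the sum-of-squares partition
    SS = (1/n) * sum of squared distances within a set."""
    n = len(groups)
    ss_t = sum(d[i][j] ** 2 for i in range(n) for j in range(i + 1, n)) / n
    ss_w = 0.0
    for g in set(groups):
        idx = [i for i in range(n) if groups[i] == g]
        ss_w += sum(
            d[i][j] ** 2 for ii, i in enumerate(idx) for j in idx[ii + 1:]
        ) / len(idx)
    a = len(set(groups))
    return ((ss_t - ss_w) / (a - 1)) / (ss_w / (n - a))
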