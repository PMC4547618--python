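"""Independent oracles used by the test suite.

Deliberately simple and separate from the library's implementations:
exhaustive alignment enumeration, brute-force rank correlation, and the
closed-form binomial sign test.
"""
from __future__ import annotations

import math


def enumerate_identity(a: str, b: str, match: int = 1, mismatch: int = -1,
                       gap: int = -1) -> float:
    """Maximum identity over all optimal-score global alignments.

    Exhaustive: propagates the full set of achievable
    (score, matches, columns) triples cell by cell, then reports
    max(matches/columns) among triples with the optimal score.  Feasible for
    short sequences only.
    """
    a = a.upper().replace("U", "T")
    b = b.upper().replace("U", "T")
    n, m = len(a), len(b)
    cells = [[set() for _ in range(m + 1)] for _ in range(n + 1)]
    cells[0][0].add((0, 0, 0))
    for i in range(n + 1):
        for j in range(m + 1):
            for score, matches, cols in cells[i][j]:
                if i < n and j < m:
                    is_match = a[i] == b[j] and a[i] != "N"
                    sub = match if is_match else mismatch
                    cells[i + 1][j + 1].add(
                        (score + sub, matches + int(is_match), cols + 1))
                if i < n:
                    cells[i + 1][j].add((score + gap, matches, cols + 1))
                if j < m:
                    cells[i][j + 1].add((score + gap, matches, cols + 1))
    finals = cells[n][m]
    best_score = max(s for s, _, _ in finals)
    return max((mt / c if c else 0.0)
               for s, mt, c in finals if s == best_score)


def brute_spearman(x, y) -> float:
    """Spearman via O(n^2) mid-ranks and raw-moment Pearson sums."""
    def ranks(v):
        out = []
        for vi in v:
            less = sum(1 for vj in v if vj < vi)
            equal = sum(1 for vj in v if vj == vi)
            out.append(less + (equal + 1) / 2.0)
        return out

    rx, ry = ranks(list(x)), ranks(list(y))
    n = len(rx)
    sx, sy = sum(rx), sum(ry)
    sxx = sum(v * v for v in rx)
    syy = sum(v * v for v in ry)
    sxy = sum(u * v for u, v in zip(rx, ry))
    num = n * sxy - sx * sy
    den = math.sqrt((n * sxx - sx * sx) * (n * syy - sy * sy))
    return num / den


def sign_test_closed_form(n_positive: int, n: int) -> float:
    """Two-sided exact sign test, 2*min(tails) capped at 1, via math.comb."""
    lower = sum(math.comb(n, i) for i in range(0, n_positive + 1))
    upper = sum(math.comb(n, i) for i in range(n_positive, n + 1))
    p = 2.0 * min(lower, upper) / 2 ** n
    return min(p, 1.0)
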