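"""Independent brute-force oracles used only by the tests.

These deliberately avoid the implementation paths they check: the sliding
window oracle is a direct python loop, and the alignment oracle is a
hand-written three-state affine dynamic program with full co-optimal
traceback enumeration.
"""

from __future__ import annotations

import math

import numpy as np
from Bio.Align import substitution_matrices

NEG = -math.inf


def brute_window_means(raw, size, min_valid_fraction=0.5):
    """Skip-missing centered boxcar means via an explicit loop (truncate edges)."""
    raw = np.asarray(raw, dtype=float)
    h = (size - 1) // 2
    out = np.full(len(raw), np.nan)
    for i in range(len(raw)):
        lo, hi = max(0, i - h), min(len(raw), i + h + 1)
        window = raw[lo:hi]
        valid = window[np.isfinite(window)]
        if len(valid) and len(valid) >= min_valid_fraction * (hi - lo):
            out[i] = valid.mean()
    return out


class AffineOracle:
    """Global affine-gap alignment: optimal score and all co-optimal identities.

    Gap of length L costs ``open + (L-1) * extend``; gaps in opposite
    sequences may abut (each opening paid separately).
    """

    def __init__(self, matrix="BLOSUM62", gap_open=12.0, gap_extend=2.0):
        self.sub = substitution_matrices.load(matrix)
        self.go = gap_open
        self.ge = gap_extend

    def _tables(self, a, b):
        n, m = len(a), len(b)
        M = np.full((n + 1, m + 1), NEG)
        X = np.full((n + 1, m + 1), NEG)  # consuming a (gap in b)
        Y = np.full((n + 1, m + 1), NEG)  # consuming b (gap in a)
        M[0, 0] = 0.0
        for i in range(1, n + 1):
            X[i, 0] = -(self.go + (i - 1) * self.ge)
        for j in range(1, m + 1):
            Y[0, j] = -(self.go + (j - 1) * self.ge)
        for i in range(n + 1):
            for j in range(m + 1):
                if i > 0 and j > 0:
                    s = self.sub[a[i - 1], b[j - 1]]
                    M[i, j] = max(M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1]) + s
                if i > 0 and (i, j) != (i, 0):
                    X[i, j] = max(
                        M[i - 1, j] - self.go, X[i - 1, j] - self.ge, Y[i - 1, j] - self.go
                    )
                if j > 0 and (i, j) != (0, j):
                    Y[i, j] = max(
                        M[i, j - 1] - self.go, Y[i, j - 1] - self.ge, X[i, j - 1] - self.go
                    )
        return M, X, Y

    def score(self, a, b):
        M, X, Y = self._tables(a, b)
        return max(M[len(a), len(b)], X[len(a), len(b)], Y[len(a), len(b)])

    def optimal_identities(self, a, b, cap=20000):
        """Set of identity percentages over all co-optimal alignments."""
        M, X, Y = self._tables(a, b)
        n, m = len(a), len(b)
        best = max(M[n, m], X[n, m], Y[n, m])
        tables = {"M": M, "X": X, "Y": Y}
        idents: set[float] = set()
        count = [0]

        def walk(state, i, j, matches, cols):
            if count[0] > cap:
                return
            if i == 0 and j == 0:
                if state == "M" and M[0, 0] == 0:
                    count[0] += 1
                    idents.add(round(100.0 * matches / cols, 9))
                return
            if state == "M":
                s = self.sub[a[i - 1], b[j - 1]]
                hit = int(a[i - 1] == b[j - 1])
                for prev in ("M", "X", "Y"):
                    if tables[prev][i - 1, j - 1] + s == M[i, j]:
                        walk(prev, i - 1, j - 1, matches + hit, cols + 1)
            elif state == "X":
                if X[i - 1, j] - self.ge == X[i, j]:
                    walk("X", i - 1, j, matches, cols + 1)
                if M[i - 1, j] - self.go == X[i, j]:
                    walk("M", i - 1, j, matches, cols + 1)
                if Y[i - 1, j] - self.go == X[i, j]:
                    walk("Y", i - 1, j, matches, cols + 1)
            else:
                if Y[i, j - 1] - self.ge == Y[i, j]:
                    walk("Y", i, j - 1, matches, cols + 1)
                if M[i, j - 1] - self.go == Y[i, j]:
                    walk("M", i, j - 1, matches, cols + 1)
                if X[i, j - 1] - self.go == Y[i, j]:
                    walk("X", i, j - 1, matches, cols + 1)

        for state in ("M", "X", "Y"):
            if tables[state][n, m] == best:
                walk(state, n, m, 0, 0)
        return best, idents
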