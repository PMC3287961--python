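"""Exhaustive-enumeration alignment oracle for short sequences.

Enumerates every monotone alignment path (no dynamic programming), scoring
affine gaps as open + k*extend for a run of length k, so it is independent
of the production aligner.  Local scores are the maximum of the global
oracle over all substring pairs (and the empty alignment).  Practical for
sequences up to length ~7.
"""

from __future__ import annotations

import math


class ExhaustiveAligner:
    def __init__(self, matrix: dict, gap_open: float, gap_extend: float):
        self.matrix = matrix
        self.gap_open = gap_open
        self.gap_extend = gap_extend
        self._cache: dict[tuple[str, str], float] = {}

    def global_score(self, a: str, b: str) -> float:
        key = (a, b)
        if key in self._cache:
            return self._cache[key]
        best = -math.inf
        open_cost = self.gap_open + self.gap_extend

        def rec(i: int, j: int, prev: str, acc: float) -> None:
            nonlocal best
            if i == len(a) and j == len(b):
                best = max(best, acc)
                return
            if i < len(a) and j < len(b):
                rec(i + 1, j + 1, "M", acc + self.matrix[a[i], b[j]])
            if i < len(a):
                rec(i + 1, j, "D",
                    acc - (self.gap_extend if prev == "D" else open_cost))
            if j < len(b):
                rec(i, j + 1, "I",
                    acc - (self.gap_extend if prev == "I" else open_cost))

        rec(0, 0, "", 0.0)
        self._cache[key] = best
        return best

    def local_score(self, a: str, b: str) -> float:
        best = 0.0
        for i in range(len(a)):
            for k in range(i + 1, len(a) + 1):
                for j in range(len(b)):
                    for m in range(j + 1, len(b) + 1):
                        best = max(best, self.global_score(a[i:k], b[j:m]))
        return best
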