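"""Independent brute-force oracles used by the tests.

Deliberately naive: exhaustive enumeration and nested loops, kept free of
any code path from the package under test.
"""

from fractions import Fraction
from itertools import combinations


def upper_tail_by_enumeration(k: int, K: int, n: int, N: int) -> Fraction:
    """P(overlap >= k) by enumerating all C(N, n) draws from a universe of N
    items of which the first K are marked. Exact rational arithmetic."""
    marked = set(range(K))
    total = 0
    at_least_k = 0
    for draw in combinations(range(N), n):
        total += 1
        if sum(1 for x in draw if x in marked) >= k:
            at_least_k += 1
    return Fraction(at_least_k, total)


def overlap_histogram(K: int, n: int, N: int) -> dict[int, int]:
    """Counts of draws by overlap size — one enumeration serves every k."""
    marked = set(range(K))
    hist: dict[int, int] = {}
    for draw in combinations(range(N), n):
        ov = sum(1 for x in draw if x in marked)
        hist[ov] = hist.get(ov, 0) + 1
    return hist
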