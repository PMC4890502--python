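"""Independent reference computations used only by the tests.

Everything here is exact rational arithmetic (fractions + math.comb) or
plain brute force, deliberately sharing no code path with the package.
"""

from __future__ import annotations

from fractions import Fraction
from math import comb


def hypergeom_tail_exact(k: int, K: int, n: int, N: int) -> Fraction:
    """P(X >= k), X ~ Hypergeometric(N, K, n), by direct rational summation."""
    total = comb(N, n)
    upper = min(K, n)
    acc = 0
    for x in range(k, upper + 1):
        acc += comb(K, x) * comb(N - K, n - x)
    return Fraction(acc, total)


def bh_adjust_exact(p_values: list[Fraction]) -> list[Fraction]:
    """Step-up BH with exact rationals, returned in input order."""
    m = len(p_values)
    order = sorted(range(m), key=lambda i: p_values[i])
    adjusted = [Fraction(0)] * m
    running_min = Fraction(1)
    for pos in range(m - 1, -1, -1):
        i = order[pos]
        candidate = p_values[i] * m / (pos + 1)
        running_min = min(running_min, candidate)
        adjusted[i] = min(running_min, Fraction(1))
    return adjusted


def hub_call_exact(degrees: dict[int, int]) -> set[int]:
    """Brute-force hub call: degree > mean + 2 * sample SD, exact arithmetic.

    The comparison d > mean + 2*sd is evaluated without floats:
    d > mean and (d - mean)^2 > 4 * variance.
    """
    values = list(degrees.values())
    n = len(values)
    mean = Fraction(sum(values), n)
    variance = sum((Fraction(v) - mean) ** 2 for v in values) / (n - 1)
    hubs = set()
    for node, d in degrees.items():
        diff = Fraction(d) - mean
        if diff > 0 and diff * diff > 4 * variance:
            hubs.add(node)
    return hubs
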