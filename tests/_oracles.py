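"""Independent brute-force oracles used by the test suite."""

from __future__ import annotations

from math import comb


def fisher_two_sided(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p by exhaustive hypergeometric enumeration.

    Sums, over all tables with the observed margins, the probabilities of
    outcomes no more likely than the observed one.  Weights are exact
    integers; the tie comparison uses the conventional relative gate
    (1 + 1e-7), applied in integer arithmetic so no floating-point error
    enters the enumeration itself.
    """
    n = a + b + c + d
    r = a + b  # row-1 margin
    col = a + c  # column-1 margin
    lo, hi = max(0, r + col - n), min(r, col)
    weights = {k: comb(col, k) * comb(n - col, r - k) for k in range(lo, hi + 1)}
    w_obs = weights[a]
    gate = w_obs * (10**7 + 1)
    total = comb(n, r)
    kept = sum(w for w in weights.values() if w * 10**7 <= gate)
    return kept / total


def all_tables(max_total: int):
    """Yield every 2x2 table (a, b, c, d) with a+b+c+d <= max_total."""
    for n in range(max_total + 1):
        for a in range(n + 1):
            for b in range(n - a + 1):
                for c in range(n - a - b + 1):
                    yield a, b, c, n - a - b - c
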