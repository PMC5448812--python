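"""Independent brute-force oracles shared across test modules."""

import math
from fractions import Fraction


def fisher_enumeration_oracle(a, b, c, d):
    """Exact two-tailed Fisher p by brute-force enumeration in rationals.

    Independent of the implementation under test: hypergeometric
    probabilities are computed with integer combinatorics, and every
    margin-preserving table whose probability does not exceed the observed
    one contributes to the two-tailed sum.
    """
    r1, c1, n = a + b, a + c, a + b + c + d
    denom = math.comb(n, c1)
    pmf = lambda k: Fraction(math.comb(r1, k) * math.comb(n - r1, c1 - k), denom)
    p_obs = pmf(a)
    lo, hi = max(0, c1 - (n - r1)), min(r1, c1)
    return float(sum(pmf(k) for k in range(lo, hi + 1) if pmf(k) <= p_obs))


def fisher_oracle_by_margins(r1, r2, c1):
    """Two-tailed p for every table with margins (r1, r2) x (c1, n-c1).

    Returns {a: p} for each feasible count a in the top-left cell. Exact
    rational arithmetic throughout; used for exhaustive sweeps where calling
    the single-table oracle per table would repeat the same enumeration.
    """
    n = r1 + r2
    denom = math.comb(n, c1)
    lo, hi = max(0, c1 - r2), min(r1, c1)
    pmf = {
        k: Fraction(math.comb(r1, k) * math.comb(r2, c1 - k), denom)
        for k in range(lo, hi + 1)
    }
    out = {}
    for a, p_obs in pmf.items():
        out[a] = float(sum(p for p in pmf.values() if p <= p_obs))
    return out
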