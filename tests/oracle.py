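"""Independent brute-force oracle for two-sided Fisher exact p-values.

Enumerates every 2x2 table with the observed margins, computes each table's
hypergeometric probability from log-factorials only (math.lgamma), and sums
the probabilities not exceeding the observed table's.  Shares no code path
with scipy.stats.fisher_exact.  The 1 + 1e-7 relative guard on the
comparison absorbs floating-point ties between equal-probability tables.
"""

from __future__ import annotations

import math


def _log_binom(n: int, k: int) -> float:
    return math.lgamma(n + 1) - math.lgamma(k + 1) - math.lgamma(n - k + 1)


def _log_hypergeom(a: int, r1: int, r2: int, c1: int) -> float:
    """log P(top-left cell = a) for fixed margins r1 (row 1), r2 (row 2),
    c1 (column 1)."""
    n = r1 + r2
    return _log_binom(r1, a) + _log_binom(r2, c1 - a) - _log_binom(n, c1)


def fisher_two_sided(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p-value of the table [[a, b], [c, d]] by full
    enumeration over the support of the top-left cell."""
    r1, r2, c1 = a + b, c + d, a + c
    lo = max(0, c1 - r2)
    hi = min(r1, c1)
    log_p_obs = _log_hypergeom(a, r1, r2, c1)
    threshold = log_p_obs + math.log1p(1e-7)
    total = 0.0
    for x in range(lo, hi + 1):
        lp = _log_hypergeom(x, r1, r2, c1)
        if lp <= threshold:
            total += math.exp(lp)
    return min(total, 1.0)
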