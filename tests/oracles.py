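"""Independent brute-force oracles used by the test suite.

These deliberately avoid the code paths they check: the binomial tail is a
direct log-space summation of probability masses, not a call into the
package or into scipy's survival function.
"""

from math import exp, lgamma, log


def binom_tail_oracle(k1: int, m: int, p0: float) -> float:
    """P(X >= k1) for X ~ Binomial(m, p0), by direct summation."""
    if k1 <= 0:
        return 1.0
    if k1 > m:
        return 0.0
    total = 0.0
    for x in range(k1, m + 1):
        logp = (
            lgamma(m + 1)
            - lgamma(x + 1)
            - lgamma(m - x + 1)
            + x * log(p0)
            + (m - x) * log(1.0 - p0)
        )
        total += exp(logp)
    return min(total, 1.0)


def rate_ratio_oracle(k1: int, n1: float, k2: int, n2: float) -> float:
    """Exact conditional test oracle: binomial tail at p0 = n1/(n1+n2)."""
    return binom_tail_oracle(k1, k1 + k2, n1 / (n1 + n2))
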