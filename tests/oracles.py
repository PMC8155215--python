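"""Independent numerical oracles used by the tests.

Kept separate from the package so they never share code with the paths they
check.
"""

import math

from scipy import integrate, special, stats


def exact_prob_beta_greater(a1: int, b1: int, a2: int, b2: int) -> float:
    """Exact P(X > Y), X ~ Beta(a1, b1), Y ~ Beta(a2, b2), integer parameters.

    Uses the finite-sum identity: with m = a2 + b2 - 1, F_Y(x) is the upper
    binomial tail sum_{j>=a2} C(m, j) x^j (1-x)^(m-j), so
    P(X > Y) = sum_j C(m, j) * B(a1 + j, b1 + m - j) / B(a1, b1).
    """
    m = a2 + b2 - 1
    return sum(
        math.comb(m, j) * math.exp(special.betaln(a1 + j, b1 + m - j) - special.betaln(a1, b1))
        for j in range(a2, m + 1)
    )


def quad_prob_beta_greater(a1: float, b1: float, a2: float, b2: float) -> float:
    """Same probability by numeric integration of f_X(x) * F_Y(x)."""
    val, _ = integrate.quad(
        lambda x: stats.beta.pdf(x, a1, b1) * stats.beta.cdf(x, a2, b2), 0.0, 1.0
    )
    return val


def exact_test_size(n: int, alpha: float = 0.05) -> float:
    """Exact size of the corrected one-sample proportion test under a fair coin."""
    crit = stats.chi2.isf(alpha, 1)
    size = 0.0
    for k in range(n + 1):
        dev = abs(k - n / 2)
        chi2 = (dev - min(0.5, dev)) ** 2 / (n * 0.25)
        if chi2 > crit:
            size += stats.binom.pmf(k, n, 0.5)
    return float(size)
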