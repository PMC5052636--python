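"""Independent brute-force oracles used to validate the fast code paths.

These deliberately avoid the library's vectorised log-space machinery:
likelihoods are accumulated in probability space with ``math.fsum`` and
plain Python loops, so agreement with the package is evidence about the
package, not a tautology.
"""

import math

import numpy as np
from scipy.stats import binom


def bulk_likelihood_finite(k: int, n: int, f: float, n_individuals: int, epsilon: float) -> float:
    """P(k of n reads carry P1 | expected chromosome frequency f), summing
    over the Binomial(2N, f) number of P1 chromosomes in the bulk."""
    two_n = 2 * n_individuals
    j = np.arange(two_n + 1)
    weights = binom.pmf(j, two_n, f)
    p_read = j / two_n * (1 - epsilon) + (1 - j / two_n) * epsilon
    return math.fsum(weights * binom.pmf(k, n, p_read))


def posterior_bruteforce(k_m: int, n_m: int, k_w: int, n_w: int, params) -> float:
    """Finite-bulk linkage posterior by direct enumeration over the r grid."""
    liks = [
        bulk_likelihood_finite(k_m, n_m, 1.0 - r, params.n_mutant, params.epsilon)
        * bulk_likelihood_finite(k_w, n_w, (1.0 + r) / 3.0, params.n_wt, params.epsilon)
        for r in params.r_grid
    ]
    lbar = math.fsum(liks) / len(liks)
    lnull = bulk_likelihood_finite(
        k_m, n_m, 0.5, params.n_mutant, params.epsilon
    ) * bulk_likelihood_finite(k_w, n_w, 0.5, params.n_wt, params.epsilon)
    num = params.pi * lbar
    den = num + (1.0 - params.pi) * lnull
    return num / den if den > 0 else params.pi


def window_medians_sorted(values, window_size, step):
    """Sliding-window medians via explicit sorting (order-statistics oracle)."""
    out = []
    s = len(values)
    start = 0
    while start + window_size <= s:
        w = sorted(values[start : start + window_size])
        mid = window_size // 2
        if window_size % 2:
            out.append(w[mid])
        else:
            out.append((w[mid - 1] + w[mid]) / 2.0)
        start += step
    return out


def random_model_config(rng, max_depth=50, epsilon=0.01):
    """Draw one SNP-count configuration from the generative model: linked
    with probability 1/2 (r uniform) else unlinked, depths <= max_depth."""
    r = rng.uniform(0, 0.5) if rng.random() < 0.5 else 0.5
    n_m, n_w = (int(x) for x in rng.integers(1, max_depth + 1, 2))
    p_m = (1 - r) * (1 - epsilon) + r * epsilon
    f_w = (1 + r) / 3
    p_w = f_w * (1 - epsilon) + (1 - f_w) * epsilon
    return int(rng.binomial(n_m, p_m)), n_m, int(rng.binomial(n_w, p_w)), n_w
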