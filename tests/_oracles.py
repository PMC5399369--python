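"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's own code paths: exact rational
arithmetic for the Hardy-Weinberg conditional test, naive per-element
loops for network quantities, and the hat-matrix identity for
leave-one-out predictions.
"""

from fractions import Fraction
from math import factorial

import numpy as np


def hwe_exact_oracle(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Exact HWE p by full enumeration with rational arithmetic.

    Conditional on allele counts, the weight of a table with h
    heterozygotes is 2^h * n! / (hom_rare! h! hom_common!); the p-value
    sums normalized weights not exceeding the observed table's.
    """
    n = n_AA + n_Aa + n_aa
    n_rare = 2 * min(n_AA, n_aa) + n_Aa

    def weight(h: int) -> Fraction:
        hom_r = (n_rare - h) // 2
        hom_c = n - h - hom_r
        return Fraction(2**h * factorial(n), factorial(hom_r) * factorial(h) * factorial(hom_c))

    hets = range(n_rare % 2, min(n_rare, 2 * n - n_rare) + 1, 2)
    weights = {h: weight(h) for h in hets}
    total = sum(weights.values())
    w_obs = weights[n_Aa]
    return float(sum(w for w in weights.values() if w <= w_obs) / total)


def dc_bruteforce(matrix: np.ndarray) -> np.ndarray:
    """Node strengths by naive per-node, per-neighbor summation."""
    k = matrix.shape[0]
    out = np.zeros(k)
    for i in range(k):
        for j in range(k):
            out[i] += matrix[i, j]
    return out


def edge_weight_bruteforce(lengths, fas, s_i, s_j) -> float:
    """Fiber-density weight by an explicit loop."""
    if len(lengths) == 0:
        return 0.0
    inv_len = 0.0
    for l in lengths:
        inv_len += 1.0 / l
    mean_fa = sum(fas) / len(fas)
    return mean_fa * 2.0 / (s_i + s_j) * inv_len


def loocv_leverage_oracle(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Closed-form LOOCV predictions: y_i - e_i / (1 - h_ii)."""
    H = X @ np.linalg.inv(X.T @ X) @ X.T
    beta = np.linalg.lstsq(X, y, rcond=None)[0]
    resid = y - X @ beta
    return y - resid / (1.0 - np.diag(H))
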