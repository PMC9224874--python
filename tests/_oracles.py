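"""Independent oracles used by the test suite.

These deliberately avoid the code paths they check: exact-rational
enumeration for the HWE and Fisher tests, concordant-pair counting for
AUC-ROC, and a hand-rolled IRLS Newton solver for logistic regression.
"""

from __future__ import annotations

from fractions import Fraction
from math import comb, factorial

import numpy as np


def hwe_enum(n_hom_ref: int, n_het: int, n_hom_alt: int) -> Fraction:
    """Exact two-sided HWE p by direct enumeration of genotype tables.

    Conditional probability of a table (a, h, c) given allele counts:
    P = n! / (a! h! c!) * 2^h * n_ref! n_alt! / (2n)!  (Levene).
    Sums P over tables whose P <= P(observed), in exact rationals.
    """
    a, h, c = n_hom_ref, n_het, n_hom_alt
    n = a + h + c
    n_ref, n_alt = 2 * a + h, h + 2 * c
    if n_ref == 0 or n_alt == 0:
        return Fraction(1)
    denom = factorial(2 * n) // (factorial(n_ref) * factorial(n_alt))

    def prob(h2: int) -> Fraction:
        a2, c2 = (n_ref - h2) // 2, (n_alt - h2) // 2
        num = factorial(n) // (factorial(a2) * factorial(h2) * factorial(c2)) * 2**h2
        return Fraction(num, denom)

    p_obs = prob(h)
    total = Fraction(0)
    for h2 in range(n_ref % 2, min(n_ref, n_alt) + 1, 2):
        p = prob(h2)
        if p <= p_obs:
            total += p
    return total


def fisher_enum(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p by margin-preserving enumeration.

    Hypergeometric table probabilities in exact rationals; tables whose
    probability is <= observed * (1 + 1e-7) are summed (the standard
    point-probability convention).
    """
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    lo, hi = max(0, r1 + c1 - n), min(r1, c1)
    denom = comb(n, c1)
    probs = {x: Fraction(comb(r1, x) * comb(r2, c1 - x), denom) for x in range(lo, hi + 1)}
    p_obs = probs[a]
    cut = p_obs + p_obs * Fraction(1, 10**7)
    return float(sum(p for p in probs.values() if p <= cut))


def auc_pairs(scores: np.ndarray, labels: np.ndarray) -> float:
    """AUC-ROC as the concordant-pair fraction (ties count 1/2)."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = 0.0
    for sp in pos:
        for sn in neg:
            wins += 1.0 if sp > sn else 0.5 if sp == sn else 0.0
    return wins / (len(pos) * len(neg))


def irls_logistic(x: np.ndarray, y: np.ndarray, tol: float = 1e-12, max_iter: int = 200):
    """Newton–Raphson ML fit of logit P(y=1) = b0 + b1 x; returns (beta, se)."""
    X = np.column_stack([np.ones_like(x, dtype=float), x])
    beta = np.zeros(2)
    for _ in range(max_iter):
        eta = X @ beta
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = mu * (1 - mu)
        grad = X.T @ (y - mu)
        hess = X.T @ (X * w[:, None])
        step = np.linalg.solve(hess, grad)
        beta = beta + step
        if np.abs(step).max() < tol:
            break
    eta = X @ beta
    mu = 1.0 / (1.0 + np.exp(-eta))
    cov = np.linalg.inv(X.T @ (X * (mu * (1 - mu))[:, None]))
    return beta, np.sqrt(np.diag(cov))
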