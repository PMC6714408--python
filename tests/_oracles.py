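"""Independent reference implementations used only to check the package.

Each oracle deliberately recomputes its quantity by a different route than
the library: exhaustive path enumeration instead of dynamic programming,
exact rational arithmetic instead of log-gamma, textbook IRLS instead of
statsmodels, and the literal step-up definition instead of the vectorized
adjusted-p formula.
"""

from __future__ import annotations

import itertools
from fractions import Fraction
from math import comb

import numpy as np

from cnvresp.hmm import HmmModel, emission_matrix, transition_log_matrix


def brute_force_best_path(signals, model: HmmModel) -> tuple[tuple[int, ...], float]:
    """Best copy-number path by enumerating all 5^n candidates."""
    E = emission_matrix(signals, model)
    pos = np.array([s.probe.position for s in signals])
    n = len(signals)
    paths = np.array(list(itertools.product(range(5), repeat=n)), dtype=np.int64)
    lp = model.start_log_probs()[paths[:, 0]] + E[0][paths[:, 0]]
    for t in range(1, n):
        T = transition_log_matrix(float(pos[t] - pos[t - 1]), model)
        lp += T[paths[:, t - 1], paths[:, t]] + E[t][paths[:, t]]
    best = int(np.argmax(lp))
    return tuple(int(s) for s in paths[best]), float(lp[best])


def score_path(path, signals, model: HmmModel) -> float:
    """Joint log probability of one explicit path (matrix lookups only)."""
    E = emission_matrix(signals, model)
    pos = np.array([s.probe.position for s in signals])
    lp = model.start_log_probs()[path[0]] + E[0][path[0]]
    for t in range(1, len(signals)):
        T = transition_log_matrix(float(pos[t] - pos[t - 1]), model)
        lp += T[path[t - 1], path[t]] + E[t][path[t]]
    return float(lp)


def hwe_exact_enumeration(n_het: int, n_hom_rare: int, n_hom_common: int) -> float:
    """Exact conditional HWE p-value with rational arithmetic.

    Enumerates every heterozygote count compatible with the observed allele
    counts, computes each probability as an exact Fraction, and sums those
    not exceeding the observed one.
    """
    n = n_het + n_hom_rare + n_hom_common
    n_rare = 2 * n_hom_rare + n_het
    if n_rare > n:
        n_rare = 2 * n - n_rare
    if n == 0 or n_rare == 0:
        return 1.0
    denom = comb(2 * n, n_rare)
    probs: dict[int, Fraction] = {}
    for het in range(n_rare % 2, n_rare + 1, 2):
        rare_hom = (n_rare - het) // 2
        common_hom = n - het - rare_hom
        if common_hom < 0:
            continue
        ways = (
            Fraction(
                comb(n, het) * comb(n - het, rare_hom) * 2**het,
                denom,
            )
        )
        probs[het] = ways
    obs = probs[n_het]
    return float(sum(p for p in probs.values() if p <= obs))


def irls_logistic(y: np.ndarray, X: np.ndarray, tol: float = 1e-12, max_iter: int = 200) -> np.ndarray:
    """Textbook iteratively reweighted least squares for logistic regression."""
    beta = np.zeros(X.shape[1])
    for _ in range(max_iter):
        eta = X @ beta
        p = 1.0 / (1.0 + np.exp(-eta))
        w = np.clip(p * (1.0 - p), 1e-12, None)
        z = eta + (y - p) / w
        wx = X * w[:, None]
        new = np.linalg.solve(X.T @ wx, X.T @ (w * z))
        if np.abs(new - beta).max() < tol:
            return new
        beta = new
    return beta


def bh_brute_force(p_values: np.ndarray, q: float) -> np.ndarray:
    """Literal Benjamini–Hochberg: reject all p <= the largest p(k) <= k*q/m."""
    p = np.asarray(p_values, dtype=float)
    m = p.size
    order = np.sort(p)
    threshold = 0.0
    for k in range(1, m + 1):
        if order[k - 1] <= k * q / m:
            threshold = order[k - 1]
    return p <= threshold if threshold > 0 else np.zeros(m, dtype=bool)
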