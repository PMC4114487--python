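"""Independent brute-force oracles used by the test suite.

These deliberately avoid the code paths they check: Viterbi by exhaustive
path enumeration, dispersion criteria by literal formula expansion.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy.stats import multivariate_normal


def brute_force_viterbi(startprob, transmat, means, covars, X) -> np.ndarray:
    """Most probable state path by enumerating all K**T sequences."""
    T = len(X)
    K = len(startprob)
    emission = np.array([
        [multivariate_normal.logpdf(x, means[k], covars[k]) for k in range(K)]
        for x in X
    ])
    best_logp, best_path = -np.inf, None
    for path in itertools.product(range(K), repeat=T):
        logp = np.log(startprob[path[0]]) + emission[0, path[0]]
        for t in range(1, T):
            logp += np.log(transmat[path[t - 1], path[t]]) + emission[t, path[t]]
        if logp > best_logp:
            best_logp, best_path = logp, path
    return np.array(best_path)


def calinski_harabasz_by_hand(X, labels) -> float:
    """Literal expansion of CH = [B/(K-1)] / [W/(n-K)]."""
    X = np.asarray(X, dtype=float)
    ks = np.unique(labels)
    n, K = len(X), len(ks)
    c = X.mean(axis=0)
    B = sum(len(X[labels == k]) * np.sum((X[labels == k].mean(axis=0) - c) ** 2)
            for k in ks)
    W = sum(np.sum((X[labels == k] - X[labels == k].mean(axis=0)) ** 2) for k in ks)
    return (B / (K - 1)) / (W / (n - K))


def chi_square_by_hand(observed, expected) -> float:
    """Sum of (O - E)^2 / E."""
    return float(sum((o - e) ** 2 / e for o, e in zip(observed, expected)))
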