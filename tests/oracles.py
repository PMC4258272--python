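"""Independent brute-force oracles used to check the implementation."""

import numpy as np


def brute_force_standardize(X):
    """Entrywise chi-square standardization straight from the definition."""
    n = X.sum()
    P = X / n
    r = P.sum(axis=1)
    c = P.sum(axis=0)
    out = np.empty_like(P)
    for i in range(X.shape[0]):
        for j in range(X.shape[1]):
            out[i, j] = (P[i, j] - r[i] * c[j]) / np.sqrt(r[i] * c[j])
    return out


def exhaustive_1d_kmeans(scores):
    """Minimum within-cluster-SS two-group partition by trying every threshold."""
    order = np.argsort(scores)
    s = np.asarray(scores, dtype=float)[order]
    best, best_ss = None, np.inf
    for cut in range(1, len(s)):
        lo, hi = s[:cut], s[cut:]
        ss = ((lo - lo.mean()) ** 2).sum() + ((hi - hi.mean()) ** 2).sum()
        if ss < best_ss:
            best_ss, best = ss, cut
    positive = np.zeros(len(s), dtype=bool)
    positive[order[best:]] = True
    return positive
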