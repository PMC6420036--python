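"""Independent numerical oracles shared by the test modules."""

import math

import numpy as np


def brute_binom(z, z0, p):
    """Binomial mass by direct factorial computation."""
    return math.comb(z0, z) * p**z * (1.0 - p) ** (z0 - z)


def power_iteration_bound(A, n_iter=5000, tol=1e-12):
    """Dominant eigenvalue via power iteration on the non-negative shift
    A + s*I — an independent route to the spectral bound."""
    s = float(-A.diagonal().min()) + 1.0
    M = A + s * np.eye(A.shape[0])
    v = np.ones(A.shape[0])
    lam = 0.0
    for _ in range(n_iter):
        w = M @ v
        lam_new = float(v @ w / (v @ v))
        v = w / np.linalg.norm(w)
        if abs(lam_new - lam) < tol:
            lam = lam_new
            break
        lam = lam_new
    return lam - s, v
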