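"""Independent reference implementations used only to check the package.

Nothing here touches the package's solver or scoring code paths: the
elastic-net oracle is plain proximal (sub)gradient descent on the printed
objective, the ridge oracle is the closed form obtained by differentiating
it at alpha = 0, and the ssGSEA oracle is a naive per-position loop.
"""

from __future__ import annotations

import numpy as np


def enet_objective(X, y, p, lam, alpha):
    r = y - X @ p
    return float(r @ r + lam * ((1 - alpha) / 2 * (p @ p) + alpha * np.abs(p).sum()))


def prox_gradient_enet(X, y, lam, alpha, n_iter=3000):
    """Proximal (sub)gradient descent on ||y-Xp||^2 + lam[(1-a)/2|p|^2 + a|p|_1]."""
    L = 2 * np.linalg.eigvalsh(X.T @ X).max() + lam * (1 - alpha) + 1e-12
    p = np.zeros(X.shape[1])
    thr = lam * alpha / L
    for _ in range(n_iter):
        g = 2 * X.T @ (X @ p - y) + lam * (1 - alpha) * p
        q = p - g / L
        p = np.sign(q) * np.maximum(np.abs(q) - thr, 0.0)
    return p


def ridge_closed_form(X, y, lam):
    """Minimizer of ||y - Xp||^2 + (lam/2)||p||^2."""
    K = X.shape[1]
    return np.linalg.solve(X.T @ X + (lam / 2) * np.eye(K), X.T @ y)


def ssgsea_brute(values, gene_set, tau, normalize):
    """Naive loop evaluation of the rank-weighted running-sum score.

    ``values`` is a mapping gene -> expression. Ranking is descending by
    value, ties broken by gene id ascending.
    """
    ranked = sorted(values, key=lambda g: (-values[g], g))
    N = len(ranked)
    members = set(gene_set)
    n_out = N - len(members & set(ranked))
    w_total = 0.0
    for i, g in enumerate(ranked):
        if g in members:
            w_total += (N - i) ** tau
    es = 0.0
    p_in = 0.0
    p_out = 0.0
    for i, g in enumerate(ranked):
        if g in members:
            p_in += (N - i) ** tau / w_total
        else:
            p_out += 1.0 / n_out
        es += p_in - p_out
    return es / N if normalize else es
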