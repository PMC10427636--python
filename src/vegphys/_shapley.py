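"""Interventional Shapley values for black-box regressors.

Feature contributions are Shapley values of the coalition game
``v(S) = E_b[f(x_S, b_{~S})]`` where the expectation runs over a background
sample ``b``.  For p <= ``exact_threshold`` features all 2^p coalitions are
enumerated (exact values); above that, permutations are sampled and marginal
contributions averaged.  Both estimators satisfy the efficiency identity

    base + sum_j phi_j == f(x)          (to floating-point precision)

because every permutation's marginals telescope from v(empty) to v(full),
and v(full) evaluates f at x itself.
"""

from __future__ import annotations

from math import factorial

import numpy as np


def _coalition_values(predict, X, background, masks):
    """v(S) for every instance (rows of X) and every mask in `masks`.

    Returns an array (n_masks, n_instances).  Batched into a single predict
    call: rows are background copies with masked features replaced by the
    instance's values.
    """
    n, p = X.shape
    m = background.shape[0]
    k = len(masks)
    out = np.empty((k, n))
    chunk = max(1, int(2_000_000 / max(n * m, 1)))
    for lo in range(0, k, chunk):
        sub = masks[lo : lo + chunk]
        big = np.empty((len(sub), n, m, p))
        big[:] = background[None, None, :, :]
        for s, mask in enumerate(sub):
            if mask.any():
                big[s, :, :, mask] = X[:, mask].T[:, :, None]
        preds = predict(big.reshape(len(sub) * n * m, p)).reshape(len(sub), n, m)
        out[lo : lo + chunk] = preds.mean(axis=2)
    return out


def shapley_values(
    predict,
    X: np.ndarray,
    background: np.ndarray,
    exact_threshold: int = 10,
    n_permutations: int = 64,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, float]:
    """Shapley contributions phi (n_instances x p) and the base value.

    ``predict`` maps an (m x p) array to m predictions.  The base value is
    the background-mean prediction; ``base + phi.sum(1)`` equals
    ``predict(X)`` row-wise.
    """
    X = np.asarray(X, dtype=float)
    background = np.asarray(background, dtype=float)
    n, p = X.shape
    base = float(predict(background).mean())
    if p <= exact_threshold:
        return _exact(predict, X, background, base), base
    if rng is None:
        rng = np.random.default_rng(0)
    return _sampled(predict, X, background, base, n_permutations, rng), base


def _exact(predict, X, background, base):
    n, p = X.shape
    masks = []
    for code in range(2**p):
        masks.append(np.array([(code >> j) & 1 for j in range(p)], dtype=bool))
    values = _coalition_values(predict, X, background, masks)  # (2^p, n)
    phi = np.zeros((n, p))
    fact = [factorial(i) for i in range(p + 1)]
    for code in range(2**p):
        size = bin(code).count("1")
        for j in range(p):
            if code & (1 << j):
                continue
            w = fact[size] * fact[p - size - 1] / fact[p]
            phi[:, j] += w * (values[code | (1 << j)] - values[code])
    return phi


def _sampled(predict, X, background, base, n_permutations, rng):
    n, p = X.shape
    phi = np.zeros((n, p))
    for _ in range(n_permutations):
        perm = rng.permutation(p)
        masks = [np.zeros(p, dtype=bool)]
        mask = np.zeros(p, dtype=bool)
        for j in perm:
            mask = mask.copy()
            mask[j] = True
            masks.append(mask)
        values = _coalition_values(predict, X, background, masks)  # (p+1, n)
        for k, j in enumerate(perm):
            phi[:, j] += values[k + 1] - values[k]
    return phi / n_permutations
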