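"""Numba kernels: elastic-net coordinate descent and skip-gram SGD.

These are the two inner loops hot enough to need compiled code — the
penalized least-squares solver runs thousands of times inside nested
cross-validation, and the embedding trainer performs millions of
stochastic-gradient updates.  Everything here is plain-array code; the
public surfaces live in :mod:`multifuse.coop` and :mod:`multifuse.viral`.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=False)
def _soft(x: float, t: float) -> float:
    if x > t:
        return x - t
    if x < -t:
        return x + t
    return 0.0


@njit(cache=False)
def enet_coordinate_descent(A, b, n0, lam, alpha, beta, max_iter, tol):
    """Elastic-net coordinate descent on the (possibly augmented) system.

    Minimizes  (1/(2*n0))‖b − Aβ‖² + λ(α‖β‖₁ + (1−α)/2 ‖β‖²)
    in place on ``beta`` with active-set cycling; returns the number of
    full sweeps performed.
    """
    N, P = A.shape
    col_ss = np.empty(P)
    for j in range(P):
        s = 0.0
        for i in range(N):
            s += A[i, j] * A[i, j]
        col_ss[j] = s / n0
    r = b - A @ beta
    l1 = lam * alpha
    l2 = lam * (1.0 - alpha)
    active = np.ones(P, dtype=np.bool_)
    sweeps = 0
    for it in range(max_iter):
        sweeps += 1
        full = (it % 10 == 0)  # periodic full sweep to refresh the active set
        max_delta = 0.0
        for j in range(P):
            if not (full or active[j]):
                continue
            if col_ss[j] == 0.0:
                beta[j] = 0.0
                continue
            bj = beta[j]
            z = 0.0
            for i in range(N):
                z += A[i, j] * r[i]
            z = z / n0 + col_ss[j] * bj
            bnew = _soft(z, l1) / (col_ss[j] + l2)
            if bnew != bj:
                d = bj - bnew
                for i in range(N):
                    r[i] += A[i, j] * d
                beta[j] = bnew
                if abs(d) > max_delta:
                    max_delta = abs(d)
            active[j] = beta[j] != 0.0
        if max_delta < tol and full:
            break
        if max_delta < tol and not full:
            # converged on the active set; force a confirming full sweep
            max_delta2 = 0.0
            for j in range(P):
                if col_ss[j] == 0.0:
                    continue
                bj = beta[j]
                z = 0.0
                for i in range(N):
                    z += A[i, j] * r[i]
                z = z / n0 + col_ss[j] * bj
                bnew = _soft(z, l1) / (col_ss[j] + l2)
                if bnew != bj:
                    d = bj - bnew
                    for i in range(N):
                        r[i] += A[i, j] * d
                    beta[j] = bnew
                    if abs(d) > max_delta2:
                        max_delta2 = abs(d)
                active[j] = beta[j] != 0.0
            if max_delta2 < tol:
                break
    return sweeps


@njit(cache=False)
def skipgram_train(tokens, offsets, w_in, w_out, window, negatives,
                   neg_table, epochs, lr_start, lr_end, seed):
    """Skip-gram with negative sampling over token-id sentences.

    ``tokens`` is the concatenation of all sentences, delimited by
    ``offsets``; ``neg_table`` is the unigram^0.75 sampling table.  The
    learning rate decays linearly from ``lr_start`` to ``lr_end`` over all
    updates.  Deterministic for a fixed seed (single-threaded).
    """
    np.random.seed(seed)
    n_sent = offsets.shape[0] - 1
    dim = w_in.shape[1]
    total = 0
    for s in range(n_sent):
        length = offsets[s + 1] - offsets[s]
        total += length
    total_updates = total * epochs
    tsize = neg_table.shape[0]
    count = 0
    grad = np.empty(dim)
    for _ in range(epochs):
        for s in range(n_sent):
            start, end = offsets[s], offsets[s + 1]
            for i in range(start, end):
                center = tokens[i]
                frac = count / max(1, total_updates)
                lr = lr_start + (lr_end - lr_start) * frac
                count += 1
                lo = i - window if i - window > start else start
                hi = i + window + 1 if i + window + 1 < end else end
                for j in range(lo, hi):
                    if j == i:
                        continue
                    context = tokens[j]
                    for d in range(dim):
                        grad[d] = 0.0
                    for k in range(negatives + 1):
                        if k == 0:
                            target = context
                            label = 1.0
                        else:
                            target = neg_table[np.random.randint(tsize)]
                            if target == context:
                                continue
                            label = 0.0
                        dot = 0.0
                        for d in range(dim):
                            dot += w_in[center, d] * w_out[target, d]
                        if dot > 8.0:
                            f = 1.0
                        elif dot < -8.0:
                            f = 0.0
                        else:
                            f = 1.0 / (1.0 + np.exp(-dot))
                        g = lr * (label - f)
                        for d in range(dim):
                            grad[d] += g * w_out[target, d]
                            w_out[target, d] += g * w_in[center, d]
                    for d in range(dim):
                        w_in[center, d] += grad[d]
    return count
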