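"""Numba kernels for the fitting inner loop.

The model-fitting objective re-runs the DP-KF over a whole session for
every parameter proposal, which is far too slow in interpreted numpy for
restarted optimization over many participants.  This module repeats the
filter recursion of :mod:`dpkf.filter` as compiled loops.  It is an
implementation detail: the readable numpy filter is the reference, and
the two are equivalence-tested to 1e-10.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

_LOG2PI = math.log(2.0 * math.pi)

# prediction-convention codes
PRED_MIXTURE = 0
PRED_MAP = 1


@njit(cache=True)
def _qeff(q: float, lam: float, delta: int) -> float:
    if lam == 1.0:
        return q * delta
    return q * (1.0 - lam ** (2 * delta)) / (1.0 - lam * lam)


@njit(cache=True)
def _filter_block(y, alpha, beta, q, r, lam, m0, c, pred_code, pred_out, assign_out):
    """One DP-KF pass over a T x D block; fills predictions and MAP
    assignments, returns the number of modes created."""
    T, D = y.shape
    means = np.zeros((T, D))
    variances = np.zeros((T, D))
    counts = np.zeros(T)
    last = np.zeros(T, dtype=np.int64)
    K = 0
    prev = -1

    pm = np.zeros((T + 1, D))  # per-candidate predicted means (K existing + new)
    pv = np.zeros((T + 1, D))

    for t in range(T):
        now = t + 1
        # candidate moments and log-likelihoods
        for k in range(K):
            delta = now - last[k]
            ld = lam**delta
            for d in range(D):
                pm[k, d] = ld * means[k, d]
                pv[k, d] = ld * ld * variances[k, d] + _qeff(q[d], lam, delta)
        for d in range(D):
            pm[K, d] = m0[d]
            pv[K, d] = c

        # sticky-CRP prior weights (unnormalized)
        wsum = alpha
        for k in range(K):
            wsum += counts[k]
        if prev >= 0:
            wsum += beta

        # behavioral prediction before seeing y[t]
        if K == 0:
            for d in range(D):
                pred_out[t, d] = m0[d]
        elif pred_code == PRED_MIXTURE:
            for d in range(D):
                acc = alpha * m0[d]
                for k in range(K):
                    w = counts[k] + (beta if k == prev else 0.0)
                    acc += w * pm[k, d]
                pred_out[t, d] = acc / wsum
        else:  # PRED_MAP: a-priori most probable candidate
            # strict > keeps the first maximum: lower labels win ties and
            # existing modes beat the new mode, matching the reference.
            best_w = -1.0
            best_k = 0
            for k in range(K + 1):
                w = alpha if k == K else counts[k] + (beta if k == prev else 0.0)
                if w > best_w:
                    best_w = w
                    best_k = k
            for d in range(D):
                pred_out[t, d] = pm[best_k, d]

        # posterior over candidates; hard MAP assignment
        best_lp = -np.inf
        z = 0
        for k in range(K + 1):
            if K == 0:
                w = 1.0
            elif k == K:
                w = alpha
            else:
                w = counts[k] + (beta if k == prev else 0.0)
            if w <= 0.0:
                continue
            lp = math.log(w)
            for d in range(D):
                tv = pv[k, d] + r[d]
                diff = y[t, d] - pm[k, d]
                lp += -0.5 * (_LOG2PI + math.log(tv) + diff * diff / tv)
            if lp > best_lp:
                best_lp = lp
                z = k

        # Kalman update of the assigned mode only
        if z == K:
            K += 1
        for d in range(D):
            eta = pv[z, d] / (pv[z, d] + r[d])
            means[z, d] = pm[z, d] + eta * (y[t, d] - pm[z, d])
            variances[z, d] = (1.0 - eta) * pv[z, d]
        counts[z] += 1.0
        last[z] = now
        prev = z
        assign_out[t] = z + 1

    return K


@njit(cache=True)
def session_predictions(stims, alpha, beta, q, r, lam, m0, c, pred_code):
    """DP-KF predictions for every block of a session.

    ``stims`` is B x T x D; returns (predictions B x T x D,
    assignments B x T, modes-per-block B).
    """
    B, T, D = stims.shape
    preds = np.empty((B, T, D))
    assigns = np.empty((B, T), dtype=np.int64)
    Ks = np.empty(B, dtype=np.int64)
    for b in range(B):
        Ks[b] = _filter_block(
            stims[b], alpha, beta, q, r, lam, m0, c, pred_code, preds[b], assigns[b]
        )
    return preds, assigns, Ks
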