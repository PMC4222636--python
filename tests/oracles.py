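"""Independent reference implementations used only as test oracles.

Deliberately naive: a textbook scalar Kalman filter, exact Gaussian
conditioning on the joint distribution over a state chain, the
conjugate posterior for a stationary Gaussian mean, and exhaustive
enumeration of Chinese-restaurant-process partition probabilities.
None of these share code with the package.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def textbook_kf(y, q, r, lam, m0, c):
    """Scalar Kalman filter one-step predictions and filtered moments
    for x_t = lam * x_{t-1} + N(0, q), y_t = x_t + N(0, r), x_1 ~ N(m0, c)."""
    T = len(y)
    pred_mean = np.empty(T)
    pred_var = np.empty(T)
    filt_mean = np.empty(T)
    filt_var = np.empty(T)
    m, P = m0, c
    for t in range(T):
        pred_mean[t], pred_var[t] = m, P
        K = P / (P + r)
        m = m + K * (y[t] - m)
        P = (1 - K) * P
        filt_mean[t], filt_var[t] = m, P
        m, P = lam * m, lam * lam * P + q
    return pred_mean, pred_var, filt_mean, filt_var


def chain_joint_gaussian(times, y, q, r, lam, m0, c):
    """Exact conditional means of the states of one mode's chain.

    ``times`` are the (sorted, 1-based) trials of the chain; between
    consecutive members the state takes ``delta`` diffusion steps.
    Returns (filtered_means, smoothed_means): position i of
    ``filtered_means`` conditions on y[: i + 1]; ``smoothed_means``
    conditions on the whole chain.
    """
    L = len(times)
    # build mean vector and covariance of the latent states
    mean = np.empty(L)
    cov = np.empty((L, L))
    mean[0] = m0
    var = [c]
    scale = [1.0]  # prod of lam**delta from position 0 to i
    for i in range(1, L):
        delta = times[i] - times[i - 1]
        ld = lam**delta
        if lam == 1.0:
            qeff = q * delta
        else:
            qeff = q * (1 - lam ** (2 * delta)) / (1 - lam**2)
        mean[i] = ld * mean[i - 1]
        var.append(ld * ld * var[-1] + qeff)
        scale.append(scale[-1] * ld)
    for i in range(L):
        for j in range(i, L):
            # cov(x_i, x_j) = var_i * prod(lam**delta) between them
            cov[i, j] = cov[j, i] = var[i] * (scale[j] / scale[i])
    obs_cov = cov + r * np.eye(L)
    smoothed = mean + cov @ np.linalg.solve(obs_cov, np.asarray(y) - mean)
    filtered = np.empty(L)
    for i in range(L):
        sub = slice(0, i + 1)
        filtered[i] = mean[i] + cov[i, sub] @ np.linalg.solve(
            obs_cov[sub, sub], np.asarray(y)[sub] - mean[sub]
        )
    return filtered, smoothed


def stationary_posterior_mean(y, r, m0, c):
    """Conjugate posterior mean of a constant Gaussian state given
    observations with noise variance r and prior N(m0, c)."""
    n = len(y)
    return (m0 / c + np.sum(y) / r) / (1 / c + n / r)


def crp_mode_count_distribution(T, alpha, beta=0.0):
    """Exact distribution of the number of occupied modes after T
    sequential sticky-CRP draws, by exhaustive path enumeration."""
    dist: dict[int, float] = {}

    def recurse(counts, prev, prob, t):
        if t == T:
            dist[len(counts)] = dist.get(len(counts), 0.0) + prob
            return
        if not counts:
            recurse([1], 0, prob, t + 1)
            return
        total = sum(counts) + beta + alpha
        for k, n in enumerate(counts):
            w = n + (beta if k == prev else 0.0)
            if w > 0:
                nxt = list(counts)
                nxt[k] += 1
                recurse(nxt, k, prob * w / total, t + 1)
        if alpha > 0:
            recurse(list(counts) + [1], len(counts), prob * alpha / total, t + 1)

    recurse([], None, 1.0, 0)
    return dist


def manual_rm_anova_interaction(cells):
    """2x2 repeated-measures ANOVA interaction F by hand.

    ``cells[(subject, a, b)]`` with a, b in {0, 1}.  Returns (F, df1, df2).
    """
    subjects = sorted({s for s, _, _ in cells})
    n = len(subjects)
    # interaction contrast per subject: (a0b0 - a0b1) - (a1b0 - a1b1)
    grand = np.mean(list(cells.values()))
    a_means = {a: np.mean([v for (s, x, b), v in cells.items() if x == a]) for a in (0, 1)}
    b_means = {b: np.mean([v for (s, a, x), v in cells.items() if x == b]) for b in (0, 1)}
    ab_means = {
        (a, b): np.mean([v for (s, x, yv), v in cells.items() if x == a and yv == b])
        for a, b in itertools.product((0, 1), repeat=2)
    }
    s_means = {s: np.mean([v for (x, a, b), v in cells.items() if x == s]) for s in subjects}
    sa_means = {
        (s, a): np.mean([v for (x, z, b), v in cells.items() if x == s and z == a])
        for s in subjects for a in (0, 1)
    }
    sb_means = {
        (s, b): np.mean([v for (x, a, z), v in cells.items() if x == s and z == b])
        for s in subjects for b in (0, 1)
    }
    ss_ab = n * sum(
        (ab_means[a, b] - a_means[a] - b_means[b] + grand) ** 2
        for a, b in itertools.product((0, 1), repeat=2)
    )
    ss_err = sum(
        (
            cells[s, a, b]
            - ab_means[a, b]
            - sa_means[s, a]
            - sb_means[s, b]
            + a_means[a]
            + b_means[b]
            + s_means[s]
            - grand
        )
        ** 2
        for s, a, b in cells
    )
    df1 = 1
    df2 = n - 1
    return (ss_ab / df1) / (ss_err / df2), df1, df2


def gauss_logpdf(x, mean, var):
    return -0.5 * (math.log(2 * math.pi * var) + (x - mean) ** 2 / var)
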