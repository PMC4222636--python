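"""Simulation of the sticky-CRP switching linear-Gaussian generative model.

At each time step a mode is drawn from a sticky Chinese restaurant
process: an existing mode ``k`` with probability proportional to its
usage count ``N_k`` (plus a stickiness bonus ``beta`` if it was active
on the previous step), or a brand-new mode with probability proportional
to the concentration ``alpha``.  A new mode's state is drawn from the
Gaussian base measure ``Normal(m0, c)``; every already-created mode's
state — active or not — diffuses as ``x <- decay * x + Normal(0, q)``;
the observation is the active mode's state plus sensory noise
``Normal(0, r)``.

Also provides the 1-D morph protocols (gradual vs. mixed presentation
order of a morph continuum) used to demonstrate mode segmentation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .params import Hyperparameters

__all__ = ["SimulatedSequence", "crp_prior", "simulate_sequence", "morph_sequence"]


def crp_prior(
    counts: np.ndarray | list,
    prev_mode: int | None,
    alpha: float,
    beta: float,
) -> np.ndarray:
    """Sticky-CRP probabilities over K existing modes plus one new mode.

    Entry ``k < K`` is proportional to ``counts[k] + beta * [k == prev_mode]``;
    the last entry (a new mode) is proportional to ``alpha``.  Mode labels
    are 1-based: ``prev_mode`` is in ``1..K`` or ``None`` on the first draw.

    With no existing modes the new mode is certain (even at ``alpha = 0``).
    """
    counts = np.asarray(counts, dtype=float)
    if counts.ndim != 1:
        raise ValueError("counts must be a 1-D array")
    if np.any(counts < 0):
        raise ValueError("counts must be nonnegative")
    if alpha < 0 or beta < 0:
        raise ValueError("alpha and beta must be >= 0")
    K = counts.size
    if K == 0:
        return np.array([1.0])
    if prev_mode is not None and not (1 <= prev_mode <= K):
        raise ValueError(f"prev_mode must be in 1..{K} or None")
    w = np.empty(K + 1)
    w[:K] = counts
    if prev_mode is not None:
        w[prev_mode - 1] += beta
    w[K] = alpha
    total = w.sum()
    if total <= 0:
        raise ValueError("degenerate CRP weights: all counts zero and alpha = 0")
    return w / total


@dataclass
class SimulatedSequence:
    """Output of :func:`simulate_sequence`.

    ``observations`` is T x D; ``true_modes`` holds 1-based mode labels in
    first-appearance order (each new label is 1 + the running maximum);
    ``true_states`` is a T x K_total x D array of the state means of every
    created mode at each time (NaN before a mode's creation).
    """

    observations: np.ndarray
    true_states: np.ndarray
    true_modes: np.ndarray

    @property
    def n_modes(self) -> int:
        return int(self.true_modes.max())

    def to_frame(self) -> pd.DataFrame:
        T, D = self.observations.shape
        data = {"t": np.arange(1, T + 1), "mode": self.true_modes}
        for d in range(D):
            data[f"obs_dim{d + 1}"] = self.observations[:, d]
        for d in range(D):
            # state of the active mode at each time
            data[f"state_dim{d + 1}"] = self.true_states[
                np.arange(T), self.true_modes - 1, d
            ]
        return pd.DataFrame(data)


def simulate_sequence(
    hyper: Hyperparameters, T: int, rng: np.random.Generator
) -> SimulatedSequence:
    """Draw a length-``T`` sequence from the generative model."""
    if T < 1:
        raise ValueError("T must be >= 1")
    D = hyper.n_dims
    lam, q = hyper.decay, hyper.q
    states: list[np.ndarray] = []  # current state mean of each created mode
    counts: list[int] = []
    prev: int | None = None
    modes = np.empty(T, dtype=int)
    obs = np.empty((T, D))
    state_log = np.full((T, T, D), np.nan)  # trimmed to K_total afterwards

    for t in range(T):
        # every already-created mode diffuses, active or not
        for k in range(len(states)):
            states[k] = lam * states[k] + rng.normal(0.0, np.sqrt(q), size=D)
        p = crp_prior(np.array(counts), prev, hyper.alpha, hyper.beta)
        z = int(rng.choice(p.size, p=p)) + 1
        if z == len(states) + 1:  # new mode
            states.append(hyper.m0 + rng.normal(0.0, np.sqrt(hyper.c), size=D))
            counts.append(0)
        counts[z - 1] += 1
        prev = z
        modes[t] = z
        obs[t] = states[z - 1] + rng.normal(0.0, np.sqrt(hyper.r), size=D)
        for k, s in enumerate(states):
            state_log[t, k] = s

    K_total = len(states)
    return SimulatedSequence(obs, state_log[:, :K_total, :], modes)


def morph_sequence(
    protocol: str, n_morphs: int, rng: np.random.Generator | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """1-D morph continuum presented in gradual or scrambled order.

    Returns ``(values, morph_index)``: ``values[i]`` is the stimulus shown
    at position ``i`` and ``morph_index[i]`` its index on the 0..1
    continuum, so a mixed sequence re-sorted by ``morph_index`` recovers
    the gradual one.
    """
    if n_morphs < 2:
        raise ValueError("n_morphs must be >= 2")
    levels = np.linspace(0.0, 1.0, n_morphs)
    if protocol == "gradual":
        idx = np.arange(n_morphs)
    elif protocol == "mixed":
        if rng is None:
            raise ValueError("mixed protocol requires an rng")
        idx = rng.permutation(n_morphs)
    else:
        raise ValueError(f"unknown protocol {protocol!r}; expected 'gradual' or 'mixed'")
    return levels[idx], idx
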