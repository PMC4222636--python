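"""DP-KF sequential inference: local-MAP switching Kalman filtering.

The filter maintains a single high-probability partition of trials into
modes (a "local" approximation to the full posterior over partitions).
On each trial it

1. forms a behavioral prediction from the sticky-CRP prior over modes
   (by default the prior-weighted mixture of the modes' predicted means,
   including the new-mode term at the prior mean ``m0``),
2. scores every instantiated mode and the potential new mode by
   prior x likelihood (in log space),
3. hard-assigns the trial to the MAP mode, and
4. applies the per-dimension Kalman update to that mode only.

A mode that is not chosen is untouched; its uncertainty grows lazily —
when next considered, its predictive variance includes one diffusion
step per elapsed trial, so long-dormant modes are more tolerant of
prediction errors.

All inference is deterministic; there is no sampling anywhere.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .generative import crp_prior
from .params import Hyperparameters

__all__ = [
    "ModeState",
    "FilterTrace",
    "predict_mode",
    "kalman_gain",
    "update_mode",
    "mode_loglik",
    "filter_step",
    "run_filter",
]

_LOG2PI = math.log(2.0 * math.pi)


@dataclass(frozen=True)
class ModeState:
    """Sufficient statistics of one dynamical mode.

    ``mean``/``var`` are the per-dimension posterior of the mode's state
    as of trial ``last_active`` (1-based); ``count`` is the number of
    trials assigned to the mode.
    """

    mean: np.ndarray
    var: np.ndarray
    count: int
    last_active: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "mean", np.asarray(self.mean, dtype=float))
        object.__setattr__(self, "var", np.asarray(self.var, dtype=float))
        if np.any(self.var <= 0):
            raise ValueError("mode variance must stay > 0 componentwise")
        if self.count < 1:
            raise ValueError("an instantiated mode has count >= 1")


def _diffusion_var(hyper: Hyperparameters, delta: int) -> np.ndarray:
    """Accumulated diffusion variance over ``delta`` steps of x <- lam*x + N(0,q)."""
    lam = hyper.decay
    if lam == 1.0:
        return delta * hyper.q
    return hyper.q * (1.0 - lam ** (2 * delta)) / (1.0 - lam**2)


def predict_mode(
    state: ModeState | None, now: int, hyper: Hyperparameters
) -> tuple[np.ndarray, np.ndarray]:
    """Per-dimension predictive mean and variance of a mode at trial ``now``.

    For an instantiated mode with gap ``delta = now - last_active``:
    mean ``decay**delta * mean`` and variance ``decay**(2*delta) * var``
    plus the diffusion accumulated over ``delta`` steps.  ``state=None``
    denotes the virtual new mode, predicted at the base measure (m0, c).
    """
    if state is None:
        return hyper.m0.copy(), np.full(hyper.n_dims, hyper.c)
    delta = now - state.last_active
    if delta <= 0:
        raise ValueError(f"now={now} must exceed last_active={state.last_active}")
    lam = hyper.decay
    mean = lam**delta * state.mean
    var = lam ** (2 * delta) * state.var + _diffusion_var(hyper, delta)
    return mean, var


def kalman_gain(pred_var: np.ndarray, r: np.ndarray) -> np.ndarray:
    """Per-dimension learning rate eta = pred_var / (pred_var + r)."""
    pred_var = np.asarray(pred_var, dtype=float)
    r = np.asarray(r, dtype=float)
    if np.any(pred_var <= 0) or np.any(r <= 0):
        raise ValueError("variances must be > 0")
    return pred_var / (pred_var + r)


def update_mode(
    state: ModeState | None, y: np.ndarray, now: int, hyper: Hyperparameters
) -> ModeState:
    """Assign observation ``y`` at trial ``now`` to a mode and update it.

    Returns a new :class:`ModeState`; the input is not mutated.
    """
    y = np.asarray(y, dtype=float)
    if not np.all(np.isfinite(y)):
        raise ValueError("observation must be finite")
    m, s = predict_mode(state, now, hyper)
    eta = kalman_gain(s, hyper.r)
    new_mean = m + eta * (y - m)
    new_var = (1.0 - eta) * s
    count = 1 if state is None else state.count + 1
    return ModeState(new_mean, new_var, count, now)


def mode_loglik(
    state: ModeState | None, y: np.ndarray, now: int, hyper: Hyperparameters
) -> float:
    """Log-likelihood of ``y`` under one mode's predictive distribution.

    Sum over dimensions of ``log Normal(y; pred_mean, pred_var + r)``.
    For the never-instantiated new mode the predictive distribution is
    ``Normal(m0, c + r)``.
    """
    y = np.asarray(y, dtype=float)
    m, s = predict_mode(state, now, hyper)
    total_var = s + hyper.r
    return float(-0.5 * np.sum(_LOG2PI + np.log(total_var) + (y - m) ** 2 / total_var))


@dataclass
class _FilterState:
    """Mutable inference state threaded through :func:`filter_step`."""

    hyper: Hyperparameters
    modes: list[ModeState] = field(default_factory=list)
    prev_mode: int | None = None
    t: int = 0  # trials consumed so far

    @property
    def counts(self) -> np.ndarray:
        return np.array([m.count for m in self.modes], dtype=float)


@dataclass
class FilterTrace:
    """Per-trial record of DP-KF inference over a sequence.

    ``mode_probs[t]`` is the posterior over the modes instantiated before
    trial ``t+1`` plus the new mode (last entry).  ``assignments`` are
    1-based MAP labels; ``predicted_obs`` is the behavioral prediction
    made before seeing each observation, under the configured convention;
    ``assigned_pred`` is the predicted mean of the trial's MAP-assigned
    mode (the quantity plotted when predictions are colored by
    assignment).
    """

    hyper: Hyperparameters
    predicted_obs: np.ndarray
    assigned_pred: np.ndarray
    prediction_error: np.ndarray
    mode_probs: list[np.ndarray]
    assignments: np.ndarray
    modes: list[ModeState]
    prediction: str = "mixture"

    @property
    def n_modes(self) -> int:
        return len(self.modes)

    def chain(self, mode: int) -> np.ndarray:
        """1-based trial indices assigned to ``mode``."""
        if not (1 <= mode <= self.n_modes):
            raise ValueError(f"mode {mode} not in 1..{self.n_modes}")
        return np.flatnonzero(self.assignments == mode) + 1

    def mode_prob_series(self, mode: int) -> np.ndarray:
        """Posterior probability of a given (1-based) mode label at each
        trial; zero before the label was instantiable."""
        T = len(self.assignments)
        out = np.zeros(T)
        for t, p in enumerate(self.mode_probs):
            if mode <= p.size:  # existing modes + the would-be new label
                out[t] = p[mode - 1]
        return out

    def to_frame(self) -> pd.DataFrame:
        T, D = self.predicted_obs.shape
        data: dict = {"t": np.arange(1, T + 1)}
        for d in range(D):
            data[f"predicted_dim{d + 1}"] = self.predicted_obs[:, d]
        data["map_mode"] = self.assignments
        data["posterior"] = [json.dumps([round(float(x), 10) for x in p]) for p in self.mode_probs]
        return pd.DataFrame(data)

    def summary(self) -> dict:
        return {
            "K": self.n_modes,
            "assignments": [int(z) for z in self.assignments],
            "modes": [
                {
                    "mean": [float(x) for x in m.mean],
                    "var": [float(x) for x in m.var],
                    "count": int(m.count),
                    "last_active": int(m.last_active),
                }
                for m in self.modes
            ],
        }


def _step(fs: _FilterState, y: np.ndarray, prediction: str):
    """Advance the filter by one observation; returns per-trial records."""
    hyper = fs.hyper
    y = np.asarray(y, dtype=float)
    if y.shape != (hyper.n_dims,):
        raise ValueError(f"observation has shape {y.shape}, expected ({hyper.n_dims},)")
    now = fs.t + 1

    prior = crp_prior(fs.counts, fs.prev_mode, hyper.alpha, hyper.beta)
    K = len(fs.modes)
    pred_means = np.empty((K + 1, hyper.n_dims))
    logliks = np.empty(K + 1)
    for k in range(K):
        pred_means[k], _ = predict_mode(fs.modes[k], now, hyper)
        logliks[k] = mode_loglik(fs.modes[k], y, now, hyper)
    pred_means[K] = hyper.m0
    logliks[K] = mode_loglik(None, y, now, hyper)

    if prediction == "mixture":
        predicted = prior @ pred_means
    elif prediction == "map":
        predicted = pred_means[int(np.argmax(prior))]
    else:
        raise ValueError(f"unknown prediction convention {prediction!r}")

    with np.errstate(divide="ignore"):  # alpha = 0 gives a -inf log prior
        log_post = np.log(prior) + logliks
    post = np.exp(log_post - logsumexp(log_post))
    post /= post.sum()
    z = int(np.argmax(post)) + 1  # ties: lowest label wins, existing before new

    new_state = update_mode(fs.modes[z - 1] if z <= K else None, y, now, hyper)
    if z <= K:
        fs.modes[z - 1] = new_state
    else:
        fs.modes.append(new_state)
    fs.prev_mode = z
    fs.t = now
    return predicted, pred_means[z - 1], post, z


def filter_step(
    fs: _FilterState, y: np.ndarray, prediction: str = "mixture"
):
    """Public single-step interface; see :func:`run_filter` for the fold."""
    return _step(fs, y, prediction)


def run_filter(
    observations: np.ndarray,
    hyper: Hyperparameters,
    prediction: str = "mixture",
) -> FilterTrace:
    """Fold the DP-KF over a T x D observation sequence.

    ``prediction`` selects the behavioral-prediction convention:
    ``"mixture"`` (CRP-prior-weighted mean over modes incl. the new-mode
    term at m0; the default) or ``"map"`` (predicted mean of the a-priori
    most probable mode).
    """
    obs = np.atleast_2d(np.asarray(observations, dtype=float))
    if obs.shape[0] == 0:
        raise ValueError("observation sequence is empty")
    if obs.shape[1] != hyper.n_dims:
        raise ValueError(f"observations have {obs.shape[1]} dims, hyper has {hyper.n_dims}")
    T, D = obs.shape
    fs = _FilterState(hyper)
    predicted = np.empty((T, D))
    assigned_pred = np.empty((T, D))
    probs: list[np.ndarray] = []
    assignments = np.empty(T, dtype=int)
    for t in range(T):
        predicted[t], assigned_pred[t], post, z = _step(fs, obs[t], prediction)
        probs.append(post)
        assignments[t] = z
    return FilterTrace(
        hyper=hyper,
        predicted_obs=predicted,
        assigned_pred=assigned_pred,
        prediction_error=obs - predicted,
        mode_probs=probs,
        assignments=assignments,
        modes=fs.modes,
        prediction=prediction,
    )
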