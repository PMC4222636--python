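"""Memory reconstruction by within-mode Kalman (RTS) smoothing.

Retrieval of a probed past stimulus re-examines the observations that
were assigned to the probed trial's mode — and only those — and refines
the trial's state estimate with information from later trials of the
same mode, via the Rauch-Tung-Striebel backward recursion.  Smoothing
never crosses mode boundaries: observations explained by other modes
cannot distort the reconstruction.

To model noise in the retrieval process, a constant (default 5) is
added to the sensory-noise variance for both the forward re-filtering
pass and the backward pass (``where="both"``); ``where="backward"``
keeps the original filtering pass and inflates only the backward
recursion's filtered inputs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .filter import FilterTrace, _diffusion_var, kalman_gain
from .params import Hyperparameters

__all__ = ["Reconstruction", "smooth_mode_chain", "reconstruct", "RETRIEVAL_NOISE"]

RETRIEVAL_NOISE = 5.0  # variance added to r at retrieval


@dataclass(frozen=True)
class Reconstruction:
    """Smoothed estimate of the stimulus at a probed trial."""

    probe_t: int
    estimate: np.ndarray
    mode: int
    chain: np.ndarray

    def __post_init__(self) -> None:
        if self.probe_t not in self.chain:
            raise ValueError("probe_t must belong to the probed mode's chain")
        if not np.all(np.isfinite(self.estimate)):
            raise ValueError("reconstruction estimate must be finite")

    def to_frame(self, participant=None, block=None) -> pd.DataFrame:
        row = {"participant": participant, "block": block, "probe_t": self.probe_t}
        for d, x in enumerate(self.estimate):
            row[f"estimate_dim{d + 1}"] = float(x)
        row["mode"] = self.mode
        row["chain_length"] = len(self.chain)
        return pd.DataFrame([row])


def _chain_filter(
    y: np.ndarray, gaps: np.ndarray, hyper: Hyperparameters, r: np.ndarray
):
    """Per-dimension Kalman filter along one mode's observation chain.

    ``gaps[i]`` is the trial gap between chain members i-1 and i (the
    first entry is ignored); dormant intervals accumulate diffusion.
    Returns filtered means/variances and the one-step predicted
    means/variances (L x D arrays).
    """
    L, D = y.shape
    lam = hyper.decay
    fm = np.empty((L, D))
    fv = np.empty((L, D))
    pm = np.empty((L, D))
    pv = np.empty((L, D))
    mean, var = hyper.m0.astype(float), np.full(D, hyper.c)
    for i in range(L):
        if i > 0:
            d = int(gaps[i])
            mean = lam**d * mean
            var = lam ** (2 * d) * var + _diffusion_var(hyper, d)
        pm[i], pv[i] = mean, var
        eta = kalman_gain(var, r)
        mean = mean + eta * (y[i] - mean)
        var = (1.0 - eta) * var
        fm[i], fv[i] = mean, var
    return fm, fv, pm, pv


def smooth_mode_chain(
    trace: FilterTrace,
    observations: np.ndarray,
    mode: int,
    hyper: Hyperparameters | None = None,
    extra_r: float = 0.0,
    where: str = "both",
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """RTS-smoothed estimates along one mode's chain, holding the
    partition fixed.

    Returns ``(chain, smoothed_means, smoothed_vars)`` where ``chain``
    holds the 1-based trial indices of the mode and the arrays are
    L x D.  ``extra_r >= 0`` inflates the sensory-noise variance
    (retrieval noise); with ``where="both"`` it applies to the forward
    re-filtering pass as well as the backward pass.
    """
    if extra_r < 0:
        raise ValueError("extra_r must be >= 0")
    hyper = trace.hyper if hyper is None else hyper
    chain = trace.chain(mode)
    obs = np.atleast_2d(np.asarray(observations, dtype=float))
    y = obs[chain - 1]
    gaps = np.diff(chain, prepend=chain[0])
    r_filter = hyper.r + (extra_r if where == "both" else 0.0)
    if where not in ("both", "backward"):
        raise ValueError("where must be 'both' or 'backward'")
    fm, fv, pm, pv = _chain_filter(y, gaps, hyper, r_filter)

    L, D = y.shape
    lam = hyper.decay
    sm = np.empty((L, D))
    sv = np.empty((L, D))
    sm[-1], sv[-1] = fm[-1], fv[-1]
    for i in range(L - 2, -1, -1):
        d = int(gaps[i + 1])
        lam_d = lam**d
        # predicted moments of the next chain member given time i
        pred_mean = lam_d * fm[i]
        pred_var = lam_d**2 * fv[i] + _diffusion_var(hyper, d)
        with np.errstate(invalid="ignore", divide="ignore"):
            J = np.where(pred_var > 0, lam_d * fv[i] / pred_var, 0.0)
        sm[i] = fm[i] + J * (sm[i + 1] - pred_mean)
        sv[i] = fv[i] + J**2 * (sv[i + 1] - pred_var)
    return chain, sm, sv


def reconstruct(
    trace: FilterTrace,
    observations: np.ndarray,
    probe_t: int,
    hyper: Hyperparameters | None = None,
    extra_r: float = RETRIEVAL_NOISE,
    where: str = "both",
) -> Reconstruction:
    """Model reconstruction of the stimulus shown at trial ``probe_t``.

    Identifies the probed trial's MAP mode and returns the within-mode
    smoothed estimate at the probe, with retrieval noise ``extra_r``
    added to the sensory variance.
    """
    T = len(trace.assignments)
    if not (1 <= probe_t <= T):
        raise ValueError(f"probe_t must be in 1..{T}")
    mode = int(trace.assignments[probe_t - 1])
    chain, sm, _ = smooth_mode_chain(trace, observations, mode, hyper, extra_r, where)
    pos = int(np.flatnonzero(chain == probe_t)[0])
    return Reconstruction(probe_t=probe_t, estimate=sm[pos], mode=mode, chain=chain)
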