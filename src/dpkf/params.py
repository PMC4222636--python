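"""Model hyperparameters and the four nested model variants.

The full model is a nonparametric switching linear-Gaussian state-space
model: at each trial a dynamical mode is drawn from a sticky Chinese
restaurant process (concentration ``alpha``, stickiness ``beta``); each
mode carries a per-dimension hidden state that diffuses as
``x <- decay * x + Normal(0, q)``; observations add sensory noise ``r``;
behavioral responses add response noise ``v``.  New modes draw their
state from ``Normal(m0, c)``.

Restricting ``alpha = 0`` removes mode switching (Kalman-filter
variants); restricting ``q = 0`` freezes each mode's state (stationary
variants).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import yaml

__all__ = ["Hyperparameters", "VariantSpec", "VARIANTS", "load_config", "save_config"]


def _as_vector(x, n_dims: int, name: str) -> np.ndarray:
    arr = np.atleast_1d(np.asarray(x, dtype=float))
    if arr.size == 1:
        arr = np.full(n_dims, float(arr[0]))
    if arr.shape != (n_dims,):
        raise ValueError(f"{name} must be a scalar or length-{n_dims} vector, got shape {arr.shape}")
    return arr


@dataclass(frozen=True)
class Hyperparameters:
    """Constants of the generative model and its inference algorithm.

    Parameters
    ----------
    alpha : float
        CRP concentration, >= 0.  ``alpha = 0`` forbids new modes, so
        exactly one mode is ever created.
    beta : float
        Stickiness bonus added to the previous trial's mode, >= 0.
    q : array-like
        Per-dimension diffusion variance (stimulus-units^2), >= 0.  Zero
        gives the stationary variants.
    r : array-like
        Per-dimension sensory-noise variance, > 0.
    v : array-like
        Per-dimension response-noise variance, > 0.
    decay : float
        State decay lambda in (0, 1]; 1 gives a pure random walk.
    m0 : array-like
        Per-dimension prior mean of a new mode's state.
    c : float
        Prior variance of a new mode's state; the default 1000 makes the
        prior approximately uniform over the [0, 100] stimulus space.
    n_dims : int
        Number of stimulus dimensions.
    """

    alpha: float = 1.0
    beta: float = 0.0
    q: np.ndarray = field(default=1.0)  # type: ignore[assignment]
    r: np.ndarray = field(default=1.0)  # type: ignore[assignment]
    v: np.ndarray = field(default=1.0)  # type: ignore[assignment]
    decay: float = 1.0
    m0: np.ndarray = field(default=50.0)  # type: ignore[assignment]
    c: float = 1000.0
    n_dims: int = 2

    def __post_init__(self) -> None:
        if self.n_dims < 1:
            raise ValueError("n_dims must be a positive integer")
        for name in ("q", "r", "v", "m0"):
            object.__setattr__(self, name, _as_vector(getattr(self, name), self.n_dims, name))
        if self.alpha < 0:
            raise ValueError("alpha must be >= 0")
        if self.beta < 0:
            raise ValueError("beta must be >= 0")
        if np.any(self.q < 0):
            raise ValueError("q must be >= 0 componentwise")
        if np.any(self.r <= 0):
            raise ValueError("r must be > 0 componentwise")
        if np.any(self.v <= 0):
            raise ValueError("v must be > 0 componentwise")
        if not (0.0 < self.decay <= 1.0):
            raise ValueError("decay must lie in (0, 1]")
        if self.c <= 0:
            raise ValueError("c must be > 0")

    def replace(self, **changes) -> "Hyperparameters":
        return replace(self, **changes)

    def to_dict(self) -> dict:
        return {
            "alpha": float(self.alpha),
            "beta": float(self.beta),
            "q": [float(x) for x in self.q],
            "r": [float(x) for x in self.r],
            "v": [float(x) for x in self.v],
            "decay": float(self.decay),
            "m0": [float(x) for x in self.m0],
            "c": float(self.c),
            "n_dims": int(self.n_dims),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Hyperparameters":
        known = {k: d[k] for k in ("alpha", "beta", "q", "r", "v", "decay", "m0", "c", "n_dims") if k in d}
        return cls(**known)


@dataclass(frozen=True)
class VariantSpec:
    """One of the four nested model variants.

    ``stationary_kf`` (5 free parameters: v1, v2, r1, r2, decay),
    ``kf`` (7: + q1, q2), ``stationary_dpkf`` (7: + alpha, beta) and
    ``dpkf`` (9: all).  Stationary variants fix q = 0; KF variants fix
    alpha = 0 (a single mode is ever created).
    """

    name: str
    free: tuple  # parameter names the optimizer sees (besides profiled v)
    fix_alpha: bool
    fix_q: bool

    @property
    def n_free(self) -> int:
        # v1, v2 are always free (profiled analytically); decay is free.
        return 2 + len(self.free)

    def restrict(self, hyper: Hyperparameters) -> Hyperparameters:
        """Apply the variant's parameter restrictions."""
        changes = {}
        if self.fix_alpha:
            changes["alpha"] = 0.0
            changes["beta"] = 0.0
        if self.fix_q:
            changes["q"] = np.zeros(hyper.n_dims)
        return hyper.replace(**changes) if changes else hyper


VARIANTS: dict[str, VariantSpec] = {
    "stationary_kf": VariantSpec("stationary_kf", ("r1", "r2", "decay"), fix_alpha=True, fix_q=True),
    "kf": VariantSpec("kf", ("r1", "r2", "decay", "q1", "q2"), fix_alpha=True, fix_q=False),
    "stationary_dpkf": VariantSpec(
        "stationary_dpkf", ("r1", "r2", "decay", "alpha", "beta"), fix_alpha=False, fix_q=True
    ),
    "dpkf": VariantSpec(
        "dpkf", ("r1", "r2", "decay", "q1", "q2", "alpha", "beta"), fix_alpha=False, fix_q=False
    ),
}


def load_config(path: str | Path) -> Hyperparameters:
    """Read hyperparameters from a flat key-value YAML file."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise ValueError(f"config file {path} must hold a mapping")
    return Hyperparameters.from_dict(data)


def save_config(hyper: Hyperparameters, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(hyper.to_dict(), fh, sort_keys=False)
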