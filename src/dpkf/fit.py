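"""Maximum-likelihood fitting of the four model variants.

Participants' prediction-trial responses are modeled as the filter's
trial-wise prediction corrupted by anisotropic Gaussian response noise
``Normal(0, v_d)``.  Each variant's free parameters are estimated by
minimizing the negative log-likelihood over prediction trials, under
box constraints (v <= 10, q <= 30, r <= 20, following the response
ranges of the rescaled [0, 100] stimulus space), with a bounded Powell
search restarted from 3 random interior points.  Reconstruction trials
are never used in fitting; they serve as held-out validation, as does
an even/odd block split.

The response-noise variances do not influence the filter's predictions,
so they are profiled out analytically: at any setting of the remaining
parameters the optimal ``v_d`` is the clipped mean squared prediction
residual.  The optimizer therefore searches only over the dynamical
parameters (r, decay, and per variant q, alpha, beta).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from . import _fast
from .filter import run_filter
from .params import Hyperparameters, VariantSpec, VARIANTS
from .smoother import RETRIEVAL_NOISE, reconstruct
from .task import ResponseSet, Session

__all__ = [
    "FitResult",
    "BOUNDS",
    "response_nll",
    "fit_participant",
    "crossval_predictive_ll",
    "reconstruction_ll",
]

_LOG2PI = math.log(2.0 * math.pi)

#: box constraints per parameter (lower, upper)
BOUNDS: dict[str, tuple[float, float]] = {
    "v": (1e-3, 10.0),
    "q": (0.0, 30.0),
    "r": (1e-3, 20.0),
    "alpha": (0.0, 10.0),
    "beta": (0.0, 20.0),
    "decay": (0.25, 1.0),
}


@dataclass
class FitResult:
    participant_id: str
    variant: str
    hyper: Hyperparameters
    train_nll: float
    restart_nlls: list = field(default_factory=list)
    predictive_ll_heldout: float | None = None
    reconstruction_ll: float | None = None
    K_by_condition: dict | None = None

    def to_dict(self) -> dict:
        return {
            "participant_id": self.participant_id,
            "variant": self.variant,
            "hyper": self.hyper.to_dict(),
            "train_nll": float(self.train_nll),
            "restart_nlls": [float(x) for x in self.restart_nlls],
            "predictive_ll_heldout": self.predictive_ll_heldout,
            "reconstruction_ll": self.reconstruction_ll,
            "K_by_condition": self.K_by_condition,
        }


class FitError(RuntimeError):
    """All restarts failed; carries the underlying diagnostics."""


def _stack(session: Session, responses: ResponseSet, blocks=None):
    idx = range(len(session.blocks)) if blocks is None else list(blocks)
    stims = np.stack([session.blocks[i].stimuli for i in idx])
    resps = np.stack([responses.predictions[i] for i in idx])
    return np.ascontiguousarray(stims), np.ascontiguousarray(resps)


def _gaussian_nll(resid: np.ndarray, v: np.ndarray) -> float:
    n = resid.shape[0]
    return float(np.sum(0.5 * n * (_LOG2PI + np.log(v)) + np.sum(resid**2, axis=0) / (2 * v)))


def response_nll(
    responses: ResponseSet,
    session: Session,
    hyper: Hyperparameters,
    include_trial1: bool = True,
    blocks=None,
    prediction: str = "mixture",
) -> float:
    """Negative log-likelihood of prediction-trial responses.

    Reference (numpy) implementation; deterministic.  ``blocks`` selects
    a subset of 0-based block indices (default: all); ``include_trial1``
    keeps the first trial of each block, which is scored against the
    prior mixture mean (= m0).
    """
    idx = list(range(len(session.blocks))) if blocks is None else list(blocks)
    if not idx:
        raise ValueError("empty block subset")
    start = 0 if include_trial1 else 1
    resids = []
    for i in idx:
        trace = run_filter(session.blocks[i].stimuli, hyper, prediction=prediction)
        resids.append(responses.predictions[i][start:] - trace.predicted_obs[start:])
    resid = np.concatenate(resids, axis=0)
    return _gaussian_nll(resid, hyper.v)


def _fast_nll_factory(
    stims: np.ndarray,
    resps: np.ndarray,
    variant: VariantSpec,
    include_trial1: bool,
    prediction: str,
    fit_decay: bool,
    m0: np.ndarray,
    c: float,
):
    """Objective over the optimizer's parameter vector, with v profiled."""
    start = 0 if include_trial1 else 1
    pred_code = _fast.PRED_MIXTURE if prediction == "mixture" else _fast.PRED_MAP
    names = _theta_names(variant, fit_decay)
    n_included = stims.shape[0] * (stims.shape[1] - start)

    def unpack(theta: np.ndarray) -> dict:
        p = dict(zip(names, theta))
        return {
            "alpha": 0.0 if variant.fix_alpha else p["alpha"],
            "beta": 0.0 if variant.fix_alpha else p["beta"],
            "q": np.zeros(2) if variant.fix_q else np.array([p["q1"], p["q2"]]),
            "r": np.array([p["r1"], p["r2"]]),
            "decay": p.get("decay", 1.0),
        }

    def profiled_v(theta: np.ndarray):
        p = unpack(theta)
        preds, _, _ = _fast.session_predictions(
            stims, p["alpha"], p["beta"], p["q"], p["r"], p["decay"], m0, c, pred_code
        )
        resid = (resps[:, start:, :] - preds[:, start:, :]).reshape(-1, stims.shape[2])
        v = np.clip(resid.var(axis=0) + resid.mean(axis=0) ** 2, *BOUNDS["v"])
        nll = _gaussian_nll(resid, v)
        return nll, v, p

    def objective(theta: np.ndarray) -> float:
        return profiled_v(theta)[0]

    objective.profiled_v = profiled_v  # type: ignore[attr-defined]
    objective.n_included = n_included  # type: ignore[attr-defined]
    return objective


def _theta_names(variant: VariantSpec, fit_decay: bool) -> list[str]:
    names = ["r1", "r2"]
    if fit_decay:
        names.append("decay")
    if not variant.fix_q:
        names += ["q1", "q2"]
    if not variant.fix_alpha:
        names += ["alpha", "beta"]
    return names


def _theta_bounds(names: list[str]) -> list[tuple[float, float]]:
    return [BOUNDS[n.rstrip("12")] for n in names]


def _hyper_to_theta(hyper: Hyperparameters, names: list[str]) -> np.ndarray:
    values = {
        "r1": hyper.r[0], "r2": hyper.r[1], "decay": hyper.decay,
        "q1": hyper.q[0], "q2": hyper.q[1], "alpha": hyper.alpha, "beta": hyper.beta,
    }
    theta = np.array([values[n] for n in names])
    lo, hi = np.array(_theta_bounds(names)).T
    return np.clip(theta, lo, hi)


def fit_participant(
    responses: ResponseSet,
    session: Session,
    variant: str | VariantSpec,
    rng: np.random.Generator,
    n_restarts: int = 3,
    include_trial1: bool = True,
    prediction: str = "mixture",
    fit_decay: bool = True,
    blocks=None,
    compute_k: bool = True,
    extra_starts: tuple = (),
) -> FitResult:
    """Fit one variant to one participant's prediction trials.

    The optimization is run from ``n_restarts`` starting points drawn
    uniformly inside the box; the best restart is returned.  ``m0`` is
    fixed at the stimulus-space center (50, 50) and the new-mode prior
    variance at c = 1000.

    ``extra_starts`` may hold already-fitted :class:`Hyperparameters`
    (typically from a nested, more restricted variant) used as
    additional warm starts, which guards the nested-likelihood
    inequality against local minima.
    """
    spec = VARIANTS[variant] if isinstance(variant, str) else variant
    stims, resps = _stack(session, responses, blocks)
    m0 = np.full(2, 50.0)
    c = 1000.0
    obj = _fast_nll_factory(stims, resps, spec, include_trial1, prediction, fit_decay, m0, c)
    names = _theta_names(spec, fit_decay)
    bounds = _theta_bounds(names)

    starts = [
        np.array([rng.uniform(lo + 0.02 * (hi - lo), hi - 0.02 * (hi - lo)) for lo, hi in bounds])
        for _ in range(n_restarts)
    ]
    starts += [_hyper_to_theta(h, names) for h in extra_starts]

    best = None
    restart_nlls = []
    failures = []
    for x0 in starts:
        try:
            res = minimize(
                obj,
                x0,
                method="Powell",
                bounds=bounds,
                options={"xtol": 1e-6, "ftol": 1e-6, "maxfev": 20000},
            )
        except Exception as exc:  # pragma: no cover - optimizer failure path
            failures.append(repr(exc))
            continue
        restart_nlls.append(float(res.fun))
        if best is None or res.fun < best.fun:
            best = res
    if best is None:
        raise FitError(f"all {len(starts)} restarts failed: {failures}")

    nll, v, p = obj.profiled_v(best.x)
    hyper = Hyperparameters(
        alpha=p["alpha"], beta=p["beta"], q=p["q"], r=p["r"], v=v,
        decay=p["decay"], m0=m0, c=c, n_dims=2,
    )
    result = FitResult(
        participant_id=session.participant_id,
        variant=spec.name,
        hyper=hyper,
        train_nll=float(min(restart_nlls)),
        restart_nlls=restart_nlls,
    )
    if compute_k:
        result.K_by_condition = inferred_mode_counts(session, hyper, prediction)
    return result


def inferred_mode_counts(
    session: Session, hyper: Hyperparameters, prediction: str = "mixture"
) -> dict:
    """Mean number of modes the filter instantiates per condition."""
    ks: dict[str, list[int]] = {"gradual": [], "jump": []}
    for block in session.blocks:
        trace = run_filter(block.stimuli, hyper, prediction=prediction)
        ks[block.condition].append(trace.n_modes)
    return {cond: float(np.mean(v)) for cond, v in ks.items() if v}


def crossval_predictive_ll(
    responses: ResponseSet,
    session: Session,
    variant: str | VariantSpec,
    rng: np.random.Generator,
    **fit_kwargs,
) -> dict:
    """Even/odd block cross-validation of prediction-trial likelihood.

    Fits on odd-numbered blocks (1-based) and evaluates the held-out
    log-likelihood on even-numbered blocks, and vice versa; returns both
    folds and their sum.  Reconstruction trials are never touched.
    """
    n = len(session.blocks)
    odd = [i for i in range(n) if (i + 1) % 2 == 1]
    even = [i for i in range(n) if (i + 1) % 2 == 0]
    out: dict = {}
    total = 0.0
    for train, test, name in ((odd, even, "fit_odd"), (even, odd, "fit_even")):
        fr = fit_participant(
            responses, session, variant, rng, blocks=train, compute_k=False, **fit_kwargs
        )
        ll = -response_nll(responses, session, fr.hyper, blocks=test)
        out[name] = {"train_nll": fr.train_nll, "heldout_ll": ll}
        total += ll
    out["total_heldout_ll"] = total
    return out


def reconstruction_ll(
    responses: ResponseSet,
    session: Session,
    hyper: Hyperparameters,
    extra_r: float = RETRIEVAL_NOISE,
    prediction: str = "mixture",
) -> float:
    """Log-likelihood of the reconstruction responses under a fitted model.

    The model's reconstruction is the within-mode smoothed estimate at
    the probe (retrieval noise added to the sensory variance); the
    response likelihood uses the fitted response-noise variances.  The
    model is never fit to these trials.
    """
    ll = 0.0
    for i, block in enumerate(session.blocks):
        trace = run_filter(block.stimuli, hyper, prediction=prediction)
        rec = reconstruct(trace, block.stimuli, block.probe_t, extra_r=extra_r)
        resid = responses.reconstructions[i] - rec.estimate
        ll += float(np.sum(-0.5 * (_LOG2PI + np.log(hyper.v) + resid**2 / hyper.v)))
    return ll
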