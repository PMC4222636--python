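"""Behavioral task: stimulus trajectories, sessions and synthetic agents.

The task presents sequences of line segments that drift through a 2-D
(orientation, length) space standardized to [0, 100] per dimension.
Every transition moves one fixed step per dimension at a 45-degree angle
(random sign per dimension); in jump blocks a single 4x-magnitude step
is inserted between trials 9 and 10.  Trajectories never exactly
backtrack, and the start-to-end Euclidean distance is constrained to
60-70% of the space's diagonal in both conditions.

A session holds 12 blocks (6 gradual, 6 jump, randomly interleaved),
each with 18 prediction trials and one reconstruction probe drawn from
the block's first three trials.

Synthetic participants respond with the model's trial-wise prediction
(and its smoothed reconstruction at the probe), corrupted by anisotropic
Gaussian response noise — the response model used for fitting.

Trajectory sampling is constructive rather than naive-rejection: the
distance band constrains the per-dimension net step counts so tightly
(13-17 of 17 steps must share a sign) that blind resampling is
impractical.  The sampler enumerates the admissible net-displacement
pairs once, draws one, shuffles the step order, re-shuffles on a
backtracking violation, and places the starting point uniformly in the
interval that keeps the whole path inside the space (the path span
never exceeds the space, so a feasible start always exists).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd

from .filter import run_filter
from .params import Hyperparameters
from .smoother import RETRIEVAL_NOISE, reconstruct

__all__ = [
    "TaskGeometry",
    "Block",
    "Session",
    "ResponseSet",
    "generate_block",
    "build_session",
    "simulate_responses",
    "session_to_frame",
    "responses_to_frame",
    "frame_to_sessions",
    "DEFAULT_AGENT",
]

DIM_NAMES = ("angle", "length")


@dataclass(frozen=True)
class TaskGeometry:
    """Geometry knobs of the trajectory generator."""

    step: float = 5.0
    jump_mult: int = 4
    n_trials: int = 18
    jump_after: int = 9  # jump inserted between this trial and the next
    dist_band: tuple[float, float] = (0.60, 0.70)
    extent: float = 100.0
    max_tries: int = 500

    @property
    def n_steps(self) -> int:
        return self.n_trials - 1


class GenerationError(RuntimeError):
    """Raised when the configured geometry admits no valid trajectory."""


@dataclass(frozen=True)
class Block:
    condition: str  # "gradual" | "jump"
    stimuli: np.ndarray  # n_trials x 2, [0, extent] per dimension
    jump_after: int | None
    probe_t: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "stimuli", np.asarray(self.stimuli, dtype=float))


@dataclass(frozen=True)
class Session:
    participant_id: str
    blocks: tuple
    seed: int | None = None


@dataclass
class ResponseSet:
    """Trial-wise predictions and one reconstruction per block."""

    predictions: list  # per block: n_trials x 2
    reconstructions: list  # per block: length-2 vector
    generator: str = "synthetic"
    hyper_true: Hyperparameters | None = None


@lru_cache(maxsize=None)
def _admissible_nets(geom: TaskGeometry, condition: str) -> tuple:
    """Signed per-dimension net displacements (in step units) compatible
    with the start-to-end distance band.

    Gradual blocks take ``n_steps`` unit steps per dimension; jump blocks
    take ``n_steps - 1`` unit steps plus one ``jump_mult`` step, so each
    entry also records the jump's sign per dimension.
    """
    diag = geom.extent * np.sqrt(2.0)
    lo = geom.dist_band[0] * diag / geom.step
    hi = geom.dist_band[1] * diag / geom.step
    eps = 1e-9
    out = []
    if condition == "gradual":
        n = geom.n_steps
        for a in range(-n, n + 1):
            for b in range(-n, n + 1):
                if (a + n) % 2 or (b + n) % 2:
                    continue  # parity: net of n unit steps
                if lo - eps <= np.hypot(a, b) <= hi + eps:
                    out.append((a, b, 0, 0))
    elif condition == "jump":
        n = geom.n_steps - 1
        m = geom.jump_mult
        for t1 in range(-(n + m), n + m + 1):
            for t2 in range(-(n + m), n + m + 1):
                if not (lo - eps <= np.hypot(t1, t2) <= hi + eps):
                    continue
                for j1 in (1, -1):
                    for j2 in (1, -1):
                        a, b = t1 - m * j1, t2 - m * j2
                        if abs(a) <= n and abs(b) <= n and (a + n) % 2 == 0 and (b + n) % 2 == 0:
                            out.append((a, b, j1, j2))
    else:
        raise ValueError(f"unknown condition {condition!r}")
    if not out:
        raise GenerationError(
            f"no trajectory with step={geom.step} can satisfy the "
            f"{geom.dist_band} distance band for condition {condition!r}"
        )
    return tuple(out)


def _sign_sequence(n: int, net: int, rng: np.random.Generator) -> np.ndarray:
    """Random ordering of n unit steps with the given net sum."""
    n_plus = (n + net) // 2
    seq = np.concatenate([np.ones(n_plus), -np.ones(n - n_plus)])
    return rng.permutation(seq)


def generate_block(
    condition: str,
    rng: np.random.Generator,
    geom: TaskGeometry = TaskGeometry(),
    probe_t: int | None = None,
) -> Block:
    """Sample one stimulus trajectory satisfying every task constraint."""
    nets = _admissible_nets(geom, condition)
    jump_idx = geom.jump_after - 1  # 0-based index into the step list
    for _ in range(geom.max_tries):
        a, b, j1, j2 = nets[rng.integers(len(nets))]
        steps = np.empty((geom.n_steps, 2))
        if condition == "gradual":
            steps[:, 0] = _sign_sequence(geom.n_steps, a, rng)
            steps[:, 1] = _sign_sequence(geom.n_steps, b, rng)
        else:
            normal = np.delete(np.arange(geom.n_steps), jump_idx)
            steps[normal, 0] = _sign_sequence(geom.n_steps - 1, a, rng)
            steps[normal, 1] = _sign_sequence(geom.n_steps - 1, b, rng)
            steps[jump_idx] = (geom.jump_mult * j1, geom.jump_mult * j2)
        if np.any(np.all(steps[1:] == -steps[:-1], axis=1)):
            continue  # exact reversal of the previous move: re-shuffle
        rel = np.vstack([np.zeros(2), np.cumsum(steps * geom.step, axis=0)])
        lo = -rel.min(axis=0)
        hi = geom.extent - rel.max(axis=0)
        if np.any(hi < lo):  # cannot happen with default geometry; guard anyway
            continue
        start = rng.uniform(lo, hi)
        stimuli = start + rel
        probe = int(probe_t) if probe_t is not None else int(rng.integers(1, 4))
        return Block(
            condition=condition,
            stimuli=stimuli,
            jump_after=geom.jump_after if condition == "jump" else None,
            probe_t=probe,
        )
    raise GenerationError(
        f"failed to build a valid {condition!r} trajectory in {geom.max_tries} tries "
        f"(geometry: {geom})"
    )


def build_session(
    participant_id: str,
    rng: np.random.Generator,
    geom: TaskGeometry = TaskGeometry(),
    n_blocks_per_condition: int = 6,
) -> Session:
    """12 blocks, 6 per condition, randomly interleaved; probe trial
    uniform over the block's first three trials."""
    conditions = ["gradual"] * n_blocks_per_condition + ["jump"] * n_blocks_per_condition
    order = rng.permutation(len(conditions))
    blocks = tuple(generate_block(conditions[i], rng, geom) for i in order)
    return Session(participant_id=participant_id, blocks=blocks)


DEFAULT_AGENT = Hyperparameters(
    alpha=0.05,
    beta=15.0,
    q=2.0,
    r=18.0,
    v=4.0,
    decay=1.0,
    m0=50.0,
    c=1000.0,
    n_dims=2,
)
"""Generating parameters of the synthetic cohort.

Chosen so that the agent sits in the regime the model is about: gradual
blocks are mostly explained by a single mode (small concentration and
strong stickiness keep the tracking lag of the per-trial drift below
the new-mode threshold), the 4x jump reliably opens a second mode, and
within-mode smoothing (sensory noise large relative to diffusion)
reaches far enough backward for late trials to distort the memory of
early ones.  See the methods note for the calibration.
"""


def simulate_responses(
    session: Session,
    hyper_true: Hyperparameters,
    rng: np.random.Generator,
    prediction: str = "mixture",
    extra_r: float = RETRIEVAL_NOISE,
) -> ResponseSet:
    """Simulate a participant that responds with the model's posterior
    predictions corrupted by anisotropic Gaussian noise."""
    sd = np.sqrt(hyper_true.v)
    preds, recons = [], []
    for block in session.blocks:
        trace = run_filter(block.stimuli, hyper_true, prediction=prediction)
        noise = rng.normal(0.0, 1.0, size=trace.predicted_obs.shape) * sd
        preds.append(trace.predicted_obs + noise)
        rec = reconstruct(trace, block.stimuli, block.probe_t, extra_r=extra_r)
        recons.append(rec.estimate + rng.normal(0.0, 1.0, size=2) * sd)
    return ResponseSet(predictions=preds, reconstructions=recons, hyper_true=hyper_true)


def session_to_frame(session: Session, responses: ResponseSet | None = None) -> pd.DataFrame:
    """Tidy long table of a session (and optionally its responses)."""
    rows = []
    for b, block in enumerate(session.blocks, start=1):
        for t in range(1, block.stimuli.shape[0] + 1):
            row = {
                "participant": session.participant_id,
                "block": b,
                "condition": block.condition,
                "trial": t,
                "trial_type": "prediction",
                "probe_t": block.probe_t,
            }
            for d, name in enumerate(DIM_NAMES):
                row[f"stim_{name}"] = block.stimuli[t - 1, d]
                row[f"resp_{name}"] = (
                    responses.predictions[b - 1][t - 1, d] if responses is not None else np.nan
                )
            rows.append(row)
        row = {
            "participant": session.participant_id,
            "block": b,
            "condition": block.condition,
            "trial": block.probe_t,
            "trial_type": "reconstruction",
            "probe_t": block.probe_t,
        }
        for d, name in enumerate(DIM_NAMES):
            row[f"stim_{name}"] = block.stimuli[block.probe_t - 1, d]
            row[f"resp_{name}"] = (
                responses.reconstructions[b - 1][d] if responses is not None else np.nan
            )
        rows.append(row)
    return pd.DataFrame(rows)


def responses_to_frame(sessions: list, response_sets: list) -> pd.DataFrame:
    return pd.concat(
        [session_to_frame(s, r) for s, r in zip(sessions, response_sets)],
        ignore_index=True,
    )


def frame_to_sessions(df: pd.DataFrame) -> tuple[list, list]:
    """Invert :func:`responses_to_frame` (lossless round trip)."""
    sessions, response_sets = [], []
    for pid, pdf in df.groupby("participant", sort=False):
        blocks, preds, recons = [], [], []
        for _, bdf in pdf.groupby("block", sort=True):
            pred_rows = bdf[bdf.trial_type == "prediction"].sort_values("trial")
            stim = pred_rows[[f"stim_{n}" for n in DIM_NAMES]].to_numpy()
            condition = bdf.condition.iloc[0]
            probe_t = int(bdf.probe_t.iloc[0])
            geom_jump = TaskGeometry().jump_after if condition == "jump" else None
            blocks.append(Block(condition, stim, geom_jump, probe_t))
            preds.append(pred_rows[[f"resp_{n}" for n in DIM_NAMES]].to_numpy())
            rec_rows = bdf[bdf.trial_type == "reconstruction"]
            recons.append(rec_rows[[f"resp_{n}" for n in DIM_NAMES]].to_numpy()[0])
        sessions.append(Session(participant_id=pid, blocks=tuple(blocks)))
        response_sets.append(ResponseSet(predictions=preds, reconstructions=recons))
    return sessions, response_sets
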