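"""Behavioral and model-based analyses.

Implements the reconstruction-distance analysis (distance of each
block's reconstruction to the block's first and last stimulus, with the
2x2 repeated-measures interaction test that diagnoses retroactive
interference), inferred-mode-count comparisons, model-vs-observed
reconstruction correlations, and the two demonstration simulations:
the jump catch-up comparison of the DP-KF against a plain Kalman
filter, and the gradual/mixed morph protocols.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.anova import AnovaRM

from .filter import run_filter
from .generative import morph_sequence
from .params import Hyperparameters

__all__ = [
    "DistanceSummary",
    "distance_analysis",
    "mode_count_analysis",
    "model_human_correlation",
    "JumpDemoConfig",
    "MorphDemoConfig",
    "demo_fig1",
]

Z_CAP = 18.0  # atanh overflow guard for |r| -> 1


@dataclass
class DistanceSummary:
    """Per-block distances and the 2x2 (first/last x gradual/jump)
    repeated-measures ANOVA of their subject-level means."""

    per_block: pd.DataFrame
    cell_means: pd.DataFrame  # distance_type x condition means + within-subject SEM
    interaction_F: float
    interaction_p: float

    @property
    def crossover(self) -> dict:
        m = self.cell_means.set_index(["distance_type", "condition"])["mean"]
        return {
            "d_first_jump_minus_gradual": m[("first", "jump")] - m[("first", "gradual")],
            "d_last_gradual_minus_jump": m[("last", "gradual")] - m[("last", "jump")],
        }


def _within_subject_sem(cells: pd.DataFrame) -> pd.Series:
    """Loftus-Masson style SEM: remove each subject's mean before
    computing cell SEMs, with the Morey small-cell correction."""
    wide = cells.pivot_table(index="participant", columns=["distance_type", "condition"], values="value")
    n, n_cells = wide.shape
    normalized = wide.sub(wide.mean(axis=1), axis=0) + wide.to_numpy().mean()
    correction = np.sqrt(n_cells / (n_cells - 1))
    return normalized.std(axis=0, ddof=1) / np.sqrt(n) * correction


def distance_analysis(sessions: list, response_sets: list) -> DistanceSummary:
    """Euclidean distances of each reconstruction to the block's first
    and last stimulus, and the condition-by-probe-type interaction.

    A crossover — reconstructions closer to the first stimulus in jump
    blocks but closer to the last stimulus in gradual blocks — is the
    signature of mode-protected memory.
    """
    if len(sessions) < 2:
        raise ValueError("need >= 2 participants for the repeated-measures test")
    rows = []
    for sess, resp in zip(sessions, response_sets):
        for i, block in enumerate(sess.blocks):
            rec = np.asarray(resp.reconstructions[i], dtype=float)
            rows.append(
                {
                    "participant": sess.participant_id,
                    "block": i + 1,
                    "condition": block.condition,
                    "probe_t": block.probe_t,
                    "d_first": float(np.linalg.norm(rec - block.stimuli[0])),
                    "d_last": float(np.linalg.norm(rec - block.stimuli[-1])),
                }
            )
    per_block = pd.DataFrame(rows)

    cells = per_block.melt(
        id_vars=["participant", "condition"],
        value_vars=["d_first", "d_last"],
        var_name="distance_type",
    )
    cells["distance_type"] = cells["distance_type"].str.removeprefix("d_")
    cell_data = (
        cells.groupby(["participant", "distance_type", "condition"], as_index=False)["value"].mean()
    )
    if cell_data.groupby("participant").size().min() < 4:
        raise ValueError("every participant needs all four condition x probe-type cells")

    table = AnovaRM(
        cell_data, depvar="value", subject="participant", within=["distance_type", "condition"]
    ).fit().anova_table
    inter = table.loc["distance_type:condition"]

    sems = _within_subject_sem(cell_data)
    cell_means = (
        cell_data.groupby(["distance_type", "condition"], as_index=False)["value"]
        .mean()
        .rename(columns={"value": "mean"})
    )
    cell_means["within_subject_sem"] = [
        sems[(dt, c)] for dt, c in zip(cell_means["distance_type"], cell_means["condition"])
    ]
    return DistanceSummary(
        per_block=per_block,
        cell_means=cell_means,
        interaction_F=float(inter["F Value"]),
        interaction_p=float(inter["Pr > F"]),
    )


def mode_count_analysis(
    sessions: list,
    hypers: list | Hyperparameters,
    prediction: str = "mixture",
) -> dict:
    """Mean inferred mode count K per condition and a paired comparison.

    ``hypers`` is one Hyperparameters per participant (e.g. each
    participant's fitted DP-KF), or a single set shared by all.
    """
    if isinstance(hypers, Hyperparameters):
        hypers = [hypers] * len(sessions)
    rows = []
    for sess, hp in zip(sessions, hypers):
        ks: dict = {"gradual": [], "jump": []}
        for block in sess.blocks:
            ks[block.condition].append(run_filter(block.stimuli, hp, prediction=prediction).n_modes)
        rows.append(
            {
                "participant": sess.participant_id,
                "K_gradual": float(np.mean(ks["gradual"])),
                "K_jump": float(np.mean(ks["jump"])),
            }
        )
    df = pd.DataFrame(rows)
    diff = df["K_jump"] - df["K_gradual"]
    if np.allclose(diff, 0):
        t, p = 0.0, 1.0
    else:
        t, p = stats.ttest_rel(df["K_jump"], df["K_gradual"])
    return {
        "per_participant": df,
        "mean_K_gradual": float(df["K_gradual"].mean()),
        "mean_K_jump": float(df["K_jump"].mean()),
        "t": float(t),
        "p": float(p),
    }


def model_human_correlation(model_recons: list, observed_recons: list) -> dict:
    """Per-participant Pearson correlation between model and observed
    reconstructions, Fisher z-transformed, with a group test against 0.

    Inputs are per-participant arrays of shape (n_blocks, n_dims);
    participants need >= 3 blocks.  Perfect correlations are capped at
    |z| = 18 and flagged.
    """
    rows = []
    for i, (m, o) in enumerate(zip(model_recons, observed_recons)):
        m = np.asarray(m, float)
        o = np.asarray(o, float)
        if m.shape[0] < 3:
            raise ValueError("need >= 3 blocks per participant")
        for d in range(m.shape[1]):
            if np.std(m[:, d]) == 0 or np.std(o[:, d]) == 0:
                raise ValueError(f"zero-variance input for participant {i}, dim {d}")
            r, _ = stats.pearsonr(m[:, d], o[:, d])
            with np.errstate(divide="ignore"):
                raw_z = np.arctanh(r)  # +-inf at |r| = 1
            rows.append(
                {
                    "participant": i,
                    "dim": d,
                    "r": float(r),
                    "z": float(np.clip(raw_z, -Z_CAP, Z_CAP)),
                    "capped": bool(abs(raw_z) > Z_CAP),
                }
            )
    df = pd.DataFrame(rows)
    group = {}
    for d, ddf in df.groupby("dim"):
        t, p = stats.ttest_1samp(ddf["z"], 0.0)
        group[int(d)] = {"mean_z": float(ddf["z"].mean()), "t": float(t), "p": float(p)}
    return {"per_participant": df, "group": group}


# --------------------------------------------------------------------------
# demonstration simulations


@dataclass(frozen=True)
class JumpDemoConfig:
    """1-D ramp-with-jump comparison of DP-KF vs. plain KF.

    The stimulus climbs by ``step`` per trial and jumps by ``jump``
    between trials ``jump_after`` and ``jump_after + 1``.  ``q`` is set
    so the ramp's steady one-step tracking lag (step/eta) stays below
    the new-mode threshold, keeping the pre-jump phase in one mode.
    Predictions are read out under the "assigned" convention (the
    predicted mean of the trial's MAP-assigned mode, the quantity
    plotted when inferred states are colored by assignment).
    """

    n_trials: int = 30
    jump_after: int = 15
    step: float = 0.5
    jump: float = 8.0
    alpha: float = 1.0
    beta: float = 0.0
    q: float = 0.2
    r: float = 1.0
    m0: float = 0.0
    c: float = 1000.0
    n_runs: int = 100


@dataclass(frozen=True)
class MorphDemoConfig:
    """Gradual vs. mixed morph protocols on the [0, 1] continuum.

    Noise scales are set for the unit interval (the jump-demo scales
    would swamp the morph spacing).  The reported posterior curve is the
    probability of the low-anchor mode: the mode MAP-assigned to morph
    index 0, which in the gradual protocol is simply the first mode.
    """

    n_morphs: int = 20
    alpha: float = 1.0
    beta: float = 0.0
    q: float = 0.002
    r: float = 0.005
    m0: float = 0.5
    c: float = 1000.0
    n_runs: int = 100


def _jump_demo_sequence(cfg: JumpDemoConfig, rng: np.random.Generator) -> np.ndarray:
    truth = cfg.step * np.arange(cfg.n_trials, dtype=float)
    truth[cfg.jump_after:] += cfg.jump
    return truth + rng.normal(0.0, np.sqrt(cfg.r), size=cfg.n_trials)


def _catch_up_lag(err: np.ndarray, jump_after: int) -> int:
    """Trials after the first post-jump observation until the one-step
    absolute prediction error falls back below the pre-jump median."""
    med = np.median(err[1:jump_after])  # trials 2..jump_after (trial 1 is the prior)
    post = err[jump_after + 1:]  # trials jump_after+2 onward
    below = np.flatnonzero(post < med)
    return int(below[0]) + 1 if below.size else len(post) + 1


def demo_fig1(
    seed: int,
    jump_cfg: JumpDemoConfig = JumpDemoConfig(),
    morph_cfg: MorphDemoConfig = MorphDemoConfig(),
) -> dict:
    """Run both demonstration simulations; returns summary metrics and
    the averaged per-trial curves."""
    rng = np.random.default_rng(seed)

    # --- panel A: jump catch-up -------------------------------------
    base = dict(q=jump_cfg.q, r=jump_cfg.r, v=1.0, m0=jump_cfg.m0, c=jump_cfg.c, n_dims=1)
    hp_dpkf = Hyperparameters(alpha=jump_cfg.alpha, beta=jump_cfg.beta, **base)
    hp_kf = Hyperparameters(alpha=0.0, beta=0.0, **base)
    lags = {"dpkf": [], "kf": []}
    err_curves = {"dpkf": [], "kf": []}
    for _ in range(jump_cfg.n_runs):
        y = _jump_demo_sequence(jump_cfg, rng)[:, None]
        for name, hp in (("dpkf", hp_dpkf), ("kf", hp_kf)):
            trace = run_filter(y, hp)
            err = np.abs(trace.assigned_pred[:, 0] - y[:, 0])
            lags[name].append(_catch_up_lag(err, jump_cfg.jump_after))
            err_curves[name].append(err)

    # --- panel B: morph protocols -----------------------------------
    hp_m = Hyperparameters(
        alpha=morph_cfg.alpha, beta=morph_cfg.beta, q=morph_cfg.q, r=morph_cfg.r,
        v=1.0, m0=morph_cfg.m0, c=morph_cfg.c, n_dims=1,
    )
    curves = {"gradual": [], "mixed": []}
    dominant = {"gradual": [], "mixed": []}
    for _ in range(morph_cfg.n_runs):
        for protocol in ("gradual", "mixed"):
            values, idx = morph_sequence(protocol, morph_cfg.n_morphs, rng)
            trace = run_filter(values[:, None], hp_m)
            anchor = int(trace.assignments[np.flatnonzero(idx == 0)[0]])
            series = trace.mode_prob_series(anchor)
            resorted = np.empty_like(series)
            resorted[idx] = series
            curves[protocol].append(resorted)
            n_dominant = sum(
                trace.mode_prob_series(m).max() > 0.5 for m in range(1, trace.n_modes + 1)
            )
            dominant[protocol].append(n_dominant)

    avg_curves = {k: np.mean(v, axis=0) for k, v in curves.items()}
    morph_axis = np.linspace(0.0, 1.0, morph_cfg.n_morphs)
    mixed_below = np.flatnonzero(avg_curves["mixed"] < 0.5)
    if mixed_below.size and mixed_below[0] > 0:
        i = mixed_below[0]
        transition = float(0.5 * (morph_axis[i - 1] + morph_axis[i]))
    elif mixed_below.size:
        transition = 0.0
    else:
        transition = 1.0

    return {
        "dpkf_lag_median": float(np.median(lags["dpkf"])),
        "kf_lag_median": float(np.median(lags["kf"])),
        "lags": lags,
        "mean_abs_error": {k: np.mean(v, axis=0) for k, v in err_curves.items()},
        "gradual_dominant_modes": int(np.bincount(dominant["gradual"]).argmax()),
        "mixed_dominant_modes": int(np.bincount(dominant["mixed"]).argmax()),
        "anchor_mode_curves": avg_curves,
        "morph_axis": morph_axis,
        "transition_morph": transition,
    }
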