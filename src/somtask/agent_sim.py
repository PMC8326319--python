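"""Synthetic participants: performance-tracking agents with a tunable,
context-signed self-other mergence (SOM) bias.

Agents track all six player-by-minigame performance levels with the same
delta rule the analysis model assumes, and emit ratings and engage/avoid
choices through the same softmax — except that the rating decision
variables carry an additive SOM term: the *inappropriate* player's
current estimate, centred on the scale midpoint (8), multiplied by the
social context (+1 cooperation / -1 competition) and a weight.  With both
weights at zero the agent is exactly the pure appropriate-estimation
model; with positive weights its ratings show the cooperation-positive /
competition-negative cross-talk that the rating GLMs are built to detect.

The cohort generator emulates the stimulation study's layout: two groups
(dmPFC and vertex), two sessions per participant on an identical feedback
schedule (one cTBS, one not; order counterbalanced), with an additive
shift of the S-to-O SOM weight applied only in dmPFC cTBS sessions.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.stats import truncnorm

from .exceptions import DesignError, ParameterError
from .rl_model import RATING_BONUS, BehavioralRecord
from .schedule import (
    SCALE_MID,
    MINIGAMES,
    PLAYERS,
    Schedule,
    generate_feedback_schedule,
    generate_schedule,
    generate_thresholds,
    settle_trial,
)
from .rl_model import ev_engage as _ev_engage
from scipy.special import expit

MARKER_INIT = 7.5  # scale midpoint rounded to the half-integer grid


@dataclass
class AgentParams:
    """Generating parameters of one simulated session.

    ``w_som_StoO`` weights the context-signed influence of the agent's own
    tracked performance on its ratings of the other player; ``w_som_OtoS``
    the converse.  Zero weights recover the pure tracking model.
    """

    alpha: float
    beta: float
    w_som_StoO: float = 0.0
    w_som_OtoS: float = 0.0

    def __post_init__(self):
        if not (0.0 <= self.alpha <= 1.0):
            raise ParameterError(f"alpha={self.alpha} outside [0, 1]")
        if self.beta <= 0:
            raise ParameterError(f"beta={self.beta} must be positive")


def simulate_participant(schedule: Schedule, params: AgentParams, seed: int,
                         *, p_false_start: float = 0.0,
                         rating_bonus: float = RATING_BONUS) -> BehavioralRecord:
    """Play one session of the task and return the behavioral record.

    The agent initializes all performance estimates at the scale midpoint,
    updates them from every observed feedback (skipping its own on false
    starts), staircases the rating markers from its own ratings, and logs
    ratings, markers, choice, engage/avoid payoff and total trial reward.
    """
    for t in schedule.trials:
        if t.feedback_S is None:
            raise DesignError("schedule lacks feedback; fill it first")
        if t.threshold is None:
            raise DesignError("schedule lacks thresholds; fill them first")
    rng = np.random.default_rng(seed)
    perf = {(p, g): SCALE_MID for p in PLAYERS for g in MINIGAMES}
    markers = {(p, g): MARKER_INIT for p in PLAYERS for g in MINIGAMES}
    last_starter_fb: dict = {}
    in_main = False

    rows = []
    for t in schedule.trials:
        g = t.minigame
        other = t.relevant_other
        if t.phase == "main" and not in_main:
            # entering the main phase: restart each estimate at the last
            # starter feedback of that player/minigame, the same
            # initialization convention the analysis model uses, so an
            # unbiased agent is exactly the pure tracking model
            in_main = True
            for key, fb0 in last_starter_fb.items():
                perf[key] = float(fb0)
        fs = bool(t.false_start) or (p_false_start > 0 and rng.random() < p_false_start)
        row = {
            "session_id": t.session_id, "trial_index": t.trial_index,
            "phase": t.phase, "minigame": g, "context": t.context,
            "relevant_other": other, "threshold": t.threshold,
            "feedback_S": t.feedback_S, "feedback_O1": t.feedback_O1,
            "feedback_O2": t.feedback_O2, "false_start": fs,
            "has_decisions": t.has_decisions,
            "rating_S": np.nan, "rating_O": np.nan,
            "marker_S": np.nan, "marker_O": np.nan,
            "choice": None, "payoff": np.nan, "reward": np.nan,
        }
        if t.has_decisions:
            m_S = markers[("S", g)]
            m_O = markers[(other, g)]
            s_p, o_p = perf[("S", g)], perf[(other, g)]
            dv_S = s_p + params.w_som_OtoS * t.context * (o_p - SCALE_MID) - m_S
            dv_O = o_p + params.w_som_StoO * t.context * (s_p - SCALE_MID) - m_O
            rating_S = 1 if rng.random() < expit(params.beta * dv_S) else -1
            rating_O = 1 if rng.random() < expit(params.beta * dv_O) else -1
            ev = _ev_engage(s_p, o_p, t.threshold, t.context)
            choice = "engage" if rng.random() < expit(params.beta * ev) else "avoid"

            spec = replace(t, false_start=fs)
            payoff = settle_trial(choice, spec, rng)
            if fs:
                reward = payoff  # sole payoff; ratings yield nothing
            else:
                bonus_S = (rating_bonus if (t.feedback_S > m_S) == (rating_S > 0)
                           else -rating_bonus) if rating_S > 0 else 0.0
                bonus_O = (rating_bonus if (spec.feedback_O > m_O) == (rating_O > 0)
                           else -rating_bonus) if rating_O > 0 else 0.0
                reward = payoff + bonus_S + bonus_O
            row.update(rating_S=rating_S, rating_O=rating_O, marker_S=m_S,
                       marker_O=m_O, choice=choice, payoff=payoff,
                       reward=reward)
            markers[("S", g)] = float(np.clip(m_S + rating_S, 1.5, 14.5))
            markers[(other, g)] = float(np.clip(m_O + rating_O, 1.5, 14.5))
        rows.append(row)

        for p in PLAYERS:
            if p == "S" and fs:
                continue  # no self feedback on false starts
            fb = t.feedback_S if p == "S" else getattr(t, f"feedback_{p}")
            perf[(p, g)] += params.alpha * (fb - perf[(p, g)])
            if t.phase == "starter":
                last_starter_fb[(p, g)] = fb

    return BehavioralRecord(trials=pd.DataFrame(rows))


@dataclass
class ParticipantDataset:
    """All sessions of one simulated or loaded participant."""

    participant_id: str
    group: str
    sessions: list = field(default_factory=list)


@dataclass
class CohortSpec:
    """Population and design parameters for a simulated stimulation cohort.

    Defaults emulate the study conditions: 28 participants per group, two
    88-trial sessions per participant on one shared feedback schedule with
    a 16-trial starter phase, session order counterbalanced, and the
    S-to-O SOM weight shifted by ``ctbs_som_delta`` only in dmPFC cTBS
    sessions.  Per-participant parameters are drawn from truncated
    normals.
    """

    n_per_group: int = 28
    groups: tuple = ("dmPFC", "vertex")
    ctbs_som_delta: float = 0.4
    alpha_mean: float = 0.3
    alpha_sd: float = 0.1
    beta_mean: float = 0.8
    beta_sd: float = 0.2
    w_som_StoO_mean: float = 0.1
    w_som_StoO_sd: float = 0.15
    w_som_OtoS_mean: float = 0.07
    w_som_OtoS_sd: float = 0.15
    seed: int = 0
    n_main: int = 88
    n_starter: int = 16
    drift_sd: float = 0.5
    obs_sd: float = 1.0
    threshold_noise_sd: float = 2.0
    p_false_start: float = 0.0

    def to_dict(self) -> dict:
        d = dict(vars(self))
        d["groups"] = list(self.groups)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "CohortSpec":
        d = dict(d)
        if "groups" in d:
            d["groups"] = tuple(d["groups"])
        return cls(**d)


def _trunc_normal(rng, mean, sd, lo, hi):
    if sd == 0:
        return float(np.clip(mean, lo, hi))
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return float(truncnorm.rvs(a, b, loc=mean, scale=sd, random_state=rng))


def build_cohort_schedule(spec: CohortSpec) -> Schedule:
    """The single task schedule shared by every session of the cohort."""
    ss = np.random.SeedSequence(spec.seed)
    s_design, s_feedback, s_threshold = (int(c.generate_state(1)[0] % (2**31))
                                         for c in ss.spawn(3))
    sched = generate_schedule(s_design, n_main=spec.n_main,
                              n_starter=spec.n_starter)
    sched = generate_feedback_schedule(s_feedback, sched,
                                       drift_sd=spec.drift_sd,
                                       obs_sd=spec.obs_sd)
    return generate_thresholds(s_threshold, sched,
                               noise_sd=spec.threshold_noise_sd)


def simulate_cohort(spec: CohortSpec) -> list[ParticipantDataset]:
    """Simulate both groups, two sessions per participant.

    Every session of every participant replays the identical feedback
    schedule, mirroring the yoked two-session design; only the agent's
    stochastic responses and the dmPFC-cTBS SOM shift differ between
    sessions.
    """
    if spec.n_per_group < 2:
        raise ParameterError("n_per_group must be at least 2")
    schedule = build_cohort_schedule(spec)
    datasets = []
    for g_idx, group in enumerate(spec.groups):
        for i in range(spec.n_per_group):
            pid = f"{group}_{i:03d}"
            child = np.random.SeedSequence((spec.seed, g_idx + 1, i))
            prng = np.random.default_rng(child)
            base = AgentParams(
                alpha=_trunc_normal(prng, spec.alpha_mean, spec.alpha_sd, 0.02, 0.98),
                beta=_trunc_normal(prng, spec.beta_mean, spec.beta_sd, 0.05, 5.0),
                w_som_StoO=float(prng.normal(spec.w_som_StoO_mean, spec.w_som_StoO_sd)),
                w_som_OtoS=float(prng.normal(spec.w_som_OtoS_mean, spec.w_som_OtoS_sd)),
            )
            # counterbalanced session order
            conditions = (["no-cTBS", "cTBS"] if i % 2 == 0
                          else ["cTBS", "no-cTBS"])
            ds = ParticipantDataset(participant_id=pid, group=group)
            for order, cond in enumerate(conditions):
                p = base
                if group == "dmPFC" and cond == "cTBS":
                    p = replace(base, w_som_StoO=base.w_som_StoO + spec.ctbs_som_delta)
                sseed = int(prng.integers(2**31))
                rec = simulate_participant(schedule, p, sseed,
                                           p_false_start=spec.p_false_start)
                rec.participant_id = pid
                rec.session_id = f"{pid}_{cond}"
                rec.group = group
                rec.condition = cond
                rec.session_order = order
                rec.meta = {"alpha_true": p.alpha, "beta_true": p.beta,
                            "w_som_StoO_true": p.w_som_StoO,
                            "w_som_OtoS_true": p.w_som_OtoS}
                ds.sessions.append(rec)
            datasets.append(ds)
    return datasets
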