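"""Delta-rule performance tracking, choice likelihoods, and group ML fitting.

The model maintains six recency-weighted performance estimates — one per
player (S, O1, O2) and minigame — updated with a Rescorla-Wagner rule
(learning rate ``alpha``).  Binary ability ratings are modeled as a softmax
(inverse temperature ``beta``) of the difference between the current
pre-decision estimate and the trial's rating marker; engage/avoid choices
as a softmax of the expected engage value against the zero-valued avoid
default.  One (alpha, beta) pair is fitted per experimental group by
minimizing the summed negative log-likelihood over all participants'
sessions, with three likelihood terms (S rating, O rating, choice) per
decision trial.

Main-session estimates are initialized from the last starter-phase
feedback of the same player and minigame; on false-start trials the S
estimate is not updated and carries no prediction error.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.signal import lfilter
from scipy.special import expit, log_expit

from .exceptions import FitError, ParameterError
from .schedule import MINIGAMES, OTHERS, Schedule

logger = logging.getLogger(__name__)

#: upper bound on the inverse temperature during fitting
BETA_MAX = 20.0
#: floor applied to decision probabilities before taking logs
P_FLOOR = 1e-10
#: stake of the rating-accuracy bonus
RATING_BONUS = 0.25

RECORD_COLUMNS = [
    "rating_S", "rating_O", "marker_S", "marker_O", "choice",
    "payoff", "reward",
]


@dataclass
class RLParams:
    """Free parameters of the performance-tracking model (one set per group)."""

    alpha: float
    beta: float

    def __post_init__(self):
        if not (0.0 <= self.alpha <= 1.0):
            raise ParameterError(f"alpha={self.alpha} outside [0, 1]")
        if not (0.0 < self.beta <= BETA_MAX):
            raise ParameterError(f"beta={self.beta} outside (0, {BETA_MAX}]")


@dataclass
class BehavioralRecord:
    """One participant-session: the schedule plus the responses made on it.

    ``trials`` holds one row per trial with the schedule columns and, on
    decision trials, the observed responses: ``rating_S``/``rating_O``
    (+1 positive, -1 negative), the markers the ratings were made against,
    ``choice`` ("engage"/"avoid"), the engage/avoid ``payoff`` and the
    trial's total realized ``reward`` (payoff plus rating bonuses).
    """

    trials: pd.DataFrame
    participant_id: str = ""
    session_id: str = ""
    group: str = ""
    condition: str = ""          # "cTBS" | "no-cTBS"
    session_order: int = 0
    meta: dict = field(default_factory=dict)

    def main(self) -> pd.DataFrame:
        return self.trials[self.trials["phase"] == "main"]


# -- elementary model operations -------------------------------------------

def update_performance(perf: float, feedback: float, alpha: float) -> float:
    """One delta-rule step: perf + alpha * (feedback - perf)."""
    if not (0.0 <= alpha <= 1.0):
        raise ParameterError(f"alpha={alpha} outside [0, 1]")
    return perf + alpha * (feedback - perf)


def p_positive_rating(perf: float, marker: float, beta: float):
    """Softmax probability of a positive rating: logistic(beta * (perf - marker))."""
    if np.any(np.asarray(beta) <= 0):
        raise ParameterError("beta must be positive")
    return expit(beta * (np.asarray(perf, dtype=float) - marker))


def ev_rating(p_pos: float, rating: str | int, bonus: float = RATING_BONUS):
    """Expected value of a rating: (p_pos - 0.5) * 2 * bonus if positive, else 0."""
    positive = np.asarray(rating) == "positive"
    positive = positive | (np.asarray(rating, dtype=object) == 1)
    return np.where(positive, (np.asarray(p_pos, dtype=float) - 0.5) * 2.0 * bonus, 0.0)[()]


def ev_engage(S_perf: float, O_perf: float, threshold: float, context: int):
    """Expected engage value: S-O-threshold (competition), mean-threshold (cooperation)."""
    S_perf = np.asarray(S_perf, dtype=float)
    return np.where(np.asarray(context) == -1,
                    S_perf - O_perf - threshold,
                    (S_perf + O_perf) / 2.0 - threshold)[()]


def p_engage(ev: float, beta: float):
    """Softmax probability of engaging against the zero-valued avoid option."""
    if np.any(np.asarray(beta) <= 0):
        raise ParameterError("beta must be positive")
    return expit(beta * np.asarray(ev, dtype=float))


def ev_chosen_and_rpe(ev_S_rating: float, ev_O_rating: float, ev_ead: float,
                      reward: float) -> tuple[float, float]:
    """Total trial value expectation and its reward prediction error.

    ``ev_ead`` is the engage value if engage was chosen, 0 for avoid; the
    reward is the trial's total realized payoff including rating bonuses.
    """
    ev_chosen = ev_S_rating + ev_O_rating + ev_ead
    return ev_chosen, reward - ev_chosen


# -- prepared sessions and the vectorized latent pass ----------------------

@dataclass
class _PreparedSession:
    """Arrays extracted once per session so the likelihood is pure numpy."""

    # per (player_index 0..2, minigame_index 0..1): feedbacks of that
    # series over main trials, update mask, and initialization value
    series_feedback: list
    series_mask: list
    series_init: list
    # per main decision trial
    mg_idx: np.ndarray          # minigame index
    pos_in_mg: np.ndarray       # position within that minigame's main trials
    other_idx: np.ndarray       # 1 or 2
    context: np.ndarray
    threshold: np.ndarray
    marker_S: np.ndarray
    marker_O: np.ndarray
    rating_S: np.ndarray        # +1 / -1
    rating_O: np.ndarray
    choice_sign: np.ndarray     # +1 engage / -1 avoid
    engaged: np.ndarray         # boolean
    false_start: np.ndarray
    reward: np.ndarray
    trial_index: np.ndarray


def _prepare_session(record: BehavioralRecord) -> _PreparedSession:
    df = record.trials
    main = df[df["phase"] == "main"].reset_index(drop=True)
    starter = df[df["phase"] == "starter"]
    mg_codes = {g: i for i, g in enumerate(MINIGAMES)}
    fb_cols = ["feedback_S", "feedback_O1", "feedback_O2"]

    series_feedback, series_mask, series_init = [], [], []
    for p_idx, col in enumerate(fb_cols):
        for g, g_idx in mg_codes.items():
            sub = main[main["minigame"] == g]
            fb = sub[col].to_numpy(dtype=float)
            if p_idx == 0:
                mask = ~sub["false_start"].to_numpy(dtype=bool)
            else:
                mask = np.ones(len(sub), dtype=bool)
            st = starter[starter["minigame"] == g][col].dropna()
            if len(st):
                init = float(st.iloc[-1])
            else:
                # truncated external data without a starter phase
                init = float(fb[0]) if len(fb) else np.nan
                logger.warning(
                    "no starter feedback for %s/%s in %s; initializing at "
                    "first main feedback", col, g, record.session_id)
            series_feedback.append(fb)
            series_mask.append(mask)
            series_init.append(init)

    mg_idx = main["minigame"].map(mg_codes).to_numpy(dtype=int)
    pos_in_mg = np.zeros(len(main), dtype=int)
    for g_idx in range(len(MINIGAMES)):
        sel = mg_idx == g_idx
        pos_in_mg[sel] = np.arange(sel.sum())
    other_idx = main["relevant_other"].map({o: i + 1 for i, o in enumerate(OTHERS)}).to_numpy(dtype=int)
    choice = main["choice"].astype(str).to_numpy()
    engaged = choice == "engage"
    return _PreparedSession(
        series_feedback=series_feedback,
        series_mask=series_mask,
        series_init=series_init,
        mg_idx=mg_idx,
        pos_in_mg=pos_in_mg,
        other_idx=other_idx,
        context=main["context"].to_numpy(dtype=int),
        threshold=main["threshold"].to_numpy(dtype=float),
        marker_S=main["marker_S"].to_numpy(dtype=float),
        marker_O=main["marker_O"].to_numpy(dtype=float),
        rating_S=main["rating_S"].to_numpy(dtype=float),
        rating_O=main["rating_O"].to_numpy(dtype=float),
        choice_sign=np.where(engaged, 1.0, -1.0),
        engaged=engaged,
        false_start=main["false_start"].to_numpy(dtype=bool),
        reward=main["reward"].to_numpy(dtype=float),
        trial_index=main["trial_index"].to_numpy(dtype=int),
    )


def _perf_trace(feedback: np.ndarray, mask: np.ndarray, init: float,
                alpha: float) -> np.ndarray:
    """Pre-update estimates for each trial of one player-minigame series."""
    upd = feedback[mask]
    if alpha == 0.0 or len(upd) == 0:
        after = np.full(len(upd) + 1, init)
    else:
        z, _ = lfilter([alpha], [1.0, -(1.0 - alpha)], upd,
                       zi=[(1.0 - alpha) * init])
        after = np.concatenate(([init], z))
    n_before = np.cumsum(mask) - mask
    return after[n_before]


def _session_terms(prep: _PreparedSession, alpha: float):
    """Decision variables and log-probabilities for one prepared session."""
    traces = [
        _perf_trace(prep.series_feedback[k], prep.series_mask[k],
                    prep.series_init[k], alpha)
        for k in range(6)
    ]
    n = len(prep.mg_idx)
    S_perf = np.empty(n)
    O_perf = np.empty(n)
    for g in range(2):
        sel = prep.mg_idx == g
        S_perf[sel] = traces[g][prep.pos_in_mg[sel]]
    for o in (1, 2):
        for g in range(2):
            sel = (prep.other_idx == o) & (prep.mg_idx == g)
            O_perf[sel] = traces[2 * o + g][prep.pos_in_mg[sel]]
    dv_S = S_perf - prep.marker_S
    dv_O = O_perf - prep.marker_O
    ev = ev_engage(S_perf, O_perf, prep.threshold, prep.context)
    return S_perf, O_perf, dv_S, dv_O, ev


def _session_nll_prepared(prep: _PreparedSession, alpha: float,
                          beta: float) -> float:
    _, _, dv_S, dv_O, ev = _session_terms(prep, alpha)
    logp = np.concatenate([
        log_expit(prep.rating_S * beta * dv_S),
        log_expit(prep.rating_O * beta * dv_O),
        log_expit(prep.choice_sign * beta * ev),
    ])
    return float(-np.sum(np.maximum(logp, np.log(P_FLOOR))))


def session_nll(record: BehavioralRecord, params: RLParams) -> float:
    """Summed negative log-likelihood of one session's decisions.

    Each main-phase decision trial contributes three terms — the S rating,
    the O rating, and the engage/avoid choice — treated equally; starter
    trials only supply the estimate initialization.  Probabilities are
    floored at 1e-10 so the likelihood stays finite.
    """
    return _session_nll_prepared(_prepare_session(record), params.alpha,
                                 params.beta)


# -- group fitting ----------------------------------------------------------

#: fixed multi-start grid (alpha x beta) used by fit_group
START_ALPHAS = (0.1, 0.3, 0.5, 0.7, 0.9)
START_BETAS = (0.05, 0.2, 0.8, 3.0, 10.0)


@dataclass
class FitResult:
    params: RLParams
    nll: float
    n_records: int
    converged: bool
    start_used: tuple[float, float]


def fit_group(records: list[BehavioralRecord], *, full_output: bool = False,
              n_refine: int = 3):
    """Fit one (alpha, beta) pair to all sessions of a group by ML.

    Evaluates the summed negative log-likelihood on a fixed 5x5
    (alpha, beta) start grid, then refines the ``n_refine`` best grid
    points with bounded L-BFGS-B (alpha in [0, 1], beta in (0, 20]).
    Deterministic given the records.
    """
    if not records:
        raise ParameterError("fit_group requires at least one record")
    preps = [_prepare_session(r) for r in records]

    def total_nll(x):
        a, b = x
        a = float(np.clip(a, 0.0, 1.0))
        b = float(np.clip(b, 1e-6, BETA_MAX))
        return sum(_session_nll_prepared(p, a, b) for p in preps)

    grid = [(a, b) for a in START_ALPHAS for b in START_BETAS]
    grid_nll = [total_nll(x) for x in grid]
    order = np.argsort(grid_nll)

    best = None
    any_ok = False
    for idx in order[:n_refine]:
        res = minimize(total_nll, x0=np.array(grid[idx]), method="L-BFGS-B",
                       bounds=[(0.0, 1.0), (1e-4, BETA_MAX)])
        any_ok = any_ok or res.success
        if best is None or res.fun < best[0]:
            best = (res.fun, res.x, res.success, grid[idx])
    if best is None or not np.isfinite(best[0]):
        raise FitError("optimizer failed on every start point")
    # never report worse than the best raw grid point
    if grid_nll[order[0]] < best[0]:
        best = (grid_nll[order[0]], np.array(grid[order[0]]), any_ok,
                grid[order[0]])
    nll, x, ok, start = best
    params = RLParams(alpha=float(np.clip(x[0], 0.0, 1.0)),
                      beta=float(np.clip(x[1], 1e-4, BETA_MAX)))
    if not any_ok:
        raise FitError(f"no L-BFGS-B start converged (best nll {nll:.3f})")
    if full_output:
        return FitResult(params=params, nll=float(nll), n_records=len(records),
                         converged=bool(ok), start_used=tuple(start))
    return params


def group_nll(records: list[BehavioralRecord], params: RLParams) -> float:
    """Summed session_nll over a list of records."""
    return sum(session_nll(r, params) for r in records)


# -- latent traces -----------------------------------------------------------

TRACE_COLUMNS = [
    "trial_index", "S_performance", "O_performance", "PE_S", "PE_O",
    "EV_S_rating", "EV_O_rating", "EV_engage", "p_engage", "EV_chosen", "RPE",
]


def trace_latents(record: BehavioralRecord, params: RLParams) -> pd.DataFrame:
    """Per-trial latent quantities of the fitted model over the main phase.

    S_performance and O_performance are the pre-update estimates used for
    that trial's ratings and choice; PE_S is absent (NaN) on false-start
    trials, where the S estimate is not updated.
    """
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        prep = _prepare_session(record)
        S_perf, O_perf, dv_S, dv_O, ev = _session_terms(prep, params.alpha)
    beta = params.beta
    p_pos_S = expit(beta * dv_S)
    p_pos_O = expit(beta * dv_O)
    ev_S = np.where(prep.rating_S > 0, (p_pos_S - 0.5) * 2 * RATING_BONUS, 0.0)
    ev_O = np.where(prep.rating_O > 0, (p_pos_O - 0.5) * 2 * RATING_BONUS, 0.0)
    p_eng = expit(beta * ev)
    ev_ead = np.where(prep.engaged, ev, 0.0)
    ev_chosen = ev_S + ev_O + ev_ead
    rpe = prep.reward - ev_chosen

    # per-player PEs for the current trial's relevant players
    fb_S = np.empty(len(S_perf))
    fb_O = np.empty(len(O_perf))
    for g in range(2):
        sel = prep.mg_idx == g
        fb_S[sel] = prep.series_feedback[g][prep.pos_in_mg[sel]]
    for o in (1, 2):
        for g in range(2):
            sel = (prep.other_idx == o) & (prep.mg_idx == g)
            fb_O[sel] = prep.series_feedback[2 * o + g][prep.pos_in_mg[sel]]
    pe_S = np.where(prep.false_start, np.nan, fb_S - S_perf)
    pe_O = fb_O - O_perf

    return pd.DataFrame({
        "trial_index": prep.trial_index,
        "S_performance": S_perf,
        "O_performance": O_perf,
        "PE_S": pe_S,
        "PE_O": pe_O,
        "EV_S_rating": ev_S,
        "EV_O_rating": ev_O,
        "EV_engage": ev,
        "p_engage": p_eng,
        "EV_chosen": ev_chosen,
        "RPE": rpe,
    })
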