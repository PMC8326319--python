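"""Task structure: trial design, feedback schedules, thresholds, payoffs, markers.

The task is a social performance-tracking paradigm.  On each trial the
participant (S) is paired with one of two other players (the *relevant
other*, O) in either a cooperative (+1) or competitive (-1) context, makes
an engage/avoid decision against a trial-varying threshold, rates the
expected performance of S and O against staircased half-integer rating
markers, and then observes integer performance feedback (1-15) for all
three players.  Feedback is experimenter-determined and drifts slowly per
player and minigame; thresholds are constructed so that engage payoffs are
decorrelated from the players' ability levels.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .exceptions import DesignError, InvalidStateError, ParameterError

SCALE_MIN = 1
SCALE_MAX = 15
SCALE_MID = 8.0
MARKER_MIN = 1.5
MARKER_MAX = 14.5

PLAYERS = ("S", "O1", "O2")
MINIGAMES = ("game1", "game2")
CONTEXTS = (1, -1)  # +1 cooperation, -1 competition
OTHERS = ("O1", "O2")

#: payoff for a false start, regardless of choice and ratings
FALSE_START_PAYOFF = -3.0
#: magnitude of the symmetric random avoid payoff
AVOID_STAKE = 1.5

TRIAL_COLUMNS = [
    "session_id", "trial_index", "phase", "minigame", "context",
    "relevant_other", "threshold", "feedback_S", "feedback_O1",
    "feedback_O2", "false_start", "has_decisions",
]


@dataclass
class TrialSpec:
    """Experimenter-determined content of one trial."""

    session_id: str
    trial_index: int
    phase: str                     # "starter" | "main"
    minigame: str                  # "game1" | "game2"
    context: int                   # +1 cooperation, -1 competition
    relevant_other: str            # "O1" | "O2"
    threshold: float | None = None
    feedback_S: int | None = None
    feedback_O1: int | None = None
    feedback_O2: int | None = None
    false_start: bool = False
    has_decisions: bool = True

    def feedback_for(self, player: str) -> int | None:
        return getattr(self, f"feedback_{player}") if player != "S" else self.feedback_S

    @property
    def feedback_O(self) -> int | None:
        """Feedback of the trial's relevant other."""
        return getattr(self, f"feedback_{self.relevant_other}")


@dataclass
class Schedule:
    """Ordered trial list of one session (starter phase followed by main)."""

    trials: list[TrialSpec] = field(default_factory=list)

    @property
    def n_main(self) -> int:
        return sum(t.phase == "main" for t in self.trials)

    @property
    def n_starter(self) -> int:
        return sum(t.phase == "starter" for t in self.trials)

    def design_counts(self) -> dict[tuple[int, str, str], int]:
        """Main-phase trial count per (context, relevant_other, minigame) cell."""
        counts: dict[tuple[int, str, str], int] = {}
        for t in self.trials:
            if t.phase == "main":
                key = (t.context, t.relevant_other, t.minigame)
                counts[key] = counts.get(key, 0) + 1
        return counts

    def main_trials(self) -> list[TrialSpec]:
        return [t for t in self.trials if t.phase == "main"]

    def starter_trials(self) -> list[TrialSpec]:
        return [t for t in self.trials if t.phase == "starter"]

    def copy(self) -> "Schedule":
        return Schedule([replace(t) for t in self.trials])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(t) for t in self.trials], columns=TRIAL_COLUMNS)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "Schedule":
        trials = []
        for _, row in df.iterrows():
            trials.append(TrialSpec(
                session_id=str(row["session_id"]),
                trial_index=int(row["trial_index"]),
                phase=str(row["phase"]),
                minigame=str(row["minigame"]),
                context=int(row["context"]),
                relevant_other=str(row["relevant_other"]),
                threshold=None if pd.isna(row["threshold"]) else float(row["threshold"]),
                feedback_S=None if pd.isna(row["feedback_S"]) else int(row["feedback_S"]),
                feedback_O1=None if pd.isna(row["feedback_O1"]) else int(row["feedback_O1"]),
                feedback_O2=None if pd.isna(row["feedback_O2"]) else int(row["feedback_O2"]),
                false_start=bool(row["false_start"]),
                has_decisions=bool(row["has_decisions"]),
            ))
        return cls(trials)


def generate_schedule(seed: int, n_main: int = 88, n_starter: int = 16,
                      session_id: str = "s1") -> Schedule:
    """Generate a balanced pseudorandom trial order.

    The main phase is a fully crossed 2(context) x 2(partner) x 2(minigame)
    design with exactly ``n_main/8`` trials per cell; the starter phase
    spreads ``n_starter`` trials as evenly as possible over the same cells,
    with the first four trials (no decisions) covering both minigames twice
    each so that initial impressions form for every minigame.
    """
    if n_main % 8 != 0:
        raise DesignError(f"n_main={n_main} is not divisible by the 8 design cells")
    if n_starter < 4:
        raise DesignError(f"n_starter={n_starter} must be at least 4")
    rng = np.random.default_rng(seed)
    cells = list(itertools.product(CONTEXTS, OTHERS, MINIGAMES))

    # starter phase: round-robin over cells, truncated, then shuffled
    reps = -(-n_starter // 8)
    starter_cells = (cells * reps)[:n_starter]
    starter_cells = [starter_cells[i] for i in rng.permutation(n_starter)]
    # first four trials: two per minigame, no decisions
    by_game: dict[str, list[int]] = {g: [] for g in MINIGAMES}
    for i, (_, _, g) in enumerate(starter_cells):
        by_game[g].append(i)
    head = by_game["game1"][:2] + by_game["game2"][:2]
    head = [head[i] for i in rng.permutation(4)]
    order = head + [i for i in range(n_starter) if i not in head]
    starter_cells = [starter_cells[i] for i in order]

    main_cells = cells * (n_main // 8)
    main_cells = [main_cells[i] for i in rng.permutation(n_main)]

    trials: list[TrialSpec] = []
    for i, (ctx, other, game) in enumerate(starter_cells):
        trials.append(TrialSpec(session_id=session_id, trial_index=i,
                                phase="starter", minigame=game, context=ctx,
                                relevant_other=other, has_decisions=i >= 4))
    for j, (ctx, other, game) in enumerate(main_cells):
        trials.append(TrialSpec(session_id=session_id,
                                trial_index=n_starter + j, phase="main",
                                minigame=game, context=ctx,
                                relevant_other=other, has_decisions=True))
    return Schedule(trials)


DEFAULT_LEVEL_MEANS = {"S": 8.0, "O1": 9.0, "O2": 7.0}


def generate_feedback_schedule(seed: int, schedule: Schedule,
                               drift_sd: float = 0.5, obs_sd: float = 1.0,
                               level_means: dict | float | None = None) -> Schedule:
    """Fill per-player feedback with a slowly drifting bounded random walk.

    Per player and minigame a latent level performs a Gaussian random walk
    (sd ``drift_sd`` per trial of that minigame, reflected into [1, 15]);
    presented feedback is the level plus observation noise (sd ``obs_sd``),
    rounded and clipped to the integer 1-15 scale.  Because the two
    minigames carry independent walks, the interleaved feedback stream a
    participant sees has weaker lag-1 autocorrelation than either
    within-minigame stream.
    """
    if level_means is None:
        level_means = DEFAULT_LEVEL_MEANS
    if np.isscalar(level_means):
        level_means = {p: float(level_means) for p in PLAYERS}

    def mean_for(player: str, game: str) -> float:
        if (player, game) in level_means:
            return float(level_means[(player, game)])
        return float(level_means[player])

    for p in PLAYERS:
        for g in MINIGAMES:
            m = mean_for(p, g)
            if not (SCALE_MIN <= m <= SCALE_MAX):
                raise ParameterError(f"level mean {m} for {p}/{g} outside [1, 15]")

    rng = np.random.default_rng(seed)
    out = schedule.copy()
    levels = {(p, g): mean_for(p, g) for p in PLAYERS for g in MINIGAMES}
    for t in out.trials:
        for p in PLAYERS:
            lvl = levels[(p, t.minigame)]
            lvl = lvl + rng.normal(0.0, drift_sd) if drift_sd > 0 else lvl
            # reflect at the scale bounds to keep the walk inside [1, 15]
            if lvl < SCALE_MIN:
                lvl = 2 * SCALE_MIN - lvl
            elif lvl > SCALE_MAX:
                lvl = 2 * SCALE_MAX - lvl
            lvl = float(np.clip(lvl, SCALE_MIN, SCALE_MAX))
            levels[(p, t.minigame)] = lvl
            obs = lvl + (rng.normal(0.0, obs_sd) if obs_sd > 0 else 0.0)
            fb = int(np.clip(np.rint(obs), SCALE_MIN, SCALE_MAX))
            setattr(t, f"feedback_{p}" if p != "S" else "feedback_S", fb)
    return out


def generate_thresholds(seed: int, schedule: Schedule,
                        noise_sd: float = 2.0) -> Schedule:
    """Fill thresholds so engage payoffs are near zero and ability-decorrelated.

    The threshold equals the trial's payoff-relevant feedback quantity (the
    S-O difference in competition, the S/O mean in cooperation) plus
    zero-mean Gaussian noise, so the realized engage payoff is pure noise,
    centred on zero and uncorrelated with the players' ability levels.
    """
    if noise_sd <= 0:
        raise ParameterError("noise_sd must be positive: thresholds must vary")
    rng = np.random.default_rng(seed)
    out = schedule.copy()
    for t in out.trials:
        if t.feedback_S is None or t.feedback_O is None:
            raise DesignError("feedback must be filled before thresholds")
        f_s, f_o = float(t.feedback_S), float(t.feedback_O)
        base = (f_s - f_o) if t.context == -1 else (f_s + f_o) / 2.0
        t.threshold = float(base + rng.normal(0.0, noise_sd))
    return out


def engage_payoff(feedback_S: float, feedback_O: float, threshold: float,
                  context: int) -> float:
    """Realized payoff of an engage choice.

    Competition: (feedback_S - feedback_O) - threshold.
    Cooperation: (feedback_S + feedback_O)/2 - threshold.
    """
    if context == -1:
        return (feedback_S - feedback_O) - threshold
    return (feedback_S + feedback_O) / 2.0 - threshold


def settle_trial(choice: str, spec: TrialSpec, rng: np.random.Generator) -> float:
    """Realized engage/avoid payoff of a trial (rating bonuses are separate).

    False starts pay a fixed -3 regardless of choice; avoid pays +/-1.5
    with equal probability; engage pays the threshold-relative quantity.
    """
    if spec.false_start:
        return FALSE_START_PAYOFF
    if choice == "avoid":
        return AVOID_STAKE if rng.random() < 0.5 else -AVOID_STAKE
    return engage_payoff(spec.feedback_S, spec.feedback_O, spec.threshold,
                         spec.context)


def _check_marker(marker: float) -> None:
    if abs((marker - 0.5) - round(marker - 0.5)) > 1e-9:
        raise InvalidStateError(f"rating marker {marker} is off the X.5 grid")
    if not (MARKER_MIN <= marker <= MARKER_MAX):
        raise InvalidStateError(f"rating marker {marker} outside [{MARKER_MIN}, {MARKER_MAX}]")


def update_rating_marker(marker: float, rating: str | int) -> float:
    """Staircase one rating marker: +1 after a positive rating, -1 after a
    negative one, clipped to the [1.5, 14.5] half-integer grid."""
    _check_marker(marker)
    if rating in ("positive", 1):
        marker = marker + 1.0
    elif rating in ("negative", -1):
        marker = marker - 1.0
    else:
        raise ParameterError(f"unknown rating {rating!r}")
    return float(np.clip(marker, MARKER_MIN, MARKER_MAX))
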