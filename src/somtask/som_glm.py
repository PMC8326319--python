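"""Trial-wise rating GLMs and per-session self-other mergence effect sizes.

Two logistic regressions on the binary ability ratings of each
participant-session, restricted to trials on which the participant chose
to engage (the only trials on which the social context matters):

* the *binned* model fits each context separately with regressors
  {S_performance, O_performance, rating marker};
* the *interaction* model pools contexts and adds the context main effect
  and the two performance-by-context interactions.

The SOM effect sizes are the interaction coefficients: the coefficient of
S_performance x context in the O-rating model (SOM S->O) and of
O_performance x context in the S-rating model (SOM O->S).  A positive
value means the inappropriate player's tracked performance pushes the
rating upward in cooperation and downward in competition.  All regressors
— including the interaction columns, which are formed as products of
z-scored factors and then re-standardized — are z-scored within the
included trials of the session.  Effects come in a raw-coefficient flavor
(used for stimulation contrasts) and a variance-weighted flavor
(coefficient over standard error, used for baseline descriptives).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.tools.sm_exceptions import PerfectSeparationError

from .exceptions import DegenerateDesignError, UnderdeterminedDesignError
from .rl_model import BehavioralRecord, RLParams, trace_latents

logger = logging.getLogger(__name__)

GLM2_COLUMNS = ["S_performance", "O_performance", "S_performance_x_context",
                "O_performance_x_context", "context", "marker"]
GLM1_COLUMNS = ["S_performance", "O_performance", "marker"]

EFFECT_COLUMNS = [
    "participant_id", "session_id", "group", "condition", "session_order",
    "som_StoO_raw", "som_StoO_vw", "som_OtoS_raw", "som_OtoS_vw",
    "context_S_raw", "context_S_vw", "context_O_raw", "context_O_vw",
    "sperf_S_raw", "operf_O_raw", "n_engage", "converged",
]


@dataclass
class DesignMatrix:
    """Z-scored regressor matrix plus the binary rating outcome."""

    X: pd.DataFrame
    y: np.ndarray           # 1 = positive rating
    target: str             # "S" | "O"
    variant: str            # "GLM2" | "GLM1-coop" | "GLM1-comp"
    n_trials: int


@dataclass
class GLMResult:
    beta: pd.Series
    se: pd.Series
    vw_beta: pd.Series      # beta / se
    n_trials: int
    converged: bool


def _zscore(v: np.ndarray, name: str) -> np.ndarray:
    sd = v.std(ddof=0)
    if sd < 1e-12:
        raise DegenerateDesignError(f"column {name!r} has zero variance "
                                    "over the included trials")
    return (v - v.mean()) / sd


def build_design(trace: pd.DataFrame, record: BehavioralRecord, target: str,
                 variant: str = "GLM2") -> DesignMatrix:
    """Assemble the z-scored design for one rating model.

    ``trace`` is the latent-trace frame aligned to the record's main
    trials.  Engage-only filtering (and, for the binned variants, context
    filtering) happens before normalization.
    """
    if target not in ("S", "O"):
        raise ValueError(f"target must be 'S' or 'O', got {target!r}")
    if variant not in ("GLM2", "GLM1-coop", "GLM1-comp"):
        raise ValueError(f"unknown variant {variant!r}")
    main = record.main().reset_index(drop=True)
    tr = trace.reset_index(drop=True)
    if len(main) != len(tr):
        raise ValueError("trace and record are not aligned")
    df = pd.concat([main, tr[["S_performance", "O_performance"]]], axis=1)

    mask = df["choice"].astype(str) == "engage"
    if variant == "GLM1-coop":
        mask &= df["context"] == 1
    elif variant == "GLM1-comp":
        mask &= df["context"] == -1
    df = df[mask]

    cols = GLM2_COLUMNS if variant == "GLM2" else GLM1_COLUMNS
    if len(df) < len(cols) + 2:
        raise UnderdeterminedDesignError(
            f"{len(df)} engage trials for {variant}-{target}; "
            f"need at least {len(cols) + 2}")

    marker = df[f"marker_{target}"].to_numpy(dtype=float)
    s_perf = df["S_performance"].to_numpy(dtype=float)
    o_perf = df["O_performance"].to_numpy(dtype=float)
    X = pd.DataFrame(index=range(len(df)))
    zs = _zscore(s_perf, "S_performance")
    zo = _zscore(o_perf, "O_performance")
    X["S_performance"] = zs
    X["O_performance"] = zo
    if variant == "GLM2":
        zc = _zscore(df["context"].to_numpy(dtype=float), "context")
        X["S_performance_x_context"] = _zscore(zs * zc, "S_performance_x_context")
        X["O_performance_x_context"] = _zscore(zo * zc, "O_performance_x_context")
        X["context"] = zc
    X["marker"] = _zscore(marker, "marker")
    y = (df[f"rating_{target}"].to_numpy(dtype=float) > 0).astype(float)
    return DesignMatrix(X=X, y=y, target=target, variant=variant,
                        n_trials=len(df))


def fit_logistic(design: DesignMatrix) -> GLMResult:
    """Maximum-likelihood logistic regression with intercept.

    Separation or non-convergence is flagged (``converged = False``)
    rather than returning unstable estimates.
    """
    X = sm.add_constant(design.X, has_constant="add")
    converged = True
    try:
        with np.errstate(all="ignore"), warnings.catch_warnings():
            # separation and non-convergence are reported via the flag
            warnings.simplefilter("ignore")
            res = sm.Logit(design.y, X).fit(disp=0, maxiter=200)
        beta = res.params
        se = res.bse
        converged = bool(res.mle_retvals.get("converged", False))
    except (PerfectSeparationError, np.linalg.LinAlgError):
        beta = pd.Series(np.nan, index=X.columns)
        se = pd.Series(np.nan, index=X.columns)
        converged = False
    if converged and (beta.abs().max() > 50 or not np.isfinite(se).all()):
        converged = False  # quasi-separation: coefficients diverging
    with np.errstate(all="ignore"):
        vw = beta / se
    return GLMResult(beta=beta.drop("const"), se=se.drop("const"),
                     vw_beta=vw.drop("const"), n_trials=design.n_trials,
                     converged=converged)


def som_effects(record: BehavioralRecord, params: RLParams,
                trace: pd.DataFrame | None = None) -> dict:
    """SOM effect sizes of one session, raw and variance-weighted.

    Runs the latent pass, fits the interaction model for S and O ratings,
    and extracts the two SOM interaction coefficients together with the
    context main effects and the appropriate-tracking control betas.
    """
    if trace is None:
        trace = trace_latents(record, params)
    res_S = fit_logistic(build_design(trace, record, "S", "GLM2"))
    res_O = fit_logistic(build_design(trace, record, "O", "GLM2"))
    return {
        "participant_id": record.participant_id,
        "session_id": record.session_id,
        "group": record.group,
        "condition": record.condition,
        "session_order": record.session_order,
        "som_StoO_raw": float(res_O.beta["S_performance_x_context"]),
        "som_StoO_vw": float(res_O.vw_beta["S_performance_x_context"]),
        "som_OtoS_raw": float(res_S.beta["O_performance_x_context"]),
        "som_OtoS_vw": float(res_S.vw_beta["O_performance_x_context"]),
        "context_S_raw": float(res_S.beta["context"]),
        "context_S_vw": float(res_S.vw_beta["context"]),
        "context_O_raw": float(res_O.beta["context"]),
        "context_O_vw": float(res_O.vw_beta["context"]),
        "sperf_S_raw": float(res_S.beta["S_performance"]),
        "operf_O_raw": float(res_O.beta["O_performance"]),
        "n_engage": int(res_S.n_trials),
        "converged": bool(res_S.converged and res_O.converged),
    }


def cohort_som_effects(datasets, params_by_group) -> pd.DataFrame:
    """SOM effects table over a whole cohort.

    ``params_by_group`` maps group label to its fitted RLParams (or is a
    single RLParams applied to every session).  Sessions whose GLMs did
    not converge are kept in the table but flagged; group-level tests
    exclude them.
    """
    rows = []
    n_failed = 0
    for ds in datasets:
        for rec in ds.sessions:
            params = (params_by_group.get(rec.group)
                      if isinstance(params_by_group, dict) else params_by_group)
            try:
                rows.append(som_effects(rec, params))
            except (UnderdeterminedDesignError, DegenerateDesignError) as exc:
                n_failed += 1
                logger.warning("skipping %s/%s: %s", rec.participant_id,
                               rec.session_id, exc)
    if n_failed:
        logger.info("%d sessions could not be estimated", n_failed)
    return pd.DataFrame(rows, columns=EFFECT_COLUMNS)
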