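"""Group-level inference on the SOM effects table.

Baseline analyses pool the unstimulated (no-cTBS) session of every
participant across both groups and run two-sided one-sample t-tests on
the variance-weighted effect sizes.  The stimulation analysis is a
2 (group: dmPFC/vertex) x 2 (condition: cTBS/no-cTBS) mixed-design ANOVA
on the raw S->O SOM coefficient, with the group-by-condition interaction
as the test of a causal stimulation effect, plus the paired t-test within
the dmPFC group.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd
import pingouin as pg
from scipy import stats

from .exceptions import ParameterError

logger = logging.getLogger(__name__)


@dataclass
class GroupTestResult:
    test: str
    statistic: float
    df: float | tuple
    p: float
    n: int
    mean: float = np.nan

    @property
    def direction(self) -> str:
        return "positive" if self.mean > 0 else "negative"

    def to_dict(self) -> dict:
        d = asdict(self)
        if isinstance(d["df"], tuple):
            d["df"] = list(d["df"])
        return d


def _one_sample_t(values: np.ndarray, label: str) -> GroupTestResult:
    values = np.asarray(values, dtype=float)
    values = values[np.isfinite(values)]
    n = len(values)
    if n < 3:
        raise ParameterError(f"{label}: need at least 3 values, got {n}")
    if values.std(ddof=1) == 0.0:
        # degenerate sample: identical values; t is 0 at the null value
        t = 0.0 if values.mean() == 0.0 else np.inf * np.sign(values.mean())
        p = 1.0 if values.mean() == 0.0 else 0.0
    else:
        t, p = stats.ttest_1samp(values, 0.0)
    return GroupTestResult(test=label, statistic=float(t), df=float(n - 1),
                           p=float(p), n=n, mean=float(values.mean()))


def baseline_som_tests(effects: pd.DataFrame) -> dict[str, GroupTestResult]:
    """Baseline SOM and context tests on pooled no-cTBS sessions.

    One-sample two-sided t-tests across participants on the
    variance-weighted SOM interaction coefficients (both directions) and
    on the context main effects of the O- and S-rating models.
    """
    base = effects[(effects["condition"] == "no-cTBS") & effects["converged"]]
    if base["participant_id"].duplicated().any():
        raise ParameterError("more than one no-cTBS session per participant")
    return {
        "som_OtoS": _one_sample_t(base["som_OtoS_vw"], "one-sample t: SOM O->S (vw)"),
        "som_StoO": _one_sample_t(base["som_StoO_vw"], "one-sample t: SOM S->O (vw)"),
        "context_O": _one_sample_t(base["context_O_vw"], "one-sample t: context in O rating (vw)"),
        "context_S": _one_sample_t(base["context_S_vw"], "one-sample t: context in S rating (vw)"),
    }


def ctbs_interaction_test(effects: pd.DataFrame,
                          dv: str = "som_StoO_raw") -> dict[str, GroupTestResult]:
    """Stimulation tests: mixed ANOVA interaction and dmPFC paired t.

    Complete-case: participants missing either session (or with a
    non-converged GLM in either session) are dropped with a logged count.
    """
    ok = effects[effects["converged"]]
    wide = ok.pivot_table(index=["participant_id", "group"], columns="condition",
                          values=dv, aggfunc="first").reset_index()
    complete = wide.dropna(subset=["cTBS", "no-cTBS"])
    n_dropped = len(wide) - len(complete)
    if n_dropped:
        logger.info("dropping %d participants without both sessions", n_dropped)
    if complete["group"].nunique() < 2:
        raise ParameterError("need both groups for the mixed ANOVA")

    long = complete.melt(id_vars=["participant_id", "group"],
                         value_vars=["cTBS", "no-cTBS"],
                         var_name="condition", value_name=dv)
    import warnings as _warnings
    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore", RuntimeWarning)
        aov = pg.mixed_anova(data=long, dv=dv, within="condition",
                             subject="participant_id", between="group")
    inter = aov[aov["Source"] == "Interaction"].iloc[0]
    p_col = "p_unc" if "p_unc" in aov.columns else "p-unc"
    n_total = complete["participant_id"].nunique()
    f_val, p_val = float(inter["F"]), float(inter[p_col])
    cell_vals = complete[["cTBS", "no-cTBS"]].to_numpy()
    if not np.isfinite(f_val) and np.allclose(cell_vals, cell_vals.flat[0]):
        f_val, p_val = 0.0, 1.0  # fully degenerate design: no variance at all
    results = {
        "interaction": GroupTestResult(
            test="mixed ANOVA group x condition",
            statistic=f_val,
            df=(float(inter["DF1"]), float(inter["DF2"])),
            p=p_val, n=n_total),
    }
    for group in complete["group"].unique():
        sub = complete[complete["group"] == group]
        t, p = stats.ttest_rel(sub["cTBS"], sub["no-cTBS"])
        results[f"paired_{group}"] = GroupTestResult(
            test=f"paired t cTBS vs no-cTBS ({group})", statistic=float(t),
            df=float(len(sub) - 1), p=float(p), n=len(sub),
            mean=float((sub["cTBS"] - sub["no-cTBS"]).mean()))
    return results


def mixed_anova_interaction_oracle(wide: pd.DataFrame,
                                   dv_pair=("cTBS", "no-cTBS")) -> float:
    """From-scratch sums-of-squares interaction F for a 2x2 mixed design.

    On a two-level within factor the interaction F equals the two-sample
    t-statistic on per-participant condition differences, squared.  Kept
    here as an exported cross-check, independent of the ANOVA backend.
    """
    diffs = [wide.loc[wide["group"] == g, dv_pair[0]].to_numpy()
             - wide.loc[wide["group"] == g, dv_pair[1]].to_numpy()
             for g in sorted(wide["group"].unique())]
    t, _ = stats.ttest_ind(diffs[0], diffs[1])
    return float(t ** 2)
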