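"""Delta-rule model: elementary operations, session likelihood against an
independent straight-line oracle, grid-checked group fitting, and latent
traces."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst

from somtask import AgentParams, RLParams, simulate_participant
from somtask.exceptions import ParameterError
from somtask.rl_model import (
    BehavioralRecord,
    ev_chosen_and_rpe,
    ev_engage,
    ev_rating,
    fit_group,
    p_engage,
    p_positive_rating,
    session_nll,
    trace_latents,
    update_performance,
)

E_RATIO = math.e / (math.e + 1)  # logistic(1)


class TestElementaryOps:
    @pytest.mark.parametrize("perf,fb,alpha,expected", [
        (5.0, 9.0, 0.5, 7.0),
        (5.0, 9.0, 1.0, 9.0),
        (5.0, 9.0, 0.0, 5.0),
        (12.0, 12.0, 0.37, 12.0),  # zero-PE fixed point
    ])
    def test_update_performance(self, perf, fb, alpha, expected):
        assert update_performance(perf, fb, alpha) == pytest.approx(expected)

    def test_update_rejects_bad_alpha(self):
        with pytest.raises(ParameterError):
            update_performance(5.0, 9.0, 1.5)

    @pytest.mark.parametrize("perf,marker,beta,expected", [
        (8.0, 8.0, 1.0, 0.5),
        (9.0, 8.0, 1.0, E_RATIO),
        (7.0, 8.0, 1.0, 1 - E_RATIO),
        (9.0, 8.0, 500.0, 1.0),   # saturation
    ])
    def test_p_positive_rating(self, perf, marker, beta, expected):
        assert p_positive_rating(perf, marker, beta) == pytest.approx(
            expected, abs=1e-9)

    def test_p_positive_monotone_in_performance(self):
        p = p_positive_rating(np.linspace(1, 15, 30), 8.0, 0.8)
        assert (np.diff(p) > 0).all()

    @pytest.mark.parametrize("p_pos,rating,expected", [
        (1.0, "positive", 0.25),
        (0.0, "positive", -0.25),
        (0.5, "positive", 0.0),
        (0.9, "negative", 0.0),
    ])
    def test_ev_rating(self, p_pos, rating, expected):
        assert ev_rating(p_pos, rating) == pytest.approx(expected)

    @pytest.mark.parametrize("s,o,thr,ctx,expected", [
        (10, 6, 2, -1, 2.0),
        (10, 6, 8, 1, 0.0),
        (5, 5, 0, -1, 0.0),
    ])
    def test_ev_engage(self, s, o, thr, ctx, expected):
        assert ev_engage(s, o, thr, ctx) == pytest.approx(expected)

    @pytest.mark.parametrize("ev,beta,expected", [
        (0.0, 1.0, 0.5),
        (1.0, 1.0, E_RATIO),
        (-1e4, 1.0, 0.0),
    ])
    def test_p_engage(self, ev, beta, expected):
        assert p_engage(ev, beta) == pytest.approx(expected, abs=1e-9)

    @pytest.mark.parametrize("evs,reward,exp_ev,exp_rpe", [
        ((0.0, 0.0, 0.0), 1.5, 0.0, 1.5),        # avoid, both negative
        ((0.1, -0.05, 2.0), 1.5, 2.05, -0.55),
        ((0.2, 0.1, 0.7), 1.0, 1.0, 0.0),
    ])
    def test_ev_chosen_and_rpe(self, evs, reward, exp_ev, exp_rpe):
        ev_c, rpe = ev_chosen_and_rpe(*evs, reward)
        assert ev_c == pytest.approx(exp_ev)
        assert rpe == pytest.approx(exp_rpe)


def _one_trial_record():
    """A record whose three modeled decision probabilities are all 0.5:
    estimates equal the markers and the engage value is zero."""
    starter = {"session_id": "s", "trial_index": 0, "phase": "starter",
               "minigame": "game1", "context": 1, "relevant_other": "O1",
               "threshold": np.nan, "feedback_S": 8, "feedback_O1": 8,
               "feedback_O2": 8, "false_start": False, "has_decisions": False,
               "rating_S": np.nan, "rating_O": np.nan, "marker_S": np.nan,
               "marker_O": np.nan, "choice": None, "payoff": np.nan,
               "reward": np.nan}
    main = dict(starter)
    main.update(trial_index=1, phase="main", threshold=8.0, context=1,
                has_decisions=True, rating_S=1.0, rating_O=-1.0,
                marker_S=8.0, marker_O=8.0, choice="engage", payoff=0.0,
                reward=0.25)
    return BehavioralRecord(trials=pd.DataFrame([starter, main]))


def oracle_session_nll(record, alpha, beta, floor=1e-10):
    """Straight-line re-implementation of the session likelihood.

    Pure-python dict-and-loop version kept deliberately naive and
    independent of the package's vectorized pass.
    """
    df = record.trials
    perf = {}
    for g in ("game1", "game2"):
        st = df[(df["phase"] == "starter") & (df["minigame"] == g)]
        for player, col in (("S", "feedback_S"), ("O1", "feedback_O1"),
                            ("O2", "feedback_O2")):
            vals = st[col].dropna().tolist()
            if vals:
                perf[(player, g)] = float(vals[-1])
    nll = 0.0
    for _, row in df[df["phase"] == "main"].iterrows():
        g = row["minigame"]
        other = row["relevant_other"]
        s_p, o_p = perf[("S", g)], perf[(other, g)]

        def logistic(x):
            if x >= 0:
                return 1.0 / (1.0 + math.exp(-x))
            return math.exp(x) / (1.0 + math.exp(x))

        p_s = logistic(beta * (s_p - row["marker_S"]))
        p_o = logistic(beta * (o_p - row["marker_O"]))
        if row["context"] == -1:
            ev = s_p - o_p - row["threshold"]
        else:
            ev = (s_p + o_p) / 2.0 - row["threshold"]
        p_e = logistic(beta * ev)
        for p, obs in ((p_s, row["rating_S"] > 0),
                       (p_o, row["rating_O"] > 0),
                       (p_e, row["choice"] == "engage")):
            prob = p if obs else 1.0 - p
            nll -= math.log(max(prob, floor))
        for player, col in (("S", "feedback_S"), ("O1", "feedback_O1"),
                            ("O2", "feedback_O2")):
            if player == "S" and row["false_start"]:
                continue
            perf[(player, g)] += alpha * (row[col] - perf[(player, g)])
    return nll


class TestSessionNLL:
    def test_one_trial_closed_form(self):
        rec = _one_trial_record()
        nll = session_nll(rec, RLParams(alpha=0.3, beta=0.8))
        assert nll == pytest.approx(3 * math.log(2), abs=1e-12)

    def test_finite_for_extreme_parameters(self, record):
        for a, b in [(0.0, 20.0), (1.0, 20.0), (0.5, 1e-3)]:
            assert np.isfinite(session_nll(record, RLParams(a, b)))

    @pytest.mark.parametrize("seed", [11, 12, 13, 14, 15])
    def test_matches_independent_oracle(self, filled_schedule, seed):
        """Vectorized likelihood equals the naive loop re-implementation."""
        rng = np.random.default_rng(seed)
        agent = AgentParams(alpha=float(rng.uniform(0.1, 0.9)),
                            beta=float(rng.uniform(0.2, 2.0)),
                            w_som_StoO=float(rng.normal(0, 0.3)),
                            w_som_OtoS=float(rng.normal(0, 0.3)))
        rec = simulate_participant(filled_schedule, agent, seed=seed,
                                   p_false_start=0.05)
        a, b = float(rng.uniform(0.05, 0.95)), float(rng.uniform(0.1, 3.0))
        got = session_nll(rec, RLParams(a, b))
        want = oracle_session_nll(rec, a, b)
        assert got == pytest.approx(want, abs=1e-8)


class TestFitGroup:
    def test_fit_beats_grid_oracle(self, filled_schedule):
        recs = [simulate_participant(filled_schedule,
                                     AgentParams(0.4, 0.9), seed=100 + i)
                for i in range(6)]
        res = fit_group(recs, full_output=True)
        grid = [(a, b)
                for a in np.linspace(0.0, 1.0, 11)
                for b in np.geomspace(0.05, 10.0, 11)]
        grid_best = min(sum(session_nll(r, RLParams(a, b)) for r in recs)
                        for a, b in grid)
        assert res.nll <= grid_best + 1e-6

    def test_duplicating_records_leaves_argmin_unchanged(self, filled_schedule):
        recs = [simulate_participant(filled_schedule,
                                     AgentParams(0.3, 0.8), seed=i)
                for i in range(4)]
        p1 = fit_group(recs)
        p2 = fit_group(recs * 2)
        assert p2.alpha == pytest.approx(p1.alpha, abs=1e-3)
        assert p2.beta == pytest.approx(p1.beta, abs=1e-3)

    def test_empty_group_rejected(self):
        with pytest.raises(ParameterError):
            fit_group([])


class TestTraceLatents:
    def test_alpha_zero_freezes_estimates(self, record):
        tr = trace_latents(record, RLParams(alpha=0.0, beta=0.8))
        main = record.main()
        for g in ("game1", "game2"):
            sel = (main["minigame"] == g).to_numpy()
            vals = tr.loc[sel, "S_performance"].to_numpy()
            assert np.allclose(vals, vals[0])

    def test_alpha_one_tracks_previous_feedback(self, record):
        tr = trace_latents(record, RLParams(alpha=1.0, beta=0.8))
        main = record.main().reset_index(drop=True)
        for g in ("game1", "game2"):
            idx = main.index[main["minigame"] == g].to_numpy()
            fb = main.loc[idx, "feedback_S"].to_numpy(dtype=float)
            est = tr.loc[idx, "S_performance"].to_numpy()
            assert np.allclose(est[1:], fb[:-1])

    def test_trace_is_deterministic_and_aligned(self, record, params):
        t1 = trace_latents(record, params)
        t2 = trace_latents(record, params)
        pd.testing.assert_frame_equal(t1, t2)
        assert len(t1) == len(record.main())

    def test_false_start_has_no_self_pe(self, filled_schedule):
        rec = simulate_participant(filled_schedule, AgentParams(0.3, 0.8),
                                   seed=42, p_false_start=0.2)
        tr = trace_latents(rec, RLParams(0.3, 0.8))
        fs = rec.main()["false_start"].to_numpy(dtype=bool)
        assert fs.any()
        assert tr.loc[fs, "PE_S"].isna().all()
        assert tr.loc[fs, "PE_O"].notna().all()

    def test_rpe_identity(self, record, params):
        tr = trace_latents(record, params)
        reward = record.main()["reward"].to_numpy(dtype=float)
        assert np.allclose(tr["RPE"], reward - tr["EV_chosen"])


class TestModelProperties:
    @settings(deadline=None, derandomize=True, max_examples=25)
    @given(alpha=hst.floats(0.0, 1.0), init=hst.floats(1.0, 15.0),
           seed=hst.integers(0, 10_000))
    def test_estimates_stay_in_feedback_hull(self, alpha, init, seed):
        """Convexity of the delta rule keeps estimates inside [1, 15]."""
        rng = np.random.default_rng(seed)
        perf = init
        for fb in rng.integers(1, 16, size=50):
            perf = update_performance(perf, float(fb), alpha)
            assert 1.0 <= perf <= 15.0

    def test_single_trial_beta_likelihood_monotonicity(self):
        """On a single-softmax record the nll at the closed-form optimal
        beta never exceeds the nll at any other beta."""
        rec = _one_trial_record()
        nlls = {b: session_nll(rec, RLParams(0.3, b))
                for b in (0.01, 0.5, 1.0, 5.0)}
        # all three probabilities are exactly 0.5 regardless of beta here,
        # so the likelihood is flat: every beta attains the optimum
        assert max(nlls.values()) == pytest.approx(min(nlls.values()))
        # tilt the record so the observed decisions are the likely ones:
        df = rec.trials.copy()
        df.loc[1, "marker_S"] = 6.5   # estimate 8 > marker, rated positive
        df.loc[1, "rating_O"] = 1.0
        df.loc[1, "marker_O"] = 6.5
        df.loc[1, "threshold"] = 6.0  # engage value 2 > 0, engaged
        tilted = BehavioralRecord(trials=df)
        nll_small = session_nll(tilted, RLParams(0.3, 0.1))
        nll_large = session_nll(tilted, RLParams(0.3, 10.0))
        assert nll_large < nll_small
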