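import numpy as np
import pandas as pd
import pytest

from predinfer import (
    AgentProfile,
    ObserverConfig,
    compare_betas,
    fit_action_model,
    fit_all_subjects,
    fit_confidence_model,
    fit_coupling_model,
    median_r_squared,
    run_observer,
    simulate_agent,
)
from predinfer.metrics import add_derived_columns, derive_trial_metrics

from oracles import ols_by_gradient


def _derived_with_trace(session, profile, seed, subject="S0"):
    df = simulate_agent(profile, session, seed=seed)
    df["subject_id"] = subject
    trace = run_observer(session.outcome,
                         ObserverConfig(noise_var=session.config.noise_sd**2),
                         block=session.block)
    tf = trace.to_frame().rename(columns={"delta": "model_delta",
                                          "learning_rate": "model_learning_rate"})
    d = derive_trial_metrics(pd.concat([df, tf], axis=1))
    return add_derived_columns(d)


class TestActionModel:
    def test_exact_fixed_alpha_construction(self, session):
        d = _derived_with_trace(
            session, AgentProfile(policy="fixed-alpha", fixed_alpha=0.5,
                                  motor_noise_sd=0.0), seed=1)
        res = fit_action_model(d)
        assert res.r_squared == pytest.approx(1.0, abs=1e-10)
        assert res.betas["abs_delta"] == pytest.approx(0.5, abs=1e-8)
        for name in ("cpp_x_abs_delta", "ru_x_abs_delta", "hit_x_abs_delta",
                     "intercept"):
            assert res.betas[name] == pytest.approx(0.0, abs=1e-7)

    def test_block_final_trials_reduce_n(self, session):
        d = _derived_with_trace(session, AgentProfile(motor_noise_sd=0.0), seed=2)
        res = fit_action_model(d)
        n_blocks = session.config.n_blocks
        assert res.n_trials_used == session.n_trials - n_blocks

    def test_parameter_recovery(self, session):
        """Responses built as 0.2|d| + 0.6*CPP|d| + noise recover both betas."""
        rng = np.random.default_rng(3)
        recovered = []
        for _ in range(30):
            d = _derived_with_trace(session, AgentProfile(motor_noise_sd=0.0), seed=4)
            keep = ~d.excluded
            y = (0.2 * d.abs_delta + 0.6 * d.cpp * d.abs_delta
                 + rng.normal(0, 2.0, len(d)))
            d = d.copy()
            d["alpha"] = y / d["abs_delta"]
            recovered.append(fit_action_model(d).betas)
        mean_b = pd.DataFrame(recovered).mean()
        assert mean_b["abs_delta"] == pytest.approx(0.2, abs=0.05)
        assert mean_b["cpp_x_abs_delta"] == pytest.approx(0.6, abs=0.05)

    def test_residual_orthogonality(self, session):
        d = _derived_with_trace(session, AgentProfile(), seed=5)
        res = fit_action_model(d)
        keep = ~d.excluded
        y = (d.alpha * d.abs_delta)[keep].to_numpy()
        cols = {
            "abs_delta": d.abs_delta[keep].to_numpy(),
            "cpp_x_abs_delta": (d.cpp * d.abs_delta)[keep].to_numpy(),
            "ru_x_abs_delta": (d.relative_uncertainty * d.abs_delta)[keep].to_numpy(),
            "hit_x_abs_delta": (d.hit * d.abs_delta)[keep].to_numpy(),
        }
        fitted = res.betas["intercept"] + sum(res.betas[k] * v for k, v in cols.items())
        resid = y - fitted
        scale = np.abs(y).max()
        for v in cols.values():
            assert abs(resid @ v) / (scale * np.abs(v).max() * len(y)) < 1e-8

    def test_matches_gradient_descent_oracle(self, rng):
        y = rng.normal(size=40)
        X = rng.normal(size=(40, 3))
        d = pd.DataFrame({
            "subject_id": "S0", "block": 0, "trial": np.arange(40),
            "outcome": 0.0, "bucket": 0.0, "excluded": False,
            "abs_delta": X[:, 0] + 5, "cpp": rng.random(40),
            "relative_uncertainty": rng.random(40), "hit": rng.integers(0, 2, 40),
            "alpha": 0.0,
        })
        d["alpha"] = y / d["abs_delta"]
        res = fit_action_model(d)
        Xd = np.column_stack([
            d.abs_delta, d.cpp * d.abs_delta,
            d.relative_uncertainty * d.abs_delta, d.hit * d.abs_delta])
        beta_gd = ols_by_gradient(y, Xd)
        got = [res.betas["intercept"], res.betas["abs_delta"],
               res.betas["cpp_x_abs_delta"], res.betas["ru_x_abs_delta"],
               res.betas["hit_x_abs_delta"]]
        np.testing.assert_allclose(got, beta_gd, atol=1e-8)


class TestConfidenceModel:
    def test_first_trials_dropped_bookkeeping(self, session):
        d = _derived_with_trace(session, AgentProfile(), seed=6)
        res = fit_confidence_model(d)
        assert res.n_trials_used == session.n_trials - session.config.n_blocks

    def test_parameter_recovery_cpp_slope(self, session):
        """Confidence built as -0.5*CPP_{t-1} + noise recovers the beta."""
        rng = np.random.default_rng(7)
        betas = []
        for _ in range(40):
            d = _derived_with_trace(session, AgentProfile(), seed=8)
            cpp_prev = d.groupby("block")["cpp"].shift(1)
            z = -0.5 * cpp_prev.fillna(0) + rng.normal(0, 0.1, len(d))
            d = d.copy()
            d["z_confidence"] = z
            betas.append(fit_confidence_model(d).betas["cpp_prev"])
        assert np.mean(betas) == pytest.approx(-0.5, abs=0.05)

    def test_null_betas_cover_zero(self, session):
        """With confidence independent of the predictors, betas scatter
        around zero."""
        rng = np.random.default_rng(9)
        betas = []
        for _ in range(40):
            d = _derived_with_trace(session, AgentProfile(), seed=10)
            d = d.copy()
            d["z_confidence"] = rng.normal(size=len(d))
            betas.append(fit_confidence_model(d).betas["cpp_prev"])
        assert abs(np.mean(betas)) < 0.15


class TestCouplingModel:
    def test_exact_two_to_one_construction(self):
        rng = np.random.default_rng(11)
        z = np.cumsum(rng.normal(0, 0.3, 50))
        conf_update = np.abs(np.diff(z))
        bucket = np.concatenate([[0.0], np.cumsum(2 * conf_update)]) % 360
        d = pd.DataFrame({"subject_id": "S0", "block": 0, "trial": np.arange(50),
                          "bucket": bucket, "z_confidence": z})
        res = fit_coupling_model(d)
        assert res.betas["abs_conf_update"] == pytest.approx(2.0, abs=1e-9)
        assert res.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_independent_streams_slope_near_zero(self, rng):
        slopes = []
        for _ in range(100):
            d = pd.DataFrame({
                "subject_id": "S0", "block": 0, "trial": np.arange(80),
                "bucket": rng.uniform(0, 360, 80),
                "z_confidence": rng.normal(size=80)})
            slopes.append(fit_coupling_model(d).betas["abs_conf_update"])
        assert abs(np.mean(slopes)) < 5.0  # |action update| ~ 90 deg scale

    def test_constant_confidence_rejected(self):
        d = pd.DataFrame({"subject_id": "S0", "block": 0, "trial": np.arange(10),
                          "bucket": np.linspace(0, 90, 10),
                          "z_confidence": np.zeros(10)})
        with pytest.raises(ValueError):
            fit_coupling_model(d)


class TestGroupComparison:
    def _results_frame(self, values_by_group):
        rows = []
        gmap = {}
        i = 0
        for g, vals in values_by_group.items():
            for v in vals:
                sid = f"S{i}"
                rows.append({"subject_id": sid, "model": "action",
                             "beta_abs_delta": v, "r_squared": 0.5})
                gmap[sid] = g
                i += 1
        return pd.DataFrame(rows), gmap

    def test_identical_groups_give_t0_p1(self):
        vals = [0.1, 0.2, 0.3, 0.4]
        res_df, gmap = self._results_frame({"A": vals, "B": vals})
        res = compare_betas(res_df, gmap, "action", "abs_delta")
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_unequal_variances_route_to_welch(self, rng):
        chosen = []
        for _ in range(100):
            a = rng.normal(0, 1, 30)
            b = rng.normal(0, np.sqrt(10), 30)
            res_df, gmap = self._results_frame({"A": a, "B": b})
            chosen.append(compare_betas(res_df, gmap, "action", "abs_delta").test_name)
        welch_or_ranksum = sum(t in ("welch_t", "wilcoxon_rank_sum") for t in chosen)
        welch = sum(t == "welch_t" for t in chosen)
        assert welch_or_ranksum > 90
        assert welch > 50  # Welch specifically dominates for normal data

    def test_median_r_squared(self):
        res_df, gmap = self._results_frame({"A": [1, 2, 3]})
        res_df["r_squared"] = [0.1, 0.5, 0.9]
        med = median_r_squared(res_df, gmap, "action")
        assert med["A"] == pytest.approx(0.5)


class TestSmallPERefit:
    def test_runs_and_keeps_contracts(self, session):
        d = _derived_with_trace(session, AgentProfile(), seed=12)
        d = add_derived_columns(derive_trial_metrics(d))
        full = fit_all_subjects(d)
        small = fit_all_subjects(d, small_pe_only=True)
        assert set(small.model) <= {"action", "confidence"}
        n_small_action = small.loc[small.model == "action", "n_trials_used"].iloc[0]
        n_full_action = full.loc[full.model == "action", "n_trials_used"].iloc[0]
        assert 0 < n_small_action < n_full_action
        assert small.r_squared.between(0, 1).all()
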