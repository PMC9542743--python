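import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from socialsampling import metrics
from socialsampling.metrics import (
    SchemaError,
    SingularDesignError,
    UndefinedCorrelationError,
    analysis_rows,
    correlate,
    ideal_posterior,
    model_mse,
    popularity,
    regress_popularity,
)


class TestPopularity:
    def test_all_ones(self):
        assert popularity(np.ones((5, 3)), feature=0) == 1.0

    def test_count_over_size(self):
        decisions = np.zeros((20, 1))
        decisions[:13] = 1
        assert popularity(decisions, feature=0) == pytest.approx(0.65)

    def test_permutation_invariance(self, rng):
        decisions = rng.integers(0, 2, (20, 4))
        perm = rng.permutation(20)
        np.testing.assert_allclose(popularity(decisions), popularity(decisions[perm]))

    def test_empty_generation(self):
        with pytest.raises(ValueError):
            popularity(np.zeros((0, 3)))


def brute_force_posterior(outcomes, theta1, theta0):
    """Two-hypothesis Bayes enumeration over an explicit outcome sequence."""
    p1 = p0 = 0.5
    for y in outcomes:
        p1 *= theta1 if y else 1 - theta1
        p0 *= theta0 if y else 1 - theta0
    return p1 / (p1 + p0)


class TestIdealPosterior:
    def test_no_evidence_is_uniform(self):
        assert ideal_posterior(0, 0, 4, 0.6, 0.3) == 0.5

    def test_equal_thetas_uninformative(self):
        for s in range(9):
            assert ideal_posterior(s, 2, 4, 0.4, 0.4) == pytest.approx(0.5)

    def test_against_brute_force(self):
        seq = [1, 1, 1, 0]
        expected = brute_force_posterior(seq, 0.6, 0.3)
        assert ideal_posterior(3, 1, 4, 0.6, 0.3) == pytest.approx(expected, rel=1e-12)

    def test_exhaustive_enumeration_small_sequences(self):
        # every binary sequence with up to 8 outcomes, several thetas
        for theta1, theta0 in [(0.6, 0.3), (0.8, 0.2), (0.55, 0.5)]:
            for length in range(1, 9):
                for seq in itertools.product((0, 1), repeat=length):
                    expected = brute_force_posterior(seq, theta1, theta0)
                    got = ideal_posterior(sum(seq), length, 1, theta1, theta0)
                    assert got == pytest.approx(expected, rel=1e-12)

    def test_out_of_range(self):
        with pytest.raises(ValueError):
            ideal_posterior(5, 1, 4, 0.6, 0.3)

    def test_strictly_increasing_in_evidence(self):
        vals = [ideal_posterior(s, 2, 4, 0.6, 0.3) for s in range(9)]
        assert all(a < b for a, b in zip(vals, vals[1:]))

    @settings(max_examples=100, deadline=None)
    @given(s=st.integers(0, 8), t1=st.floats(0.05, 0.95), t0=st.floats(0.05, 0.95))
    def test_complement_identity(self, s, t1, t0):
        # swapping hypotheses and relabeling outcomes maps the posterior to itself
        direct = ideal_posterior(s, 2, 4, t1, t0)
        swapped = ideal_posterior(8 - s, 2, 4, 1 - t1, 1 - t0)
        assert direct == pytest.approx(swapped, rel=1e-9)

    def test_extreme_counts_stay_finite(self):
        val = ideal_posterior(400, 100, 4, 0.6, 0.3)
        assert 0.0 <= val <= 1.0 and np.isfinite(val)


class TestCorrelate:
    def test_perfect_positive(self):
        rows = pd.DataFrame({"x": [1.0, 2, 3, 4], "y": [2.0, 4, 6, 8]})
        res = correlate(rows, "x", "y")
        assert res.r == pytest.approx(1.0)
        assert res.df == 2

    def test_perfect_negative(self):
        rows = pd.DataFrame({"x": [1.0, 2, 3, 4], "y": [-1.0, -2, -3, -4]})
        assert correlate(rows, "x", "y").r == pytest.approx(-1.0)

    def test_hand_computation(self):
        x = np.array([0.2, 0.4, 0.1, 0.9, 0.6])
        y = np.array([0.3, 0.1, 0.2, 0.8, 0.9])
        rows = pd.DataFrame({"x": x, "y": y})
        # direct evaluation of the product-moment formula
        xc, yc = x - x.mean(), y - y.mean()
        expected = (xc * yc).sum() / np.sqrt((xc**2).sum() * (yc**2).sum())
        res = correlate(rows, "x", "y")
        assert res.r == pytest.approx(expected, rel=1e-12)
        assert res.df == 3

    def test_zero_variance(self):
        rows = pd.DataFrame({"x": [1.0, 1, 1, 1], "y": [1.0, 2, 3, 4]})
        with pytest.raises(UndefinedCorrelationError):
            correlate(rows, "x", "y")

    def test_too_few_rows(self):
        rows = pd.DataFrame({"x": [1.0, 2], "y": [3.0, 4]})
        with pytest.raises(UndefinedCorrelationError):
            correlate(rows, "x", "y")


def synthetic_regression_rows(rng, n=60, noise=0.0, slope_total=0.4, slope_last=0.2):
    rows = pd.DataFrame({
        "total_evidence_fraction": rng.random(n),
        "last_evidence_fraction": rng.random(n),
        "network": rng.integers(0, 3, n),
    })
    effects = np.array([0.0, 0.05, -0.05])[rows["network"]]
    rows["popularity"] = (
        0.1
        + slope_total * rows["total_evidence_fraction"]
        + slope_last * rows["last_evidence_fraction"]
        + effects
        + noise * rng.standard_normal(n)
    )
    return rows


class TestRegression:
    def test_exact_linear_recovery(self, rng):
        rows = synthetic_regression_rows(rng, noise=0.0)
        fit = regress_popularity(rows)
        assert fit.params["total_evidence_fraction"] == pytest.approx(0.4, abs=1e-10)
        assert fit.params["last_evidence_fraction"] == pytest.approx(0.2, abs=1e-10)
        assert np.abs(fit.resid).max() < 1e-10

    def test_row_order_invariance(self, rng):
        rows = synthetic_regression_rows(rng, noise=0.05)
        fit_a = regress_popularity(rows)
        fit_b = regress_popularity(rows.sample(frac=1.0, random_state=1))
        pd.testing.assert_series_equal(fit_a.params, fit_b.params, atol=1e-10)

    def test_normal_equations_oracle(self):
        # hand-computed least squares on a fixed 10-row fixture
        rng = np.random.default_rng(77)
        rows = synthetic_regression_rows(rng, n=10, noise=0.1)
        rows["network"] = [0, 1, 2, 0, 1, 2, 0, 1, 2, 0]
        rows["popularity"] += np.array([0.0, 0.05, -0.05])[rows["network"]]
        fit = regress_popularity(rows)
        x = np.column_stack([
            np.ones(10),
            rows["total_evidence_fraction"],
            rows["last_evidence_fraction"],
            (rows["network"] == 1).astype(float),
            (rows["network"] == 2).astype(float),
        ])
        y = rows["popularity"].to_numpy()
        beta = np.linalg.solve(x.T @ x, x.T @ y)
        np.testing.assert_allclose(
            fit.params.to_numpy(),
            [beta[0], beta[1], beta[2], beta[3], beta[4]],
            atol=1e-10,
        )
        assert fit.df_resid == 10 - 5

    def test_rank_deficiency_raises(self, rng):
        rows = synthetic_regression_rows(rng)
        rows["last_evidence_fraction"] = rows["total_evidence_fraction"]
        with pytest.raises(SingularDesignError):
            regress_popularity(rows)


def make_mse_rows(rng, n=50):
    p_prev = rng.random(n)
    return pd.DataFrame({
        "popularity": p_prev,  # equal to p_prev: naive copying is exact
        "p_prev": p_prev,
        "s_last": rng.integers(0, 5, n),
        "j_last": 4,
    })


class TestModelMSE:
    def test_perfect_prediction_gives_zero(self, rng):
        rows = make_mse_rows(rng)
        out = model_mse(rows, model_ids=["naive_copy"], theta1=0.6, theta0=0.3)
        assert out.loc[0, "mse"] == 0.0

    def test_naive_copy_algebraic_identity(self, rng):
        rows = make_mse_rows(rng)
        rows["popularity"] = rng.random(len(rows))
        out = model_mse(rows, model_ids=["naive_copy"], theta1=0.6, theta0=0.3)
        expected = np.mean((rows["p_prev"] - rows["popularity"]) ** 2)
        assert out.loc[0, "mse"] == pytest.approx(expected)

    def test_row_order_and_duplication_invariance(self, rng):
        rows = make_mse_rows(rng)
        rows["popularity"] = rng.random(len(rows))
        base = model_mse(rows, theta1=0.6, theta0=0.3)
        shuffled = model_mse(
            rows.sample(frac=1.0, random_state=0), theta1=0.6, theta0=0.3
        )
        doubled = model_mse(
            pd.concat([rows, rows], ignore_index=True), theta1=0.6, theta0=0.3
        )
        pd.testing.assert_frame_equal(base, shuffled)
        pd.testing.assert_frame_equal(base, doubled)

    def test_ranking_sorted_ascending(self, rng):
        rows = make_mse_rows(rng)
        out = model_mse(rows, theta1=0.6, theta0=0.3)
        assert out["mse"].is_monotonic_increasing
        assert list(out["rank"]) == list(range(1, len(out) + 1))

    def test_missing_p_prev_raises(self, rng):
        rows = make_mse_rows(rng).drop(columns="p_prev")
        with pytest.raises(SchemaError):
            model_mse(rows, theta1=0.6, theta0=0.3)

    def test_censored_naive_copy_unaffected(self, rng):
        rows = make_mse_rows(rng)
        rows["popularity"] = rng.random(len(rows))
        plain = model_mse(rows, model_ids=["naive_copy"], theta1=0.6, theta0=0.3)
        cens = model_mse(
            rows, model_ids=["naive_copy"], censored=True, theta1=0.6, theta0=0.3
        )
        assert plain.loc[0, "mse"] == cens.loc[0, "mse"]


class TestAnalysisRows:
    def test_exp1_layout_shape_and_fields(self, exp1_bayes_result):
        rows = analysis_rows(
            exp1_bayes_result.decisions_frame(),
            exp1_bayes_result.evidence_frame(),
            theta1=0.6, theta0=0.3, evidence_timing="current",
        )
        assert len(rows) == 432
        assert rows["total_evidence_fraction"].between(0, 1).all()
        assert rows["last_evidence_fraction"].between(0, 1).all()
        assert rows["ideal_posterior"].between(0, 1).all()
        assert rows["p_prev"].notna().all()

    def test_matches_trajectory(self, exp1_bayes_result):
        rows = analysis_rows(
            exp1_bayes_result.decisions_frame(),
            exp1_bayes_result.evidence_frame(),
            theta1=0.6, theta0=0.3,
        )
        traj = exp1_bayes_result.trajectory_frame()
        merged = rows.merge(
            traj, on=["network", "condition", "trial", "feature", "generation"],
            suffixes=("", "_traj"),
        )
        assert len(merged) == len(rows)
        np.testing.assert_allclose(merged["popularity"], merged["popularity_traj"])
        np.testing.assert_allclose(merged["s_cum"], merged["s_cum_traj"])
        np.testing.assert_allclose(
            merged["ideal_posterior"], merged["ideal_posterior_traj"]
        )

    def test_empty_decisions_rejected(self, exp1_bayes_result):
        empty = exp1_bayes_result.decisions_frame().iloc[0:0]
        with pytest.raises(SchemaError):
            analysis_rows(
                empty, exp1_bayes_result.evidence_frame(), theta1=0.6, theta0=0.3
            )

    def test_missing_column_rejected(self, exp1_bayes_result):
        bad = exp1_bayes_result.decisions_frame().drop(columns="decision")
        with pytest.raises(SchemaError, match="decision"):
            analysis_rows(
                bad, exp1_bayes_result.evidence_frame(), theta1=0.6, theta0=0.3
            )
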