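"""Likelihood, σ-profiling, 2-dpf convention, fitting, CIs, model comparison."""

import numpy as np
import pandas as pd
import pytest
from scipy.linalg import expm

from rheostat import (
    RheostatModel,
    SyntheticDesign,
    ValidationError,
    assess_fit,
    ci95,
    compare_variants,
    generate_measurements,
    make_problem,
    negative_log_likelihood,
    set_initial_from_data,
    sigma_mle,
)
from rheostat.calibration import fit as fit_problem
from rheostat.kinetics import EXTENDED_SPECIES, extended_system_matrices

from conftest import truth_theta

LN2PI = float(np.log(2 * np.pi))


def noise_free_table(truth, n_replicates=2, times=(2.0, 4.0), observables=None):
    """Measurement table with values exactly equal to s_i·x_i(t)."""
    observables = observables or ("sphinganine", "ceramide", "sphingosine")
    rows = []
    from rheostat.calibration import DEFAULT_CONDITIONS

    for cond in DEFAULT_CONDITIONS:
        states = truth.states(cond, times)
        for t, x in zip(times, states):
            for obs in observables:
                i = EXTENDED_SPECIES.index(obs)
                for r in range(n_replicates):
                    rows.append(
                        (obs, cond.condition_id, float(t), r,
                         truth.scalings[obs] * x[i])
                    )
    return pd.DataFrame(
        rows, columns=["observable_id", "condition_id", "time_dpf", "replicate", "value"]
    )


@pytest.fixture
def noisy_measurements(shared_s1p_truth):
    return generate_measurements(shared_s1p_truth, SyntheticDesign(), seed=123)


class TestNegativeLogLikelihood:
    def test_zero_residuals_eight_measurements(self, shared_s1p_truth):
        """With all residuals zero and σ=1, each of 8 measurements
        contributes ½ln(2π): NLL = 4·ln(2π) ≈ 7.3510."""
        table = noise_free_table(shared_s1p_truth, n_replicates=1)
        # 1 replicate × 3 obs × 2 cond × 2 times = 12 rows; trim to 8 by
        # dropping one observable's 4 dpf rows — residuals stay zero
        table = table[~(table.observable_id.isin(["sphingosine", "sphinganine"]) &
                        (table.time_dpf == 4.0))].reset_index(drop=True)
        assert len(table) == 8
        problem = make_problem(table, "feedback")
        theta = truth_theta(shared_s1p_truth)
        for o in ("sphinganine", "ceramide", "sphingosine"):
            theta[f"sigma_{o}"] = 1.0
        nll = negative_log_likelihood(theta, problem)
        assert nll == pytest.approx(4 * LN2PI, abs=1e-8)
        assert nll == pytest.approx(7.35151, abs=5e-5)

        theta2 = dict(theta)
        for o in ("sphinganine", "ceramide", "sphingosine"):
            theta2[f"sigma_{o}"] = 2.0
        assert negative_log_likelihood(theta2, problem) - nll == pytest.approx(
            8 * np.log(2), abs=1e-8
        )

    def test_matches_term_by_term_oracle(self, shared_s1p_truth, noisy_measurements):
        """Sum over measurements of ½ln2π + lnσ + (s·x(t) − m)²/2σ², with the
        state recomputed here from the matrix exponential."""
        problem = make_problem(noisy_measurements, "feedback")
        theta = truth_theta(shared_s1p_truth)
        nll = negative_log_likelihood(theta, problem)

        expected = 0.0
        for _, row in noisy_measurements.iterrows():
            cond = next(c for c in problem.conditions
                        if c.condition_id == row.condition_id)
            A, b = extended_system_matrices(shared_s1p_truth.params, cond.s_on)
            base = noisy_measurements[
                (noisy_measurements.time_dpf == 2.0)
                & (noisy_measurements.condition_id == row.condition_id)
            ]
            x0 = np.zeros(4)
            for i, sp in enumerate(EXTENDED_SPECIES):
                if sp == "s1p":
                    x0[i] = theta["x0_s1p"]
                else:
                    x0[i] = base[base.observable_id == sp].value.mean() / theta[f"s_{sp}"]
            t = row.time_dpf - 2.0
            x = x0 if t == 0 else expm(A * t) @ x0 + np.linalg.solve(A, (expm(A * t) - np.eye(4)) @ b)
            sp_i = EXTENDED_SPECIES.index(row.observable_id)
            pred = theta[f"s_{row.observable_id}"] * x[sp_i]
            sig = theta[f"sigma_{row.observable_id}"]
            expected += 0.5 * LN2PI + np.log(sig) + (pred - row.value) ** 2 / (2 * sig**2)
        assert nll == pytest.approx(expected, abs=1e-9)

    def test_removing_a_measurement_removes_exactly_its_term(
        self, shared_s1p_truth, noisy_measurements
    ):
        problem = make_problem(noisy_measurements, "feedback")
        theta = truth_theta(shared_s1p_truth)
        full = negative_log_likelihood(theta, problem)
        # drop a 4 dpf row (2 dpf rows enter the initial condition)
        idx = noisy_measurements.index[noisy_measurements.time_dpf == 4.0][5]
        row = noisy_measurements.loc[idx]
        reduced = make_problem(noisy_measurements.drop(idx), "feedback")
        part = negative_log_likelihood(theta, reduced)
        from rheostat.calibration import _predict_observables

        pred = _predict_observables(problem, theta)
        p = pred[
            (pred.observable_id == row.observable_id)
            & (pred.condition_id == row.condition_id)
            & (pred.time_dpf == row.time_dpf)
        ].predicted.iloc[0]
        sig = theta[f"sigma_{row.observable_id}"]
        term = 0.5 * LN2PI + np.log(sig) + (p - row.value) ** 2 / (2 * sig**2)
        assert full - part == pytest.approx(term, abs=1e-10)

    def test_nonpositive_sigma_rejected(self, shared_s1p_truth, noisy_measurements):
        problem = make_problem(noisy_measurements, "feedback")
        theta = truth_theta(shared_s1p_truth)
        theta["sigma_ceramide"] = 0.0
        with pytest.raises(ValidationError, match="sigma_ceramide"):
            negative_log_likelihood(theta, problem)


class TestInitialFromData:
    def test_mean_over_scaling(self, shared_s1p_truth):
        table = noise_free_table(shared_s1p_truth, n_replicates=2)
        # replace wild-type 2 dpf ceramide replicates with {4, 6}
        m = (table.observable_id == "ceramide") & (table.condition_id == "wild_type") \
            & (table.time_dpf == 2.0)
        table.loc[m, "value"] = [4.0, 6.0]
        problem = make_problem(table, "feedback")
        theta = truth_theta(shared_s1p_truth)
        theta["s_ceramide"] = 2.0
        x0 = set_initial_from_data(problem, theta)
        assert x0["wild_type"][EXTENDED_SPECIES.index("ceramide")] == pytest.approx(2.5)

    def test_two_dpf_prediction_equals_sample_mean(self, noisy_measurements):
        problem = make_problem(noisy_measurements, "feedback")
        theta = problem.nominal_theta()
        from rheostat.calibration import _predict_observables

        pred = _predict_observables(problem, theta)
        means = noisy_measurements[noisy_measurements.time_dpf == 2.0].groupby(
            ["observable_id", "condition_id"]
        )["value"].mean()
        sub = pred[pred.time_dpf == 2.0]
        for _, r in sub.iterrows():
            assert r.predicted == pytest.approx(
                means[(r.observable_id, r.condition_id)], rel=1e-12
            )

    def test_scaling_leaves_observable_invariant(self, shared_s1p_truth, noisy_measurements):
        problem = make_problem(noisy_measurements, "feedback")
        theta = truth_theta(shared_s1p_truth)
        x0_a = set_initial_from_data(problem, theta)
        theta_b = dict(theta)
        theta_b["s_ceramide"] *= 3.0
        x0_b = set_initial_from_data(problem, theta_b)
        i = EXTENDED_SPECIES.index("ceramide")
        for cond in ("wild_type", "mutant"):
            assert x0_b[cond][i] == pytest.approx(x0_a[cond][i] / 3.0)
            assert theta_b["s_ceramide"] * x0_b[cond][i] == pytest.approx(
                theta["s_ceramide"] * x0_a[cond][i]
            )

    def test_missing_baseline_is_configuration_error(self, noisy_measurements):
        broken = noisy_measurements[
            ~((noisy_measurements.observable_id == "ceramide")
              & (noisy_measurements.time_dpf == 2.0)
              & (noisy_measurements.condition_id == "mutant"))
        ]
        problem = make_problem(broken, "feedback")
        with pytest.raises(ValidationError, match="ceramide"):
            set_initial_from_data(problem, problem.nominal_theta())


class TestSigmaMLE:
    def test_closed_form(self):
        assert sigma_mle([1.0, -1.0, 1.0, -1.0]) == pytest.approx(1.0)
        assert sigma_mle([0.0, 0.0]) == 0.0
        with pytest.raises(ValidationError):
            sigma_mle([])

    def test_grid_search_attains_minimum_at_mle(self, rng):
        r = rng.normal(0, 2.0, 40)
        shat = sigma_mle(r)

        def nll(sig):
            return np.sum(0.5 * LN2PI + np.log(sig) + r**2 / (2 * sig**2))

        grid = np.linspace(0.5 * shat, 2.0 * shat, 2001)
        best = grid[np.argmin([nll(s) for s in grid])]
        assert best == pytest.approx(shat, rel=1e-3)


class TestCI95:
    def test_zero_variance_degenerates_to_point(self):
        df = pd.DataFrame(
            {"observable_id": "ceramide", "condition_id": "wild_type",
             "time_dpf": 2.0, "replicate": range(4), "value": 1.0}
        )
        ci = ci95(df)
        assert ci.ci_low.iloc[0] == ci.ci_high.iloc[0] == pytest.approx(1.0)

    def test_two_replicates_t_interval(self):
        """{0, 2}: mean 1, half-width t₀.₉₇₅,₁·sd/√2 = 12.7062·1 = 12.7062."""
        df = pd.DataFrame(
            {"observable_id": "x", "condition_id": "c", "time_dpf": 2.0,
             "replicate": [0, 1], "value": [0.0, 2.0]}
        )
        ci = ci95(df)
        assert ci["mean"].iloc[0] == pytest.approx(1.0)
        assert ci.ci_high.iloc[0] - ci["mean"].iloc[0] == pytest.approx(12.7062, abs=1e-4)

    def test_interval_contains_mean(self, noisy_measurements):
        for method in ("t", "bootstrap"):
            ci = ci95(noisy_measurements, method=method, seed=1)
            assert ((ci.ci_low <= ci["mean"]) & (ci["mean"] <= ci.ci_high)).all()

    def test_single_replicate_rejected(self):
        df = pd.DataFrame(
            {"observable_id": "x", "condition_id": "c", "time_dpf": 2.0,
             "replicate": [0], "value": [1.0]}
        )
        with pytest.raises(ValidationError, match="replicate"):
            ci95(df)


class TestFit:
    def test_deterministic_given_seed(self, noisy_measurements):
        problem = make_problem(noisy_measurements, "feedback")
        a = fit_problem(problem, n_starts=3, seed=11, maxiter=60)
        b = fit_problem(problem, n_starts=3, seed=11, maxiter=60)
        pd.testing.assert_series_equal(a.theta_hat, b.theta_hat)
        assert a.nll == b.nll
        np.testing.assert_array_equal(a.start_nlls, b.start_nlls)

    def test_noise_free_truth_is_not_beaten(self, shared_s1p_truth):
        """MLE optimality: on data generated exactly at θ_true the fitted
        NLL cannot exceed the profiled NLL at θ_true."""
        table = noise_free_table(shared_s1p_truth, n_replicates=4)
        problem = make_problem(table, "feedback")
        theta_true = truth_theta(shared_s1p_truth)
        result = fit_problem(
            problem, n_starts=2, seed=0, extra_starts=[theta_true], maxiter=150
        )
        # all residuals are zero at truth, so every σ profiles to the floor
        from rheostat.calibration import SIGMA_FLOOR

        nll_true = len(table) * (0.5 * LN2PI + np.log(SIGMA_FLOOR))
        assert result.nll <= nll_true + 1e-6

    def test_profiled_sigma_matches_joint_estimate(self, shared_s1p_truth,
                                                   noisy_measurements):
        problem = make_problem(noisy_measurements, "feedback", sigma_mode="joint")
        theta_true = truth_theta(shared_s1p_truth)
        result = fit_problem(
            problem, n_starts=3, seed=5, sigma_mode="joint",
            extra_starts=[theta_true], maxiter=400,
        )
        res = result.residuals()
        for obs in ("sphinganine", "ceramide", "sphingosine"):
            shat = sigma_mle(res.loc[res.observable_id == obs, "residual"])
            assert result.theta_hat[f"sigma_{obs}"] == pytest.approx(shat, rel=1e-4)

    def test_scaling_factor_absorbs_unit_change(self, shared_s1p_truth,
                                                noisy_measurements):
        """Multiplying one species' measurements by c and its scaling by c
        shifts the NLL by exactly n·ln c (σ scales with the data), leaving
        the standardized residual structure unchanged."""
        problem = make_problem(noisy_measurements, "feedback")
        theta = truth_theta(shared_s1p_truth)
        nll_a = negative_log_likelihood(theta, problem)

        c = 7.0
        scaled = noisy_measurements.copy()
        mask = scaled.observable_id == "ceramide"
        scaled.loc[mask, "value"] *= c
        theta_c = dict(theta)
        theta_c["s_ceramide"] *= c
        theta_c["sigma_ceramide"] *= c
        nll_b = negative_log_likelihood(theta_c, make_problem(scaled, "feedback"))
        n_cer = int(mask.sum())
        assert nll_b - nll_a == pytest.approx(n_cer * np.log(c), abs=1e-8)

    def test_summary_lists_estimates(self, noisy_measurements):
        problem = make_problem(noisy_measurements, "no_feedback")
        result = fit_problem(problem, n_starts=2, seed=3, maxiter=40)
        text = result.summary()
        assert "no_feedback" in text and "k00" in text and "profiled" in text
        assert f"{result.nll:.6f}" in text


class TestAssessAndCompare:
    def test_two_dpf_cells_pinned_inside(self, noisy_measurements):
        problem = make_problem(noisy_measurements, "feedback")
        result = fit_problem(problem, n_starts=2, seed=2, maxiter=60)
        rep = assess_fit(result).table
        early = rep[rep.time_dpf == 2.0]
        assert early.pinned.all() and early.inside.all()
        assert (rep.ci_low <= rep.ci_high).all()

    def test_feedback_recovers_structure_on_one_dataset(self, noisy_measurements):
        rep = compare_variants(noisy_measurements, seed=21, n_starts=6, maxiter=200)
        assert rep.delta_nll >= -1e-4  # nesting
        cell = lambda t: t[
            (t.observable_id == "ceramide") & (t.condition_id == "mutant")
            & (t.time_dpf == 4.0)
        ]["inside"].iloc[0]
        assert bool(cell(rep.report_feedback))
        assert not bool(cell(rep.report_no_feedback))
        assert rep.verdict.startswith("feedback variant")

    def test_nesting_on_no_feedback_truth(self, shared_s1p_truth):
        """When the truth has α_cer = 0 the variants fit equally well."""
        from rheostat.synth import no_feedback_counterpart

        truth0 = no_feedback_counterpart(shared_s1p_truth)
        m = generate_measurements(truth0, SyntheticDesign(), seed=77)
        rep = compare_variants(m, seed=77, n_starts=16, maxiter=300)
        assert rep.delta_nll >= -1e-4
        assert rep.delta_nll < 0.5  # no systematic advantage for feedback

    def test_report_round_trips_through_writer(self, tmp_path, noisy_measurements):
        from rheostat.petab_io import read_report, write_report

        rep = compare_variants(noisy_measurements, seed=9, n_starts=2, maxiter=40)
        path = tmp_path / "report.json"
        write_report(rep, path)
        back = read_report(path)
        assert back.nll_feedback == rep.nll_feedback
        assert back.theta_no_feedback == rep.theta_no_feedback
        assert back.verdict == rep.verdict
        pd.testing.assert_frame_equal(
            back.report_feedback, rep.report_feedback, check_dtype=False
        )
        write_report(back, tmp_path / "report2.json")
        assert (tmp_path / "report2.json").read_bytes() == path.read_bytes()


class TestProblemAssembly:
    def test_no_feedback_fixes_alpha_cer(self, noisy_measurements):
        problem = make_problem(noisy_measurements, "no_feedback")
        assert "alpha_cer" not in problem.free_ids()
        assert problem.parameters.loc["alpha_cer", "value"] == 0.0

    def test_feedback_fixed_mode(self, noisy_measurements):
        problem = make_problem(noisy_measurements, "feedback", alpha_cer_mode="fixed")
        assert "alpha_cer" not in problem.free_ids()
        assert problem.parameters.loc["alpha_cer", "value"] == -1.0

    def test_per_condition_latents_mode(self, noisy_measurements):
        problem = make_problem(noisy_measurements, "feedback",
                               latent_initials="per_condition")
        assert {"x0_s1p_wild_type", "x0_s1p_mutant"} <= set(problem.free_ids())

    def test_undeclared_observable_rejected(self, noisy_measurements):
        bad = noisy_measurements.copy()
        bad.loc[0, "observable_id"] = "cholesterol"
        with pytest.raises(ValidationError, match="cholesterol"):
            make_problem(bad, "feedback")

    def test_model_facade(self, noisy_measurements):
        model = RheostatModel(noisy_measurements, variant="no_feedback")
        result = model.fit(n_starts=2, seed=1, maxiter=40)
        assert np.isfinite(result.nll)
        assert result.theta_hat["alpha_cer"] == 0.0
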