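import numpy as np
import pandas as pd
import pytest
from scipy import stats

from vocalmod import association, synthetic
from vocalmod.association import (
    DEFAULT_INDICES,
    ModelSpec,
    RankDeficiencyError,
    fdr_adjust,
    fit_ols,
    fit_robust,
    huber_weight,
    influence_diagnostics,
    partial_correlation,
    run_association_suite,
)


def make_data(n=24, seed=0, ed_fn=None):
    """Per-speaker table with the model's column layout."""
    rng = np.random.default_rng(seed)
    df = pd.DataFrame(
        {
            "speaker_id": np.arange(n),
            "machiavellianism": rng.normal(25, 5, n),
            "psychopathy": rng.normal(17, 4, n),
            "affective_empathy": rng.normal(36, 5, n),
            "cognitive_empathy": rng.normal(57, 8, n),
            "age": rng.integers(18, 30, n).astype(float),
            "sex": np.where(rng.random(n) < 0.2, "male", "female"),
        }
    )
    if not (df["sex"] == "male").any():
        df.loc[0, "sex"] = "male"
    if ed_fn is None:
        df["ed"] = rng.normal(0.75, 0.3, n)
    else:
        df["ed"] = ed_fn(df, rng)
    return df


class TestFitOls:
    def test_noiseless_exact_interpolation(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame(
            {
                "speaker_id": np.arange(10),
                "x": rng.normal(size=10),
                "age": rng.normal(25, 3, 10),
                "sex": ["male", "female"] * 5,
            }
        )
        df["y"] = 2.0 + 1.0 * df["x"]
        spec = ModelSpec(outcome="y", predictors=("x",), covariates=())
        res = fit_ols(spec, df)
        # predictor z-scored: slope on z-scale = sd(x); intercept = mean(y)
        assert res.coef("intercept") == pytest.approx(df["y"].mean())
        assert res.coef("x") == pytest.approx(df["x"].std(ddof=1) * 1.0)
        assert res.extra["r2"] == pytest.approx(1.0)

    def test_df_structure_22_speakers(self):
        df = make_data(n=22)
        res = fit_ols(ModelSpec(outcome="ed"), df)
        assert (res.df_model, res.df_resid) == (6, 15)

    def test_df_structure_24_speakers(self):
        df = make_data(n=24)
        res = fit_ols(ModelSpec(outcome="ed"), df)
        assert (res.df_model, res.df_resid) == (6, 17)

    def test_normal_equations_oracle(self):
        df = make_data(n=30, seed=5)
        spec = ModelSpec(outcome="ed")
        res = fit_ols(spec, df)
        # independent solver on the same design
        cols = [np.ones(len(df))]
        for p in DEFAULT_INDICES:
            x = df[p].to_numpy(float)
            cols.append((x - x.mean()) / x.std(ddof=1))
        cols.append(association.encode_sex(df["sex"]))
        cols.append(df["age"].to_numpy(float))
        X = np.column_stack(cols)
        y = df["ed"].to_numpy(float)
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        np.testing.assert_allclose(res.terms["beta"].to_numpy(), beta, rtol=1e-10)

    def test_positive_rescaling_leaves_standardized_stats_unchanged(self):
        df = make_data(n=24, seed=2)
        spec = ModelSpec(outcome="ed")
        base = fit_ols(spec, df)
        df2 = df.copy()
        df2["cognitive_empathy"] = df2["cognitive_empathy"] * 10.0
        scaled = fit_ols(spec, df2)
        for col in ("beta", "t", "p"):
            np.testing.assert_allclose(
                base.terms[col].to_numpy(), scaled.terms[col].to_numpy(), rtol=1e-10
            )

    def test_constant_sex_raises_named_error(self):
        df = make_data(n=24, seed=3)
        df["sex"] = "female"
        with pytest.raises(RankDeficiencyError, match="sex"):
            fit_ols(ModelSpec(outcome="ed"), df)


class TestInfluenceDiagnostics:
    def test_planted_outlier_is_flagged_max(self):
        df = make_data(n=24, seed=4)
        resid_sd = 0.1
        rng = np.random.default_rng(11)
        df["ed"] = 0.7 + rng.normal(0, resid_sd, 24)
        df.loc[5, "ed"] += 10 * resid_sd
        rep = influence_diagnostics(ModelSpec(outcome="ed"), df)
        tab = rep.table.set_index("speaker_id")
        assert tab["student_resid"].abs().idxmax() == 5
        assert 5 in rep.flagged_ids

    def test_bonferroni_is_min_one_p_times_n(self):
        df = make_data(n=24, seed=6)
        rep = influence_diagnostics(ModelSpec(outcome="ed"), df)
        np.testing.assert_allclose(
            rep.table["p_bonferroni"],
            np.minimum(1.0, rep.table["p_uncorrected"] * len(df)),
        )

    def test_degenerate_noiseless_fit_errors(self):
        from vocalmod.association import DegenerateResidualError

        df = make_data(n=24, seed=7)
        z = df["cognitive_empathy"] - df["cognitive_empathy"].mean()
        df["ed"] = 1.0 + 0.5 * z / z.std(ddof=1)
        with pytest.raises(DegenerateResidualError):
            influence_diagnostics(ModelSpec(outcome="ed"), df)

    def test_type_one_flag_rate_near_five_percent(self):
        # externally studentized residuals are exactly t-distributed under H0
        n_flag = 0
        n_tot = 0
        for seed in range(400):
            df = make_data(n=24, seed=seed)
            rep = influence_diagnostics(ModelSpec(outcome="ed"), df, resid_test="none")
            n_flag += int(rep.table["flagged"].sum())
            n_tot += len(df)
        rate = n_flag / n_tot
        assert abs(rate - 0.05) < 0.01

    def test_shapiro_runs(self):
        df = make_data(n=24, seed=8)
        rep = influence_diagnostics(ModelSpec(outcome="ed"), df)
        assert rep.resid_test_name == "shapiro"
        assert 0.0 <= rep.resid_test_p <= 1.0


class TestFitRobust:
    def test_weights_to_one_limit_equals_ols(self):
        df = make_data(n=24, seed=9)
        ols = fit_ols(ModelSpec(outcome="ed"), df)
        rob = fit_robust(ModelSpec(outcome="ed"), df, huber_t=1e6)
        np.testing.assert_allclose(
            ols.terms["beta"].to_numpy(), rob.terms["beta"].to_numpy(), atol=1e-6
        )

    def test_huber_weight_at_zero_is_one(self):
        assert huber_weight(0.0) == 1.0

    def test_contamination_simulation(self):
        wins = 0
        n_rep = 300
        for seed in range(n_rep):
            rng = np.random.default_rng(seed)
            df = make_data(n=24, seed=seed)
            x = df["cognitive_empathy"].to_numpy(float)
            z = (x - x.mean()) / x.std(ddof=1)
            df["ed"] = 1.0 * z + rng.normal(0, 0.2, 24)
            # gross outliers at the top of the predictor: biases the OLS
            # slope sharply downward
            extreme = np.argsort(z)[-2:]
            df.loc[df.index[extreme], "ed"] -= 8.0
            spec = ModelSpec(outcome="ed", predictors=("cognitive_empathy",),
                             covariates=())
            b_ols = fit_ols(spec, df).coef("cognitive_empathy")
            b_rob = fit_robust(spec, df).coef("cognitive_empathy")
            if abs(b_rob - 1.0) < abs(b_ols - 1.0):
                wins += 1
        assert wins / n_rep >= 0.95

    def test_reports_scale_and_r2(self):
        df = make_data(n=24, seed=10)
        rob = fit_robust(ModelSpec(outcome="ed"), df)
        assert rob.extra["scale"] > 0
        assert rob.extra["converged"]
        assert rob.method == "robust_m"


class TestPartialCorrelation:
    def test_no_covariates_equals_plain_pearson(self, rng):
        x, y = rng.normal(size=(2, 30))
        pc = partial_correlation(x, y)
        r_ref, p_ref = stats.pearsonr(x, y)
        assert pc.r == pytest.approx(r_ref)
        assert pc.p == pytest.approx(p_ref)

    def test_exactly_explained_variable_degenerates_to_zero(self, rng):
        z = rng.normal(size=30)
        y = 2.0 + 3.0 * z
        x = rng.normal(size=30)
        with pytest.warns(RuntimeWarning, match="degenerate"):
            pc = partial_correlation(x, y, z)
        assert pc.r == 0.0 and pc.degenerate

    def test_residual_of_residuals_oracle(self, rng):
        x, y = rng.normal(size=(2, 40))
        Z = rng.normal(size=(40, 2))
        pc = partial_correlation(x, y, Z)
        C = np.column_stack([np.ones(40), Z])
        rx = x - C @ np.linalg.lstsq(C, x, rcond=None)[0]
        ry = y - C @ np.linalg.lstsq(C, y, rcond=None)[0]
        assert pc.r == pytest.approx(np.corrcoef(rx, ry)[0, 1])

    def test_inverse_correlation_matrix_identity(self, rng):
        # second independent oracle: r_xy.z = -P_xy / sqrt(P_xx P_yy)
        x, y = rng.normal(size=(2, 50))
        z = rng.normal(size=50)
        pc = partial_correlation(x, y, z)
        R = np.corrcoef(np.column_stack([x, y, z]).T)
        P = np.linalg.inv(R)
        expected = -P[0, 1] / np.sqrt(P[0, 0] * P[1, 1])
        assert pc.r == pytest.approx(expected)

    def test_matches_pingouin(self, rng):
        pingouin = pytest.importorskip("pingouin")
        df = pd.DataFrame(rng.normal(size=(35, 4)), columns=list("xyzw"))
        pc = partial_correlation(df["x"], df["y"], df[["z", "w"]])
        ref = pingouin.partial_corr(df, x="x", y="y", covar=["z", "w"])
        pcol = "p_val" if "p_val" in ref.columns else "p-val"
        assert pc.r == pytest.approx(float(ref["r"].iloc[0]))
        assert pc.p == pytest.approx(float(ref[pcol].iloc[0]))


def brute_force_bh(p):
    p = np.asarray(p, float)
    m = len(p)
    adj = np.empty(m)
    for i in range(m):
        rank_i = np.sum(p <= p[i])
        # min over the tail of p_j * m / rank_j for p_j >= p_i
        candidates = [p[j] * m / np.sum(p <= p[j]) for j in range(m) if p[j] >= p[i]]
        adj[i] = min(1.0, min(candidates))
    return adj


class TestFdrAdjust:
    def test_single_p_unchanged(self):
        assert fdr_adjust([0.03])[0] == pytest.approx(0.03)

    def test_hand_stepup_example(self):
        np.testing.assert_allclose(fdr_adjust([0.01, 0.02, 0.03, 0.04]), 0.04)

    def test_matches_brute_force_on_random_vectors(self, rng):
        for _ in range(50):
            m = int(rng.integers(1, 9))
            p = rng.random(m)
            np.testing.assert_allclose(fdr_adjust(p), brute_force_bh(p), rtol=1e-12)

    def test_matches_statsmodels(self, rng):
        from statsmodels.stats.multitest import multipletests

        p = rng.random(12)
        ref = multipletests(p, method="fdr_bh")[1]
        np.testing.assert_allclose(fdr_adjust(p), ref, rtol=1e-12)

    def test_monotone_and_dominates_raw(self, rng):
        p = rng.random(10)
        adj = fdr_adjust(p)
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-15).all()
        assert (adj >= p - 1e-12).all()
        assert (adj <= 1.0).all()

    def test_decision_equivalence_with_stepup_rule(self, rng):
        # adjusted p <= q iff the BH step-up procedure rejects at level q
        for _ in range(20):
            m = int(rng.integers(2, 9))
            p = rng.random(m)
            q = float(rng.uniform(0.01, 0.3))
            adj = fdr_adjust(p)
            srt = np.sort(p)
            passing = np.nonzero(srt <= np.arange(1, m + 1) / m * q)[0]
            k = 0 if passing.size == 0 else passing.max() + 1
            stepup_reject = p <= (srt[k - 1] if k else -1.0)
            np.testing.assert_array_equal(adj <= q, stepup_reject)

    def test_empty_input_raises(self):
        with pytest.raises(ValueError):
            fdr_adjust([])


class TestAssociationSuite:
    def test_planted_beta_recovery_single_seed(self):
        cfg = synthetic.SimulationConfig(n_speakers=500, n_listeners=500, seed=0)
        rngs = synthetic._stage_rngs(cfg.seed)
        gt = synthetic.make_ground_truth(cfg, rngs["design"])
        items, speakers = synthetic.generate_reactivity(cfg, gt, rngs["reactivity"])
        from vocalmod import scales

        profiles = scales.score_profiles(items, speakers)
        perf = synthetic.generate_performance_from_betas(
            profiles, {"cognitive_empathy": -0.45}, noise_sd=0.5, seed=1
        )
        report = run_association_suite(perf, profiles)
        b = report.full_ols.coef("cognitive_empathy")
        se = report.full_ols.se("cognitive_empathy")
        assert abs(b - (-0.45)) < 2 * se

    def test_followup_model_df(self, small_study, small_profiles):
        report = run_association_suite(small_study.performance, small_profiles)
        assert (report.followup_ols.df_model, report.followup_ols.df_resid) == (6, 17)
        assert report.followup_ols.n_used == 24

    def test_no_silent_exclusion_when_screen_not_significant(self):
        df = make_data(n=24, seed=12)
        perf = df[["speaker_id", "ed"]].copy()
        for col in ("delta_hostility", "delta_intelligence", "delta_likeability"):
            perf[col] = np.random.default_rng(1).normal(1, 1, 24)
        prof = df.drop(columns=["ed"])
        report = run_association_suite(perf, prof)
        if report.influence.resid_test_p >= 0.001:
            assert report.excluded_ids == ()
            assert report.primary_ols.n_used == 24

    def test_partial_table_shape_and_fdr(self, small_study, small_profiles):
        report = run_association_suite(small_study.performance, small_profiles)
        assert len(report.partial_table) == 12
        assert (report.partial_table["p_fdr"] >= report.partial_table["p"] - 1e-12).all()
        assert report.partial_table["p_fdr"].between(0, 1).all()
        assert report.partial_table["r_partial"].abs().le(1).all()

    def test_control_partial_present(self, small_study, small_profiles):
        report = run_association_suite(small_study.performance, small_profiles)
        assert report.control_partial is not None
        assert -1 <= report.control_partial.r <= 1

    def test_fdr_validity_under_planted_null(self):
        # with all loadings zero, the chance of any BH-significant cell
        # at q=.05 stays near/below the nominal level
        n_any = 0
        n_rep = 200
        for seed in range(n_rep):
            cfg = synthetic.SimulationConfig(
                seed=seed,
                questionnaire_loadings={k: 0.0 for k in synthetic.INDICES},
            )
            rngs = synthetic._stage_rngs(cfg.seed)
            gt = synthetic.make_ground_truth(cfg, rngs["design"])
            items, speakers = synthetic.generate_reactivity(cfg, gt, rngs["reactivity"])
            from vocalmod import scales

            profiles = scales.score_profiles(items, speakers)
            perf = synthetic.generate_performance_from_betas(
                profiles, {}, noise_sd=0.5, seed=seed + 10_000
            )
            report = run_association_suite(perf, profiles, resid_test="none")
            if (report.partial_table["p_fdr"] < 0.05).any():
                n_any += 1
        rate = n_any / n_rep
        assert rate <= 0.05 + 2 * np.sqrt(0.05 * 0.95 / n_rep)
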