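"""Nested mixed model: oracles (OLS limit, statsmodels), containment dfs,
contrasts, Holm correction, and the exploratory difference model."""

import numpy as np
import pandas as pd
import pytest

from padtrack.config import SimulationConfig
from padtrack.lmm import (
    build_long_dataset,
    containment_df_within,
    fit_difference_model,
    fit_nested_lmm,
    fit_trajectory_model,
    holm_correct,
    pairwise_contrasts,
)
from padtrack.simulate import latent_to_brainpad_records, simulate_cohort, simulate_latent_ages


def latent_dataset(cfg):
    cohort = simulate_cohort(cfg)
    latent = simulate_latent_ages(cohort, cfg)
    return build_long_dataset(latent_to_brainpad_records(latent), cohort), cohort


@pytest.fixture(scope="module")
def default_data():
    return latent_dataset(SimulationConfig(seed=4))


class TestHolm:
    def test_single_p_unchanged(self):
        np.testing.assert_allclose(holm_correct([0.03]), [0.03])

    def test_step_down_examples(self):
        np.testing.assert_allclose(holm_correct([0.01, 0.02, 0.03]), [0.03, 0.04, 0.04])
        np.testing.assert_allclose(holm_correct([0.04, 0.04, 0.04]), [0.12, 0.12, 0.12])

    def test_order_preserved(self):
        out = holm_correct([0.03, 0.01, 0.02])
        np.testing.assert_allclose(out, [0.04, 0.03, 0.04])

    @pytest.mark.parametrize("seed", range(5))
    def test_dominance_property(self, seed):
        p = np.random.default_rng(seed).uniform(0, 1, size=6)
        out = holm_correct(p)
        assert (out >= p).all() and (out <= 1).all()

    def test_invalid_values_rejected(self):
        with pytest.raises(ValueError):
            holm_correct([0.5, 1.2])


class TestLongDataset:
    def test_z_columns_standardised(self, default_data):
        data, _ = default_data
        for col in ("brain_pad_z", "age_z"):
            assert abs(data[col].mean()) < 1e-10
            assert data[col].std(ddof=1) == pytest.approx(1.0, abs=1e-10)

    def test_default_row_bookkeeping(self, default_data):
        data, _ = default_data
        assert (data["timepoint"] == "t1").sum() == 202
        assert (data["timepoint"] == "t2").sum() == 124

    def test_orphan_records_rejected(self, default_data):
        data, cohort = default_data
        rec = pd.DataFrame(
            {
                "subject_id": ["nobody"],
                "timepoint": ["t1"],
                "chronological_age": [20.0],
                "brain_pad": [0.0],
            }
        )
        with pytest.raises(ValueError):
            build_long_dataset(rec, cohort)

    def test_single_timepoint_design_rejected(self):
        cfg = SimulationConfig(group_sizes=(8, 8, 8), followup_counts=(0, 0, 0))
        data, _ = latent_dataset(cfg)
        with pytest.raises(ValueError, match="timepoint"):
            fit_trajectory_model(data)


class TestContainmentDf:
    def test_study_design_within_subject_df(self):
        assert containment_df_within(326, 202, 3) == 121

    def test_fitted_model_level_dfs(self, default_data):
        data, _ = default_data
        fit = fit_trajectory_model(data)
        n_obs, n_subj, n_fam = len(data), data["subject_id"].nunique(), data["family_id"].nunique()
        assert fit.level_dfs["obs"] == n_obs - n_subj - 3
        assert fit.level_dfs["subject"] == n_subj - n_fam - 2
        assert fit.level_dfs["family"] == n_fam - 1
        fe = fit.fixed_effects.set_index("term")
        assert fe.loc["t2", "df"] == fit.level_dfs["obs"]
        assert fe.loc["HR-well", "df"] == fit.level_dfs["subject"]
        assert fe.loc["intercept", "df"] == fit.level_dfs["family"]


class TestREMLFit:
    def test_ols_limit_oracle(self):
        """With no random-effect variance in the data the fixed effects
        coincide with OLS on the same design."""
        cfg = SimulationConfig(seed=8, subject_sd=0.0, family_sd=0.0, noise_sd=1.0)
        data, _ = latent_dataset(cfg)
        fit = fit_trajectory_model(data, outcome="brain_pad_years")
        t2 = (data["timepoint"] == "t2").to_numpy(float)
        hw = (data["group"] == "HR-well").to_numpy(float)
        hm = (data["group"] == "HR-MD").to_numpy(float)
        X = np.column_stack([np.ones_like(t2), t2, hw, hm, t2 * hw, t2 * hm])
        ols, *_ = np.linalg.lstsq(X, data["brain_pad_years"].to_numpy(), rcond=None)
        np.testing.assert_allclose(fit.beta, ols, atol=1e-4)

    def test_matches_statsmodels_mixedlm(self, default_data):
        """Independent cross-check of betas, SEs and variance components."""
        import statsmodels.formula.api as smf

        data, _ = default_data
        fit = fit_trajectory_model(data)
        df = data.rename(columns={"brain_pad_z": "y"}).copy()
        m = smf.mixedlm(
            "y ~ C(timepoint) * C(group, Treatment('C-well'))",
            df,
            groups="family_id",
            re_formula="1",
            vc_formula={"subject": "0 + C(subject_id)"},
        )
        r = m.fit(reml=True, method="lbfgs")
        sm_terms = {
            "intercept": "Intercept",
            "t2": "C(timepoint)[T.t2]",
            "HR-well": "C(group, Treatment('C-well'))[T.HR-well]",
            "HR-MD": "C(group, Treatment('C-well'))[T.HR-MD]",
            "t2:HR-well": "C(timepoint)[T.t2]:C(group, Treatment('C-well'))[T.HR-well]",
            "t2:HR-MD": "C(timepoint)[T.t2]:C(group, Treatment('C-well'))[T.HR-MD]",
        }
        for i, term in enumerate(fit.terms):
            assert fit.beta[i] == pytest.approx(r.fe_params[sm_terms[term]], abs=2e-3)
            assert fit.se[i] == pytest.approx(r.bse_fe[sm_terms[term]], rel=2e-2)
        assert fit.varcomp_residual == pytest.approx(r.scale, rel=2e-2)
        assert fit.varcomp_subject == pytest.approx(float(r.vcomp[0]), rel=5e-2, abs=1e-3)
        assert fit.varcomp_family == pytest.approx(float(r.cov_re.iloc[0, 0]), rel=5e-2, abs=1e-3)

    def test_objective_trace_and_gradient(self, default_data):
        data, _ = default_data
        fit = fit_trajectory_model(data)
        assert fit.converged
        assert fit.reml_loglik == pytest.approx(max(-np.inf, fit.reml_loglik))
        # the reported solution is the best point visited and is stationary
        assert fit.grad_norm < 1e-3
        trace = np.asarray(fit.objective_trace)
        assert np.min(trace) >= np.min(np.minimum.accumulate(trace)) - 1e-12

    def test_z_scoring_leaves_t_statistics_invariant(self, default_data):
        data, _ = default_data
        fz = fit_trajectory_model(data, outcome="brain_pad_z")
        fy = fit_trajectory_model(data, outcome="brain_pad_years")
        # the intercept shifts with the outcome mean; slope terms are invariant
        np.testing.assert_allclose(fz.t[1:], fy.t[1:], atol=1e-6)
        np.testing.assert_allclose(fz.p[1:], fy.p[1:], atol=1e-8)

    def test_balanced_no_family_fit_matches_cell_means(self):
        """Balanced two-way data with singleton families and no subject
        variance: estimates equal ANOVA cell-mean contrasts."""
        rng = np.random.default_rng(0)
        rows = []
        for g, gname in enumerate(["C-well", "HR-well", "HR-MD"]):
            for i in range(30):
                sid = f"{gname}-{i}"
                for tp in ("t1", "t2"):
                    rows.append((sid, sid, gname, tp, rng.normal(g + (tp == "t2") * 0.5, 1.0)))
        df = pd.DataFrame(rows, columns=["subject_id", "family_id", "group", "timepoint", "y"])
        t2 = (df["timepoint"] == "t2").to_numpy(float)
        hw = (df["group"] == "HR-well").to_numpy(float)
        hm = (df["group"] == "HR-MD").to_numpy(float)
        X = np.column_stack([np.ones_like(t2), t2, hw, hm, t2 * hw, t2 * hm])
        fit = fit_nested_lmm(
            X,
            df["y"].to_numpy(),
            df["family_id"].to_numpy(),
            df["subject_id"].to_numpy(),
            ("intercept", "t2", "HR-well", "HR-MD", "t2:HR-well", "t2:HR-MD"),
        )
        cell = df.groupby(["group", "timepoint"])["y"].mean()
        assert fit.beta[2] == pytest.approx(
            cell[("HR-well", "t1")] - cell[("C-well", "t1")], abs=0.05
        )
        assert fit.beta[4] == pytest.approx(
            (cell[("HR-well", "t2")] - cell[("HR-well", "t1")])
            - (cell[("C-well", "t2")] - cell[("C-well", "t1")]),
            abs=0.05,
        )


class TestContrasts:
    def test_trajectory_pair_is_interaction_difference(self, default_data):
        data, _ = default_data
        fit = fit_trajectory_model(data)
        table = pairwise_contrasts(fit, "trajectory").set_index("pair")
        terms = list(fit.terms)
        expected = fit.beta[terms.index("t2:HR-MD")] - fit.beta[terms.index("t2:HR-well")]
        assert table.loc["HR-MD vs HR-well", "estimate_z"] == pytest.approx(expected, abs=1e-12)

    def test_three_comparisons_per_stage_with_holm(self, default_data):
        data, _ = default_data
        fit = fit_trajectory_model(data)
        for stage in ("baseline", "trajectory", "followup"):
            table = pairwise_contrasts(fit, stage)
            assert len(table) == 3
            assert (table["p_holm"] >= table["p_raw"] - 1e-15).all()

    def test_unknown_stage_rejected(self, default_data):
        data, _ = default_data
        fit = fit_trajectory_model(data)
        with pytest.raises(ValueError):
            pairwise_contrasts(fit, "weekly")


class TestDifferenceModel:
    def test_outcome_rows_equal_followup_count(self, default_data):
        data, _ = default_data
        fit = fit_difference_model(data)
        assert fit.n_obs == 124

    def test_constant_differences_give_zero_slopes(self):
        rows = []
        for g in ("C-well", "HR-well"):
            for i in range(6):
                sid = f"{g}{i}"
                for tp, pad in (("t1", 0.3), ("t2", 0.8)):
                    rows.append((sid, sid, g, tp, pad, pad, 20.0 + i, 0.0, 0))
        data = pd.DataFrame(
            rows,
            columns=["subject_id", "family_id", "group", "timepoint",
                     "brain_pad_years", "brain_pad_z", "age_years", "age_z", "sex"],
        )
        fit = fit_difference_model(data)
        terms = list(fit.terms)
        assert fit.beta[terms.index("intercept")] == pytest.approx(0.5, abs=1e-8)
        for term in terms:
            if term != "intercept":
                assert fit.beta[terms.index(term)] == pytest.approx(0.0, abs=1e-8)

    def test_age_moderation_sign_recovered_at_scale(self):
        """Building a positive age x HR-MD moderation into the change score
        is recovered in sign at a scaled-up cohort."""
        cfg = SimulationConfig(
            group_sizes=(465, 370, 175), followup_counts=(230, 235, 155), seed=23
        )
        cohort = simulate_cohort(cfg)
        latent = simulate_latent_ages(cohort, cfg)
        rec = latent_to_brainpad_records(latent)
        data = build_long_dataset(rec, cohort)
        # inject moderation: HR-MD change increases with baseline age
        base_age = data.groupby("subject_id")["age_years"].transform("min")
        boost = 0.15 * (base_age - base_age.mean())
        mask = (data["group"] == "HR-MD") & (data["timepoint"] == "t2")
        data.loc[mask, "brain_pad_years"] += boost[mask]
        fit = fit_difference_model(data)
        terms = list(fit.terms)
        assert fit.beta[terms.index("age_z:HR-MD")] > 0
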