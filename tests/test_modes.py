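"""Mode regression and reconstruction: exact linear recovery, null
calibration, statsmodels cross-check, SEM masking, regional localization."""

import numpy as np
import pandas as pd
import pytest

from lvatlas.atlas import Trajectory, build_atlas
from lvatlas.fields import concentric_field, endo_radial_field, size_field, \
    wall_field
from lvatlas.modes import (build_design, fit_mode_regression,
                           measure_change_sd, mode_measure_deltas,
                           reconstruct_mode, regional_mode_map, sem_filter)
from lvatlas.template import make_template


@pytest.fixture(scope="module")
def template301():
    return make_template(p_per_surface=301)


def simple_covariates(n, rng, obese=None):
    sids = [f"S{i:04d}" for i in range(n)]
    if obese is None:
        obese = rng.random(n) < 0.3
    smoker = rng.random(n) < 0.15
    rows = []
    for exam in ("baseline", "followup"):
        rows.append(pd.DataFrame({
            "subject_id": sids, "exam": exam,
            "age": rng.normal(60, 9, n) if exam == "baseline" else 70.0,
            "sex": np.where(rng.random(n) < 0.5, "male", "female"),
            "race_ethnicity": "white",
            "bmi": np.where(obese, 33.0, 25.0),
            "sbp": rng.normal(120, 15, n), "dbp": rng.normal(72, 9, n),
            "total_cholesterol": 180.0, "ldl": rng.normal(110, 25, n),
            "hdl": rng.normal(52, 12, n), "triglycerides": 120.0,
            "smoker": smoker, "htn_diagnosis": False,
            "htn_medication": False, "statins": False,
            "diabetes_status": "none", "bsa": rng.normal(1.85, 0.2, n),
        }))
    cov = pd.concat(rows, ignore_index=True)
    # make per-subject sex/bsa consistent across exams
    base = cov[cov["exam"] == "baseline"].set_index("subject_id")
    cov.loc[cov["exam"] == "followup", "sex"] = base["sex"].to_numpy()
    return cov, obese


PREDICTORS = ("age_baseline", "delta_bsa", "sbp", "obesity", "smoking")


class TestFitModeRegression:
    def test_exact_linear_recovery(self, rng):
        # scores equal 2 x obesity indicator on component 1, zero elsewhere
        n = 80
        cov, obese = simple_covariates(n, rng)
        sids = sorted(cov["subject_id"].unique())
        scores = pd.DataFrame(0.0, index=pd.Index(sids, name="subject_id"),
                              columns=["score_1", "score_2"])
        scores["score_1"] = 2.0 * obese
        fit = fit_mode_regression(scores, cov, predictors=PREDICTORS)
        assert fit.coefficients.loc["obesity", "score_1"] \
            == pytest.approx(2.0, abs=1e-10)
        assert abs(fit.coefficients.loc["obesity", "score_2"]) < 1e-10
        others = fit.coefficients.drop(index=["obesity", "intercept"])
        assert np.abs(others.to_numpy()).max() < 1e-10

    def test_matches_statsmodels(self, rng):
        import statsmodels.api as sm
        n = 60
        cov, _ = simple_covariates(n, rng)
        sids = sorted(cov["subject_id"].unique())
        scores = pd.DataFrame(rng.normal(size=(n, 3)),
                              index=pd.Index(sids, name="subject_id"),
                              columns=["score_1", "score_2", "score_3"])
        fit = fit_mode_regression(scores, cov, predictors=PREDICTORS,
                                  standardize=False)
        design = build_design(cov, PREDICTORS)
        x = sm.add_constant(design.loc[scores.index].to_numpy())
        for j, col in enumerate(scores.columns):
            res = sm.OLS(scores[col].to_numpy(), x).fit()
            np.testing.assert_allclose(
                fit.coefficients[col].to_numpy(), res.params, atol=1e-8)
            np.testing.assert_allclose(
                fit.standard_errors[col].to_numpy(), res.bse, atol=1e-8)

    def test_null_pvalue_calibration(self, rng):
        # pure-noise scores: the fraction of |t| > t_crit must match alpha
        from scipy import stats
        n, reps, alpha = 100, 200, 0.05
        hits, total = 0, 0
        cov, _ = simple_covariates(n, rng)
        sids = sorted(cov["subject_id"].unique())
        design_cols = len(PREDICTORS)
        dof = n - design_cols - 1
        tcrit = stats.t.ppf(1 - alpha / 2, dof)
        for _ in range(reps):
            scores = pd.DataFrame(
                rng.normal(size=(n, 1)),
                index=pd.Index(sids, name="subject_id"), columns=["score_1"])
            fit = fit_mode_regression(scores, cov, predictors=PREDICTORS)
            t = (fit.coefficients.iloc[1:, 0]
                 / fit.standard_errors.iloc[1:, 0])
            hits += int((t.abs() > tcrit).sum())
            total += len(t)
        assert hits / total == pytest.approx(alpha, abs=0.02)

    def test_correlated_predictors_recovered_within_2se(self, rng):
        n = 400
        cov, obese = simple_covariates(n, rng)
        # make smoking correlated with obesity (r ~ 0.5)
        smoke = np.where(rng.random(n) < 0.6, obese,
                         rng.random(n) < 0.3)
        cov.loc[cov["exam"] == "followup", "smoker"] = \
            smoke.astype(bool)
        cov.loc[cov["exam"] == "baseline", "smoker"] = smoke.astype(bool)
        sids = sorted(cov["subject_id"].unique())
        truth = {"obesity": 1.5, "smoking": -0.8}
        scores = pd.DataFrame(
            truth["obesity"] * obese + truth["smoking"] * smoke
            + rng.normal(0, 1.0, n),
            index=pd.Index(sids, name="subject_id"), columns=["score_1"])
        fit = fit_mode_regression(scores, cov, predictors=PREDICTORS)
        for f, b in truth.items():
            est = fit.coefficients.loc[f, "score_1"]
            se = fit.standard_errors.loc[f, "score_1"]
            assert abs(est - b) < 2 * se

    def test_rank_deficient_design_names_columns(self, rng):
        n = 50
        cov, _ = simple_covariates(n, rng)
        cov["dbp"] = cov["sbp"]    # exact collinearity
        sids = sorted(cov["subject_id"].unique())
        scores = pd.DataFrame(rng.normal(size=(n, 1)),
                              index=pd.Index(sids, name="subject_id"),
                              columns=["score_1"])
        with pytest.raises(ValueError, match="collinear"):
            fit_mode_regression(scores, cov,
                                predictors=("sbp", "dbp"), standardize=False)

    def test_too_few_subjects(self, rng):
        cov, _ = simple_covariates(5, rng)
        sids = sorted(cov["subject_id"].unique())
        scores = pd.DataFrame(rng.normal(size=(5, 1)),
                              index=pd.Index(sids, name="subject_id"),
                              columns=["score_1"])
        with pytest.raises(ValueError, match="too small"):
            fit_mode_regression(scores, cov, predictors=PREDICTORS)


@pytest.fixture(scope="module")
def planted_fit(template301):
    """Cohort whose trajectories are a planted obesity field plus noise."""
    rng = np.random.default_rng(9)
    n = 150
    cov, obese = simple_covariates(n, rng)
    field = 0.9 * wall_field(template301) \
        - 0.5 * endo_radial_field(template301)
    d = template301.n_points * 6
    tvec = template301.to_vector()
    traj = []
    sids = sorted(cov["subject_id"].unique())
    for i, sid in enumerate(sids):
        disp = obese[i] * field + rng.normal(0, 0.15, d)
        traj.append(Trajectory(subject_id=sid, displacement=disp,
                               transported=tvec + disp))
    atlas = build_atlas(traj, template301)
    from lvatlas.atlas import scores_table
    scores = scores_table(atlas, traj)
    fit = fit_mode_regression(scores.iloc[:, :40], cov,
                              predictors=PREDICTORS)
    return template301, atlas, fit, field


class TestReconstructMode:
    def test_zero_coefficients_zero_mode(self, planted_fit):
        template, atlas, fit, _ = planted_fit
        import copy
        zfit = copy.deepcopy(fit)
        zfit.coefficients.loc["smoking"] = 0.0
        mode = reconstruct_mode(zfit, atlas, "smoking")
        np.testing.assert_allclose(mode.displacement, 0.0, atol=1e-12)
        assert np.abs(mode.measure_deltas.to_numpy()).max() < 1e-9
        np.testing.assert_allclose(mode.regional_thickening_delta, 0.0,
                                   atol=1e-9)

    def test_planted_field_recovered(self, planted_fit):
        template, atlas, fit, field = planted_fit
        mode = reconstruct_mode(fit, atlas, "obesity", with_measures=False)
        cos = mode.displacement @ field \
            / (np.linalg.norm(mode.displacement) * np.linalg.norm(field))
        assert abs(cos) > 0.95
        # planted mass increment reproduced by the reconstruction
        from lvatlas.geometry import derived_measures
        m0 = derived_measures(template)
        m1 = derived_measures(
            template.with_vector(template.to_vector() + field))
        planted_dmass_pct = 100.0 * (m1.mass - m0.mass) / m0.mass
        deltas = mode_measure_deltas(atlas, mode.displacement)
        assert deltas["mass"] == pytest.approx(planted_dmass_pct, rel=0.15)

    def test_displacement_linear_in_delta(self, planted_fit):
        _, atlas, fit, _ = planted_fit
        m1 = reconstruct_mode(fit, atlas, "obesity", delta=1.0,
                              with_measures=False)
        m3 = reconstruct_mode(fit, atlas, "obesity", delta=3.0,
                              with_measures=False)
        np.testing.assert_allclose(m3.displacement, 3.0 * m1.displacement,
                                   rtol=1e-10)

    def test_matches_predicted_difference_oracle(self, planted_fit):
        # oracle: average predicted transported shape at factor=1 minus at
        # factor=0 (all else at reference) equals the coefficient route
        _, atlas, fit, _ = planted_fit
        mode = reconstruct_mode(fit, atlas, "obesity", with_measures=False)
        beta = fit.coefficients.to_numpy()     # (p+1, M)
        names = list(fit.coefficients.index)
        x0 = np.zeros(len(names))
        x0[0] = 1.0                            # intercept
        x1 = x0.copy()
        x1[names.index("obesity")] = 1.0
        dz = (x1 - x0) @ beta                  # predicted z-score difference
        m = len(dz)
        oracle = (dz * atlas.score_sd[:m]) @ atlas.components[:m]
        np.testing.assert_allclose(mode.displacement, oracle, atol=1e-6)

    def test_unknown_factor_rejected(self, planted_fit):
        _, atlas, fit, _ = planted_fit
        with pytest.raises(KeyError):
            reconstruct_mode(fit, atlas, "tea_drinking")


class TestRegionalMap:
    def test_uniform_wall_increase_uniform_deltas(self, template301):
        atlas = _identity_atlas(template301)
        disp = 0.8 * wall_field(template301)
        deltas = regional_mode_map(atlas, disp)
        spread = np.nanmax(deltas) - np.nanmin(deltas)
        assert spread < 0.25 * abs(np.nanmean(deltas))

    def test_planted_anterior_field_localized(self, template301):
        atlas = _identity_atlas(template301)

        def anterior_window(theta, t):
            # mid/apical anterior sector (theta ~ +90 deg)
            w = np.exp(-((np.degrees(theta) - 90) % 360 - 0) ** 2 / (2 * 40 ** 2))
            w = np.where(np.abs((np.degrees(theta) - 90 + 180) % 360 - 180)
                         < 60, w, 0.0)
            return w * np.exp(-(t - 0.4) ** 2 / (2 * 0.25 ** 2))

        disp = -1.2 * endo_radial_field(template301, angular=anterior_window)
        deltas = regional_mode_map(atlas, disp)
        top = np.nanargmax(np.abs(deltas)) + 1
        assert top in (7, 13, 1, 8, 12, 14)   # anterior territory

    def test_zero_mode_zero_map(self, template301):
        atlas = _identity_atlas(template301)
        deltas = regional_mode_map(atlas,
                                   np.zeros(template301.n_points * 6))
        np.testing.assert_allclose(deltas, 0.0, atol=1e-12)


def _identity_atlas(template):
    from lvatlas.atlas import TrajectoryAtlas
    d = template.n_points * 6
    return TrajectoryAtlas(
        mean_baseline=template.to_vector(),
        mean_trajectory=template.to_vector(),
        components=np.zeros((1, d)), explained_variance=np.ones(1),
        explained_variance_ratio=np.ones(1), score_sd=np.ones(1),
        n_subjects=1, reference_shape=template)


class TestSemFilter:
    def test_shown_and_masked(self):
        shown, sem, mask = sem_filter(pd.Series({"a": 2.0, "b": 0.3}),
                                      pd.Series({"a": 1.2, "b": 1.2}), n=9)
        assert shown["a"] == 2.0 and not mask["a"]
        assert np.isnan(shown["b"]) and mask["b"]
        assert sem["a"] == pytest.approx(0.4)

    def test_matrix_masking_matches_elementwise_oracle(self, rng):
        sems = pd.Series([0.4, 0.6, 0.3, 0.2, 0.4, 0.3, 0.5, 0.5, 0.1],
                         index=list("abcdefghi"))
        n = 4
        sd = sems * np.sqrt(n)
        for _ in range(10):
            vals = pd.Series(rng.normal(0, 1.0, 9), index=sems.index)
            shown, sem, mask = sem_filter(vals, sd, n)
            np.testing.assert_allclose(sem, sems)
            expected_mask = vals.abs() <= sems
            pd.testing.assert_series_equal(mask, expected_mask)
            assert shown[~mask].notna().all()

    def test_needs_n_above_one(self):
        with pytest.raises(ValueError):
            sem_filter(pd.Series([1.0]), pd.Series([1.0]), n=1)
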