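"""Trajectory computation, linear-shift transport, and the trajectory PCA
atlas: planted-mode recovery, z-score properties, transport invariances."""

import numpy as np
import pytest

from lvatlas.atlas import (Trajectory, build_atlas, compute_trajectories,
                           project_scores, scores_table)
from lvatlas.cohort import SimulationConfig, simulate_cohort
from lvatlas.fields import size_field, wall_field
from lvatlas.template import make_template


@pytest.fixture(scope="module")
def template301():
    return make_template(p_per_surface=301)


def clean_config(template, **kw):
    base = dict(n_subjects=8, seed=21, template=template,
                baseline_modes=[(size_field(template), 0.03)],
                aging_drift=np.zeros(template.n_points * 6),
                effect_modes={}, noise_sd=0.0)
    base.update(kw)
    return SimulationConfig(**base)


def synthetic_trajectories(mean_vec, fields, coefs):
    """Directly constructed trajectories: transported = mean + coefs @ fields."""
    out = []
    for i, c in enumerate(coefs):
        disp = c @ fields
        out.append(Trajectory(subject_id=f"T{i:04d}", displacement=disp,
                              transported=mean_vec + disp))
    return out


class TestComputeTrajectories:
    def test_identical_exams_give_zero_displacement(self, template301):
        cohort = simulate_cohort(clean_config(template301))
        traj, mean_b, skipped = compute_trajectories(cohort.by_subject())
        assert not skipped
        for t in traj:
            np.testing.assert_array_equal(t.displacement, 0.0)
            np.testing.assert_array_equal(t.transported, mean_b.to_vector())

    def test_uniform_drift_recovered_exactly(self, template301):
        # no baseline variance, no pose: displacement must equal the planted
        # drift bit-for-bit, with zero between-subject variance
        drift = 0.01 * size_field(template301)
        cfg = clean_config(template301, baseline_modes=[],
                           aging_drift=drift,
                           pose_rotation_deg=0.0, pose_translation_mm=0.0)
        cohort = simulate_cohort(cfg)
        traj, mean_b, _ = compute_trajectories(cohort.by_subject())
        for t in traj:
            np.testing.assert_allclose(t.displacement, drift, atol=1e-9)
        stack = np.stack([t.displacement for t in traj])
        assert stack.std(axis=0).max() < 1e-12

    def test_linear_shift_identity(self, template301):
        # transported - mean_baseline == displacement, exactly, always
        cfg = clean_config(template301, noise_sd=0.4, n_subjects=6)
        cohort = simulate_cohort(cfg)
        traj, mean_b, _ = compute_trajectories(cohort.by_subject())
        mv = mean_b.to_vector()
        for t in traj:
            np.testing.assert_allclose(t.transported - mv, t.displacement,
                                       atol=1e-12)

    def test_missing_exam_skipped_with_reason(self, template301):
        cohort = simulate_cohort(clean_config(template301))
        by_subject = cohort.by_subject()
        sid = sorted(by_subject)[0]
        del by_subject[sid]["followup"]
        traj, _, skipped = compute_trajectories(by_subject)
        assert sid in skipped and "followup" in skipped[sid]
        assert len(traj) == len(by_subject) - 1

    def test_gre_baseline_requires_bias_model(self, template301):
        from lvatlas.fields import protocol_bias_field
        cfg = clean_config(template301,
                           protocol_bias=protocol_bias_field(template301))
        cohort = simulate_cohort(cfg)
        with pytest.raises(ValueError, match="bias model"):
            compute_trajectories(cohort.by_subject())


class TestBuildAtlas:
    def test_single_planted_mode_recovered(self, template301, rng):
        f = wall_field(template301)
        f = f / np.linalg.norm(f)
        coefs = rng.normal(0, 2.0, (60, 1))
        traj = synthetic_trajectories(template301.to_vector(), f[None, :],
                                      coefs)
        atlas = build_atlas(traj, template301)
        cos = abs(atlas.components[0] @ f)
        assert cos > 0.999
        assert atlas.explained_variance_ratio[0] > 0.999

    def test_two_orthogonal_modes_variance_ratio(self, template301, rng):
        f1 = wall_field(template301)
        f1 = f1 / np.linalg.norm(f1)
        f2 = size_field(template301)
        f2 = f2 - (f2 @ f1) * f1
        f2 = f2 / np.linalg.norm(f2)
        coefs = np.column_stack([rng.normal(0, 2.0, 500),
                                 rng.normal(0, 1.0, 500)])
        traj = synthetic_trajectories(template301.to_vector(),
                                      np.stack([f1, f2]), coefs)
        atlas = build_atlas(traj, template301)
        assert abs(atlas.components[0] @ f1) > 0.99
        assert abs(atlas.components[1] @ f2) > 0.99
        ratio = atlas.explained_variance[0] / atlas.explained_variance[1]
        assert ratio == pytest.approx(4.0, rel=0.2)

    def test_isotropic_noise_spectrum_flat(self, template301, rng):
        # d >> n regime: iid noise gives an approximately flat spectrum
        d = template301.n_points * 6
        coefs = rng.normal(0, 1.0, (200, d))
        traj = synthetic_trajectories(template301.to_vector(), np.eye(d)[:d],
                                      coefs)
        atlas = build_atlas(traj, template301)
        ev = atlas.explained_variance
        assert ev.max() / ev.min() < 3.0

    def test_ratios_sum_to_one(self, template301, rng):
        coefs = rng.normal(0, 1.0, (10, 2))
        fields = np.stack([size_field(template301), wall_field(template301)])
        traj = synthetic_trajectories(template301.to_vector(), fields, coefs)
        atlas = build_atlas(traj, template301)
        assert atlas.explained_variance_ratio.sum() == pytest.approx(1.0,
                                                                     abs=1e-8)
        gram = atlas.components @ atlas.components.T
        np.testing.assert_allclose(gram, np.eye(atlas.n_components),
                                   atol=1e-8)

    def test_minimum_trajectories(self, template301):
        with pytest.raises(ValueError):
            build_atlas([], template301)


@pytest.fixture(scope="module")
def fitted(template301):
    rng = np.random.default_rng(3)
    from lvatlas.fields import length_field
    fields = np.stack([size_field(template301), wall_field(template301),
                       length_field(template301)])
    coefs = rng.normal(0, [2.0, 1.0, 0.5], (40, 3))
    traj = synthetic_trajectories(template301.to_vector(), fields, coefs)
    atlas = build_atlas(traj, template301)
    return atlas, traj


class TestScores:
    def test_mean_trajectory_scores_zero(self, fitted):
        atlas, _ = fitted
        np.testing.assert_allclose(project_scores(atlas,
                                                  atlas.mean_trajectory),
                                   0.0, atol=1e-8)

    def test_unit_mode_scores_one(self, fitted):
        atlas, _ = fitted
        vec = atlas.mean_trajectory \
            + atlas.score_sd[0] * atlas.components[0]
        s = project_scores(atlas, vec)
        assert s[0] == pytest.approx(1.0, abs=1e-8)
        np.testing.assert_allclose(s[1:], 0.0, atol=1e-8)

    def test_training_scores_standardized(self, fitted):
        atlas, traj = fitted
        table = scores_table(atlas, traj)
        np.testing.assert_allclose(table.mean(axis=0), 0.0, atol=1e-8)
        np.testing.assert_allclose(table.std(axis=0, ddof=0), 1.0, atol=1e-6)

    def test_full_rank_reconstruction(self, fitted):
        atlas, traj = fitted
        for t in traj[:5]:
            s = project_scores(atlas, t)
            recon = atlas.mean_trajectory \
                + (s * atlas.score_sd) @ atlas.components
            np.testing.assert_allclose(recon, t.transported,
                                       rtol=1e-6, atol=1e-6)

    def test_constant_field_shifts_scores_along_its_direction(self, fitted):
        # transport additivity: adding a constant field c to every follow-up
        # moves every score vector by the same in-basis offset
        atlas, traj = fitted
        c = 0.5 * atlas.components[1] * atlas.score_sd[1]
        s0 = np.stack([project_scores(atlas, t) for t in traj[:8]])
        s1 = np.stack([project_scores(atlas, t.transported + c)
                       for t in traj[:8]])
        delta = s1 - s0
        np.testing.assert_allclose(delta[:, 1], 0.5, atol=1e-8)
        np.testing.assert_allclose(delta[:, [0, 2]], 0.0, atol=1e-8)

    def test_degenerate_component_flagged(self, template301, fitted):
        atlas, traj = fitted
        import copy
        degen = copy.deepcopy(atlas)
        degen.score_sd = degen.score_sd.copy()
        degen.score_sd[2] = 0.0
        with pytest.warns(UserWarning, match="degenerate"):
            s = project_scores(degen, traj[0])
        assert s[2] == 0.0


class TestCrossSectionalInvariance:
    def test_baseline_variance_scaling_leaves_scores_unchanged(self,
                                                               template301):
        # the point of transport: multiply baseline inter-subject variance
        # by 10 while keeping each subject's displacement fixed -> identical
        # z-scores. Baseline variation is a pure scaling mode so the GPA
        # rotations are unaffected.
        rng = np.random.default_rng(5)
        n = 30
        drift = wall_field(template301)
        base_mode = size_field(template301)
        disp = rng.normal(0, 0.8, n)[:, None] * drift[None, :]
        base_coef = rng.normal(0, 0.02, n)

        def cohort_shapes(scale):
            tvec = template301.to_vector()
            by_subject = {}
            for i in range(n):
                b = tvec + scale * base_coef[i] * base_mode
                by_subject[f"S{i:03d}"] = {
                    "baseline": template301.with_vector(
                        b, subject_id=f"S{i:03d}", exam="baseline",
                        protocol="SSFP"),
                    "followup": template301.with_vector(
                        b + disp[i], subject_id=f"S{i:03d}", exam="followup",
                        protocol="SSFP"),
                }
            return by_subject

        scores = {}
        for scale in (1.0, 10.0):
            traj, mean_b, _ = compute_trajectories(cohort_shapes(scale))
            atlas = build_atlas(traj, mean_b)
            scores[scale] = scores_table(atlas, traj).iloc[:, :3].to_numpy()
        assert np.abs(scores[1.0] - scores[10.0]).max() < 1e-6
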