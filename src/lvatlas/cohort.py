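"""Synthetic longitudinal cohort generator.

Emulates the statistical structure the downstream analysis assumes for a
two-exam (baseline, 10-year follow-up) CMR cohort:

* baseline inter-subject shape variation (a few global modes),
* a population aging drift over the exam interval,
* covariate-driven per-risk-factor remodeling effect modes,
* spatially smooth measurement noise (optionally iid),
* an optional systematic GRE/SSFP protocol bias on the baseline exam,
* a covariate table whose risk-factor prevalences and exam-to-exam
  transitions track a large multi-ethnic population cohort
  (obesity ~ 0.3, diabetes ~ 0.17-0.2 at follow-up, and so on),
* random per-subject pose (the same pose for both exams, as both scans are
  expressed in the subject's scanner frame).

Everything is reproducible from the config seed, and the planted truth
(mode coefficients, effect fields, labels) is returned for
parameter-recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import fields as F
from .association import RISK_FACTORS, derive_risk_labels
from .geometry import LVShape
from .template import make_template

EXAMS = ("baseline", "followup")


def exclusion_flow(initial: int,
                   exclusions: Sequence[Tuple[str, int]]) -> pd.DataFrame:
    """Sequential cohort exclusion arithmetic.

    Returns one row per stage with the number excluded and the number
    remaining after each exclusion, starting from ``initial`` participants.
    """
    if initial < 0:
        raise ValueError("initial cohort size must be non-negative")
    rows = [{"stage": "initial", "excluded": 0, "remaining": int(initial)}]
    remaining = int(initial)
    for stage, n_excl in exclusions:
        n_excl = int(n_excl)
        if n_excl < 0 or n_excl > remaining:
            raise ValueError(f"cannot exclude {n_excl} of {remaining} "
                             f"at stage {stage!r}")
        remaining -= n_excl
        rows.append({"stage": stage, "excluded": n_excl,
                     "remaining": remaining})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# covariate simulation


@dataclass
class CovariateSpec:
    """Distribution parameters for the simulated covariate table.

    Defaults follow the baseline/follow-up summary statistics of a large
    multi-ethnic cohort: mean age ~60 y at baseline, 54% female, BMI
    27.7 +/- 4.8 kg/m^2 (obesity prevalence near 0.3), rising treated
    diabetes, hypertension-diagnosis and statin use over the decade, and
    falling smoking prevalence.
    """

    age_mean: float = 59.6
    age_sd: float = 9.4
    female_p: float = 0.543
    race_p: Dict[str, float] = dc_field(default_factory=lambda: {
        "white": 0.415, "asian": 0.134, "african_american": 0.245,
        "hispanic": 0.206})
    bmi_mean: float = 27.7
    bmi_sd: float = 4.8
    bmi_change_mean: float = 0.1
    bmi_change_sd: float = 2.0
    sbp_mean: float = 123.3
    sbp_sd: float = 20.0
    sbp_change_sd: float = 15.0
    dbp_mean: float = 71.8
    dbp_sd: float = 10.1
    dbp_change_mean: float = -3.5
    dbp_change_sd: float = 8.0
    tc_mean: float = 194.8
    tc_sd: float = 35.0
    tc_change_mean: float = -10.4
    ldl_mean: float = 117.8
    ldl_sd: float = 30.9
    ldl_change_mean: float = -11.0
    hdl_mean: float = 51.6
    hdl_sd: float = 15.4
    hdl_change_mean: float = 4.5
    tg_mean: float = 130.0
    tg_sd: float = 65.0
    lipid_change_sd: float = 20.0
    smoker_p: float = 0.105
    smoker_quit_p: float = 0.33
    smoker_incident_p: float = 0.005
    htn_diagnosis_p: float = 0.378
    htn_incident_p: float = 0.31
    htn_med_given_diag_p: float = 0.75
    htn_med_given_nodiag_p: float = 0.045
    htn_med_fu_given_diag_p: float = 0.88
    statin_p: float = 0.134
    statin_incident_p: float = 0.251
    diabetes_p: Dict[str, float] = dc_field(default_factory=lambda: {
        "none": 0.809, "ifg": 0.116, "untreated": 0.013, "treated": 0.062})
    bsa_mean: float = 1.85
    bsa_sd: float = 0.22
    bsa_change_mean: float = 0.01
    bsa_change_sd: float = 0.06


def simulate_covariates(n: int, spec: CovariateSpec,
                        rng: np.random.Generator) -> pd.DataFrame:
    """Covariate table: one row per subject per exam."""
    sid = [f"S{i:05d}" for i in range(n)]
    age0 = np.clip(rng.normal(spec.age_mean, spec.age_sd, n), 45, 84)
    sex = np.where(rng.random(n) < spec.female_p, "female", "male")
    races = list(spec.race_p)
    race = rng.choice(races, size=n, p=np.array([spec.race_p[r] for r in races]))

    bmi0 = np.clip(rng.normal(spec.bmi_mean, spec.bmi_sd, n), 16, 55)
    bmi1 = np.clip(bmi0 + rng.normal(spec.bmi_change_mean,
                                     spec.bmi_change_sd, n), 16, 60)
    sbp0 = np.clip(rng.normal(spec.sbp_mean, spec.sbp_sd, n), 80, 220)
    sbp1 = np.clip(sbp0 + rng.normal(0, spec.sbp_change_sd, n), 80, 230)
    dbp0 = np.clip(rng.normal(spec.dbp_mean, spec.dbp_sd, n), 40, 130)
    dbp1 = np.clip(dbp0 + rng.normal(spec.dbp_change_mean,
                                     spec.dbp_change_sd, n), 40, 130)
    tc0 = np.clip(rng.normal(spec.tc_mean, spec.tc_sd, n), 90, 400)
    tc1 = np.clip(tc0 + rng.normal(spec.tc_change_mean,
                                   spec.lipid_change_sd, n), 90, 400)
    ldl0 = np.clip(rng.normal(spec.ldl_mean, spec.ldl_sd, n), 30, 300)
    ldl1 = np.clip(ldl0 + rng.normal(spec.ldl_change_mean,
                                     spec.lipid_change_sd, n), 30, 300)
    hdl0 = np.clip(rng.normal(spec.hdl_mean, spec.hdl_sd, n), 15, 130)
    hdl1 = np.clip(hdl0 + rng.normal(spec.hdl_change_mean,
                                     spec.lipid_change_sd / 2, n), 15, 130)
    tg0 = np.clip(rng.normal(spec.tg_mean, spec.tg_sd, n), 30, 600)
    tg1 = np.clip(tg0 + rng.normal(0, spec.lipid_change_sd * 2, n), 30, 600)

    smoke0 = rng.random(n) < spec.smoker_p
    smoke1 = np.where(smoke0, rng.random(n) >= spec.smoker_quit_p,
                      rng.random(n) < spec.smoker_incident_p)

    diag0 = rng.random(n) < spec.htn_diagnosis_p
    diag1 = diag0 | (rng.random(n) < spec.htn_incident_p)
    med0 = np.where(diag0, rng.random(n) < spec.htn_med_given_diag_p,
                    rng.random(n) < spec.htn_med_given_nodiag_p)
    med1 = med0 | np.where(diag1, rng.random(n) < spec.htn_med_fu_given_diag_p,
                           False)

    statin0 = rng.random(n) < spec.statin_p
    statin1 = statin0 | (rng.random(n) < spec.statin_incident_p)

    states = list(spec.diabetes_p)
    dia0 = rng.choice(states, size=n,
                      p=np.array([spec.diabetes_p[s] for s in states]))
    dia1 = dia0.copy()
    u = rng.random(n)
    none_m = dia0 == "none"
    dia1[none_m & (u < 0.17)] = "ifg"
    dia1[none_m & (u >= 0.17) & (u < 0.20)] = "treated"
    dia1[none_m & (u >= 0.20) & (u < 0.205)] = "untreated"
    ifg_m = dia0 == "ifg"
    dia1[ifg_m & (u < 0.40)] = "treated"
    dia1[ifg_m & (u >= 0.40) & (u < 0.50)] = "none"
    untr_m = dia0 == "untreated"
    dia1[untr_m & (u < 0.45)] = "treated"

    bsa0 = np.clip(rng.normal(spec.bsa_mean, spec.bsa_sd, n), 1.3, 2.6)
    bsa1 = np.clip(bsa0 + rng.normal(spec.bsa_change_mean,
                                     spec.bsa_change_sd, n), 1.3, 2.6)

    rows = []
    for exam, age, bmi, sbp, dbp, tc, ldl, hdl, tg, smoke, diag, med, \
            statin, dia, bsa in (
            ("baseline", age0, bmi0, sbp0, dbp0, tc0, ldl0, hdl0, tg0,
             smoke0, diag0, med0, statin0, dia0, bsa0),
            ("followup", age0 + 10, bmi1, sbp1, dbp1, tc1, ldl1, hdl1, tg1,
             smoke1, diag1, med1, statin1, dia1, bsa1)):
        rows.append(pd.DataFrame({
            "subject_id": sid, "exam": exam, "age": age, "sex": sex,
            "race_ethnicity": race, "bmi": bmi, "sbp": sbp, "dbp": dbp,
            "total_cholesterol": tc, "ldl": ldl, "hdl": hdl,
            "triglycerides": tg, "smoker": smoke.astype(bool),
            "htn_diagnosis": diag.astype(bool), "htn_medication": med.astype(bool),
            "statins": statin.astype(bool), "diabetes_status": dia,
            "bsa": bsa,
        }))
    return pd.concat(rows, ignore_index=True)


# ---------------------------------------------------------------------------
# shape simulation


@dataclass
class SimulationConfig:
    """All knobs of the synthetic cohort.

    Displacement-field entries default to the study-like conditions built on
    the template (see :mod:`lvatlas.fields`); ``None`` means "build the
    default on first use". ``protocol_bias=None`` simulates an already
    harmonized cohort (baseline labeled SSFP); passing a bias field labels
    baselines GRE and subtracts the bias from them, so the observed GRE
    baselines differ from the SSFP-equivalent truth by the planted bias.
    """

    n_subjects: int = 200
    seed: int = 0
    template: Optional[LVShape] = None
    p_per_surface: int = 781
    baseline_modes: Optional[List[Tuple[np.ndarray, float]]] = None
    aging_drift: Optional[np.ndarray] = None
    effect_modes: Optional[Dict[str, Tuple[np.ndarray, float]]] = None
    noise_sd: float = 0.5                   # mm per coordinate
    noise_model: str = "smooth"             # "smooth" | "iid"
    n_noise_fields: int = 60
    protocol_bias: Optional[np.ndarray] = None
    bias_noise_sd: float = 0.0
    interval_years: float = 10.0
    pose_rotation_deg: float = 5.0
    pose_translation_mm: float = 5.0
    covariate_spec: CovariateSpec = dc_field(default_factory=CovariateSpec)

    def resolve(self) -> "SimulationConfig":
        """Fill in template-dependent defaults; validates field lengths."""
        if self.n_subjects < 2:
            raise ValueError("n_subjects must be at least 2")
        if self.template is None:
            self.template = make_template(p_per_surface=self.p_per_surface)
        d = 2 * self.template.n_points * 3
        if self.baseline_modes is None:
            t = self.template
            self.baseline_modes = [
                (F.size_field(t), 0.04),
                (F.length_field(t), 0.03),
                (F.wall_field(t), 0.8),
                (F.sphericity_field(t), 0.02),
            ]
        if self.aging_drift is None:
            self.aging_drift = F.aging_drift_field(self.template)
        if self.effect_modes is None:
            eff = F.default_effect_fields(self.template)
            self.effect_modes = {k: (v, 1.0) for k, v in eff.items()}
        for f, sd in self.baseline_modes:
            if len(f) != d or sd < 0:
                raise ValueError("baseline mode field length/SD invalid")
        if len(self.aging_drift) != d:
            raise ValueError("aging drift field has wrong length")
        for name, (f, _) in self.effect_modes.items():
            if len(f) != d:
                raise ValueError(f"effect field {name!r} has wrong length")
        if self.protocol_bias is not None and len(self.protocol_bias) != d:
            raise ValueError("protocol bias field has wrong length")
        if self.noise_sd < 0 or self.bias_noise_sd < 0:
            raise ValueError("noise SDs must be non-negative")
        return self


@dataclass
class SyntheticCohort:
    shapes: Dict[Tuple[str, str], LVShape]     # (subject_id, exam) -> shape
    covariates: pd.DataFrame
    truth: Dict
    config: SimulationConfig

    def subject_ids(self) -> List[str]:
        return sorted({sid for sid, _ in self.shapes})

    def by_subject(self) -> Dict[str, Dict[str, LVShape]]:
        out: Dict[str, Dict[str, LVShape]] = {}
        for (sid, exam), s in self.shapes.items():
            out.setdefault(sid, {})[exam] = s
        return out

    def all_shapes(self) -> List[LVShape]:
        return [self.shapes[k] for k in sorted(self.shapes)]


def _noise_sampler(cfg: SimulationConfig, seed: int):
    d = 2 * cfg.template.n_points * 3
    if cfg.noise_model == "iid":
        def sample(rng, sd):
            return rng.normal(0.0, sd, d) if sd > 0 else np.zeros(d)
        return sample
    if cfg.noise_model != "smooth":
        raise ValueError(f"unknown noise model {cfg.noise_model!r}")
    basis = F.smooth_noise_basis(cfg.template, cfg.n_noise_fields, seed=seed)
    k = basis.shape[1]

    def sample(rng, sd):
        if sd <= 0:
            return np.zeros(d)
        return basis @ rng.normal(0.0, sd / np.sqrt(k), k)
    return sample


def _random_pose(rng, rot_deg: float, trans_mm: float):
    from scipy.spatial.transform import Rotation
    from .align import RigidTransform
    if rot_deg <= 0 and trans_mm <= 0:
        return RigidTransform.identity()
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    angle = np.radians(rng.uniform(-rot_deg, rot_deg))
    r = Rotation.from_rotvec(angle * axis).as_matrix()
    t = rng.uniform(-trans_mm, trans_mm, 3)
    return RigidTransform(r, t)


def simulate_cohort(config: SimulationConfig) -> SyntheticCohort:
    """Generate a full two-exam cohort with planted truth.

    baseline_i = template + sum_k c_ik * mode_k + noise
    followup_i = baseline_i + drift * interval/10
                 + sum_f size_f * x_if * field_f + noise'
    with x_if the follow-up risk-factor indicator derived from the simulated
    covariates, and the observed baseline additionally offset by the negative
    protocol-bias field (plus bias noise) when a bias is configured.
    """
    from .align import transform_shape

    cfg = config.resolve()
    ss = np.random.SeedSequence(cfg.seed)
    rng_cov, rng_modes, rng_noise, rng_pose, rng_bias, ss_basis = [
        np.random.default_rng(s) for s in ss.spawn(5)] + [ss.spawn(1)[0]]
    basis_seed = int(ss_basis.generate_state(1)[0] % (2 ** 31))
    sample_noise = _noise_sampler(cfg, basis_seed)

    n = cfg.n_subjects
    covariates = simulate_covariates(n, cfg.covariate_spec, rng_cov)
    labels = derive_risk_labels(covariates)
    x = pd.DataFrame(
        {f: (labels[f] == "positive").astype(float) for f in labels.columns},
        index=labels.index)

    template_vec = cfg.template.to_vector()
    sids = sorted(x.index)
    d = len(template_vec)
    if cfg.baseline_modes:
        mode_fields = np.stack([f for f, _ in cfg.baseline_modes])
        mode_sds = np.array([sd for _, sd in cfg.baseline_modes])
    else:
        mode_fields = np.zeros((1, d))
        mode_sds = np.zeros(1)
    coefs = rng_modes.normal(0.0, 1.0, (n, len(mode_sds))) * mode_sds

    shapes: Dict[Tuple[str, str], LVShape] = {}
    drift = cfg.aging_drift * (cfg.interval_years / 10.0)
    for i, sid in enumerate(sids):
        base_true = template_vec + coefs[i] @ mode_fields \
            + sample_noise(rng_noise, cfg.noise_sd)
        effect = np.zeros_like(base_true)
        for fname, (fld, size) in cfg.effect_modes.items():
            xi = float(x.loc[sid, fname]) if fname in x.columns else 0.0
            if xi:
                effect += size * xi * fld
        follow = base_true + drift + effect \
            + sample_noise(rng_noise, cfg.noise_sd)

        if cfg.protocol_bias is not None:
            base_obs = base_true - cfg.protocol_bias \
                - sample_noise(rng_bias, cfg.bias_noise_sd)
            base_protocol = "GRE"
        else:
            base_obs = base_true
            base_protocol = "SSFP"

        pose = _random_pose(rng_pose, cfg.pose_rotation_deg,
                            cfg.pose_translation_mm)
        base_shape = cfg.template.with_vector(base_obs, subject_id=sid,
                                              exam="baseline",
                                              protocol=base_protocol)
        fu_shape = cfg.template.with_vector(follow, subject_id=sid,
                                            exam="followup", protocol="SSFP")
        shapes[(sid, "baseline")] = transform_shape(base_shape, pose)
        shapes[(sid, "followup")] = transform_shape(fu_shape, pose)

    truth = {
        "seed": cfg.seed,
        "mode_coefficients": pd.DataFrame(coefs, index=sids),
        "effect_fields": {k: v[0] * v[1] for k, v in cfg.effect_modes.items()},
        "labels": x,
        "drift": drift,
    }
    return SyntheticCohort(shapes=shapes, covariates=covariates,
                           truth=truth, config=cfg)


def simulate_protocol_pairs(n: int, seed: int = 0,
                            template: Optional[LVShape] = None,
                            bias: Optional[np.ndarray] = None,
                            noise_sd: float = 0.3,
                            subject_sd: float = 0.04,
                            pose_rotation_deg: float = 5.0,
                            pose_translation_mm: float = 5.0,
                            ) -> List[Tuple[LVShape, LVShape]]:
    """Paired same-session GRE/SSFP scans of n subjects.

    SSFP_i = GRE_i + bias + smooth noise, with the default bias moving the
    endocardium outward and the epicardium inward so that SSFP shows a larger
    cavity volume and smaller mass than GRE on average. Subjects vary by the
    default baseline modes scaled by ``subject_sd``; each pair shares one
    random pose (same session coordinates).
    """
    from .align import transform_shape

    if n < 3:
        raise ValueError("need at least 3 pairs")
    if template is None:
        template = make_template()
    if bias is None:
        bias = F.protocol_bias_field(template)
    d = 2 * template.n_points * 3
    if len(bias) != d:
        raise ValueError("bias field has wrong length")

    ss = np.random.SeedSequence(seed)
    rng_modes, rng_noise, rng_pose, ss_basis = [
        np.random.default_rng(s) for s in ss.spawn(3)] + [ss.spawn(1)[0]]
    basis = F.smooth_noise_basis(
        template, 60, seed=int(ss_basis.generate_state(1)[0] % (2 ** 31)))
    k = basis.shape[1]

    modes = [(F.size_field(template), subject_sd),
             (F.length_field(template), subject_sd * 0.75),
             (F.wall_field(template), 0.6)]
    tvec = template.to_vector()
    pairs = []
    for i in range(n):
        v = tvec.copy()
        for fld, sd in modes:
            v = v + rng_modes.normal(0.0, sd) * fld
        ssfp_v = v + bias
        if noise_sd > 0:
            v = v + basis @ rng_noise.normal(0, noise_sd / np.sqrt(k), k)
            ssfp_v = ssfp_v + basis @ rng_noise.normal(
                0, noise_sd / np.sqrt(k), k)
        pose = _random_pose(rng_pose, pose_rotation_deg, pose_translation_mm)
        gre = transform_shape(
            template.with_vector(v, subject_id=f"P{i:04d}", exam="baseline",
                                 protocol="GRE"), pose)
        ssfp = transform_shape(
            template.with_vector(ssfp_v, subject_id=f"P{i:04d}",
                                 exam="baseline", protocol="SSFP"), pose)
        pairs.append((gre, ssfp))
    return pairs
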