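"""End-to-end pipeline orchestration.

Runs simulate -> bias fit/apply -> trajectories -> atlas -> scores ->
association -> remodeling modes, writing every stage's outputs (CSV/JSON)
plus the resolved configuration, a checksum manifest and a timing log to
the run directory. Identical config and seed give bit-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field as dc_field
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np
import pandas as pd
import yaml

from . import io as lvio
from .association import CVSettings, cv_compare, derive_risk_labels
from .atlas import build_atlas, compute_trajectories, scores_table
from .bias import fit_bias_model, loo_validate
from .cohort import SimulationConfig, simulate_cohort, simulate_protocol_pairs
from .fields import protocol_bias_field
from .geometry import measures_table
from .modes import DEFAULT_PREDICTORS, fit_mode_regression, measure_change_sd, \
    reconstruct_mode, sem_filter


@dataclass
class PipelineConfig:
    """Serializable settings for a full synthetic-cohort run."""

    seed: int = 0
    n_subjects: int = 200
    n_pairs: int = 60
    p_per_surface: int = 301
    noise_sd: float = 0.5
    simulate_protocol_bias: bool = True
    bias_variance_keep: float = 0.95
    bias_n_plsr: Optional[int] = 10
    atlas_variance_fraction: float = 0.99
    cv: Dict = dc_field(default_factory=dict)     # CVSettings overrides
    chol_rule: str = "any"
    bp_rule: str = "and"
    mode_predictors: List[str] = dc_field(
        default_factory=lambda: list(DEFAULT_PREDICTORS))
    run_association: bool = True
    run_modes: bool = True

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: PipelineConfig, out_dir) -> Dict:
    """Execute the full pipeline; returns a dict of in-memory results."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log: List[str] = []
    t0 = time.time()

    def stage(msg):
        log.append(f"[{time.time() - t0:8.1f}s] {msg}")

    results: Dict = {}
    try:
        ss = np.random.SeedSequence(config.seed)
        seeds = [int(s.generate_state(1)[0] % (2 ** 31)) for s in ss.spawn(3)]

        stage("simulate: cohort")
        sim_cfg = SimulationConfig(n_subjects=config.n_subjects,
                                   seed=seeds[0],
                                   p_per_surface=config.p_per_surface,
                                   noise_sd=config.noise_sd)
        sim_cfg.resolve()
        if config.simulate_protocol_bias:
            sim_cfg.protocol_bias = protocol_bias_field(sim_cfg.template)
            sim_cfg.bias_noise_sd = 0.2
        cohort = simulate_cohort(sim_cfg)
        results["cohort"] = cohort
        cohort.covariates.to_csv(out / "covariates.csv", index=False)

        bias_model = None
        if config.simulate_protocol_bias:
            stage("bias: simulate pairs and fit")
            pairs = simulate_protocol_pairs(config.n_pairs, seed=seeds[1],
                                            template=sim_cfg.template)
            bias_model = fit_bias_model(pairs,
                                        variance_keep=config.bias_variance_keep,
                                        n_plsr=config.bias_n_plsr)
            bias_model.save(out / "bias_model")
            results["bias_model"] = bias_model

        stage("trajectories and atlas")
        trajectories, mean_baseline, skipped = compute_trajectories(
            cohort.by_subject(), bias_model=bias_model)
        atlas = build_atlas(trajectories, mean_baseline)
        results["atlas"] = atlas
        m99 = atlas.n_components_for_variance(config.atlas_variance_fraction)
        scores = scores_table(atlas, trajectories)
        scores.to_csv(out / "scores.csv")
        np.savetxt(out / "atlas_variance.csv",
                   np.column_stack([atlas.explained_variance,
                                    atlas.explained_variance_ratio]),
                   delimiter=",", header="variance,ratio")
        results["scores"] = scores
        stage(f"atlas built: {atlas.n_components} components, "
              f"{m99} cover {config.atlas_variance_fraction:.0%}")

        stage("derived measures")
        measures = measures_table(cohort.all_shapes())
        measures.to_csv(out / "measures.csv", index=False)
        results["measures"] = measures

        labels = derive_risk_labels(cohort.covariates,
                                    chol_rule=config.chol_rule,
                                    bp_rule=config.bp_rule)
        labels.to_csv(out / "labels.csv")
        results["labels"] = labels

        if config.run_association:
            stage("association: Atlas vs Mass-Volume CV")
            mv = _mv_features(measures)
            cv_settings = CVSettings(**config.cv) if config.cv else CVSettings()
            cv = cv_compare(scores.iloc[:, :m99], mv, labels,
                            cohort.covariates, seed=seeds[2],
                            settings=cv_settings)
            cv.folds.to_csv(out / "cv_folds.csv", index=False)
            cv.summary.to_csv(out / "cv_summary.csv", index=False)
            results["cv"] = cv

        if config.run_modes:
            stage("remodeling modes")
            fit = fit_mode_regression(scores.iloc[:, :m99],
                                      cohort.covariates,
                                      predictors=config.mode_predictors,
                                      labels=labels)
            fit.coefficients.to_csv(out / "mode_coefficients.csv")
            sd, n_pairs_meas = measure_change_sd(measures)
            mode_rows = {}
            for factor in fit.predictors:
                if factor == "intercept":
                    continue
                mode = reconstruct_mode(fit, atlas, factor)
                shown, sem, mask = sem_filter(mode.measure_deltas, sd,
                                              n_pairs_meas)
                mode.sem, mode.masked = sem, mask
                mode_rows[factor] = shown
                np.savetxt(out / f"mode_{factor}_displacement.csv",
                           mode.displacement, delimiter=",")
            results["modes"] = mode_rows
            pd.DataFrame(mode_rows).T.to_csv(out / "mode_measure_deltas.csv")

        stage("write manifest")
        manifest = {p.name: _sha256(p) for p in sorted(out.glob("*.csv"))}
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
        config.to_yaml(out / "config_resolved.yaml")
        stage("done")
    except Exception as exc:
        stage(f"FAILED: {type(exc).__name__}: {exc}")
        (out / "run.log").write_text("\n".join(log) + "\n")
        raise
    (out / "run.log").write_text("\n".join(log) + "\n")
    return results


def _mv_features(measures: pd.DataFrame) -> pd.DataFrame:
    """Mass-Volume model features: follow-up minus baseline EDV/ESV/mass/EF."""
    piv = {exam: measures[measures["exam"] == exam].set_index("subject_id")
           for exam in ("baseline", "followup")}
    common = piv["baseline"].index.intersection(piv["followup"].index)
    out = pd.DataFrame(index=common.sort_values())
    for col in ("EDV", "ESV", "mass", "EF"):
        out[f"delta_{col}"] = (piv["followup"].loc[out.index, col]
                               - piv["baseline"].loc[out.index, col])
    return out
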