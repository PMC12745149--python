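"""Remodeling trajectories and the longitudinal PCA shape atlas.

A subject's *remodeling trajectory* is the displacement field from their
(bias-corrected, GPA-aligned) baseline shape to their follow-up shape. The
trajectory is parallel-transported onto the common reference — the mean
baseline shape — by *linear shift*, i.e., plain vector addition, which is
the appropriate transport when shapes are close enough to share a tangent
space. PCA on the transported shapes gives the longitudinal atlas; each
subject's loadings, z-scored by the training-score standard deviations, are
the trajectory scores used in all downstream association analyses. Because
transport subtracts each subject's own baseline, cross-sectional (between-
subject) shape variance does not leak into the scores.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .align import procrustes_align, transform_shape
from .bias import BiasModel, apply_bias_correction
from .geometry import LVShape


@dataclass
class Trajectory:
    subject_id: str
    displacement: np.ndarray        # follow-up minus baseline, aligned frame
    transported: np.ndarray         # mean_baseline + displacement


@dataclass
class TrajectoryAtlas:
    mean_baseline: np.ndarray       # (2*P*3,) shape vector
    mean_trajectory: np.ndarray     # (2*P*3,) mean transported shape
    components: np.ndarray          # (M, 2*P*3) orthonormal
    explained_variance: np.ndarray  # (M,)
    explained_variance_ratio: np.ndarray
    score_sd: np.ndarray            # (M,) training-score SDs for z-scoring
    n_subjects: int
    reference_shape: Optional[LVShape] = None   # topology/landmark carrier

    @property
    def n_components(self) -> int:
        return self.components.shape[0]

    def n_components_for_variance(self, fraction: float) -> int:
        """Smallest component count covering ``fraction`` of the variance."""
        if not 0 < fraction <= 1:
            raise ValueError("fraction must be in (0, 1]")
        cum = np.cumsum(self.explained_variance_ratio)
        return int(np.searchsorted(cum, fraction - 1e-12) + 1)

    def shape_from_vector(self, vec: np.ndarray, **updates) -> LVShape:
        if self.reference_shape is None:
            raise ValueError("atlas has no reference shape attached")
        return self.reference_shape.with_vector(vec, **updates)


def compute_trajectories(shapes_by_subject: Mapping[str, Mapping[str, LVShape]],
                         bias_model: Optional[BiasModel] = None,
                         mode: str = "rigid",
                         ) -> Tuple[List[Trajectory], LVShape, Dict[str, str]]:
    """Per-subject displacement fields transported to the mean baseline.

    GRE baselines are first corrected to SSFP-equivalents (``bias_model``
    required if any are present). All baselines are then GPA-aligned; each
    follow-up inherits its subject's baseline transform so the subtraction
    is not polluted by pose. Subjects missing an exam are skipped with a
    logged reason.

    Returns ``(trajectories, mean_baseline_shape, skipped)``.
    """
    usable: List[Tuple[str, LVShape, LVShape]] = []
    skipped: Dict[str, str] = {}
    for sid in sorted(shapes_by_subject):
        exams = shapes_by_subject[sid]
        if "baseline" not in exams or "followup" not in exams:
            missing = {"baseline", "followup"} - set(exams)
            skipped[sid] = f"missing exam(s): {sorted(missing)}"
            continue
        base = exams["baseline"]
        if base.protocol == "GRE" and not base.bias_corrected:
            if bias_model is None:
                raise ValueError(
                    f"subject {sid}: baseline is GRE; a bias model is "
                    "required to compute protocol-consistent trajectories")
            base = apply_bias_correction(bias_model, base)
        usable.append((sid, base, exams["followup"]))
    if len(usable) < 2:
        raise ValueError("need at least 2 complete subjects")

    baselines = [b for _, b, _ in usable]
    aligned_base, mean_shape, transforms = procrustes_align(baselines,
                                                            mode=mode)
    mean_vec = mean_shape.to_vector()
    trajectories = []
    for (sid, _, fu), ab, tf in zip(usable, aligned_base, transforms):
        fu_aligned = transform_shape(fu, tf)
        disp = fu_aligned.to_vector() - ab.to_vector()
        trajectories.append(Trajectory(subject_id=sid, displacement=disp,
                                       transported=mean_vec + disp))
    return trajectories, mean_shape, skipped


def build_atlas(trajectories: Sequence[Trajectory],
                mean_baseline: LVShape,
                n_components: Optional[int] = None) -> TrajectoryAtlas:
    """PCA atlas of the transported trajectories.

    Components are sorted by decreasing variance and sign-fixed so the
    largest-magnitude loading of each component is positive, making score
    signs reproducible across runs. ``n_components`` defaults to full rank;
    downstream consumers truncate by explained variance.
    """
    if len(trajectories) < 3:
        raise ValueError("atlas construction needs at least 3 trajectories")
    x = np.stack([t.transported for t in trajectories])
    n = x.shape[0]
    max_rank = min(n - 1, x.shape[1])
    m = max_rank if n_components is None else min(n_components, max_rank)
    pca = PCA(n_components=m, svd_solver="full")
    scores = pca.fit_transform(x)
    # drop numerically-null trailing components (data rank < requested M):
    # their ~0 score SDs would amplify roundoff into meaningless z-scores
    ev = pca.explained_variance_
    keep = ev > ev[0] * 1e-10
    m_eff = int(keep.sum())
    scores = scores[:, :m_eff]
    comps = pca.components_[:m_eff].copy()
    # deterministic sign: positive dot with a fixed reference vector (robust
    # to loading-magnitude ties on symmetric templates, where the
    # largest-|loading| rule flips with roundoff)
    ref = np.random.default_rng(0).standard_normal(comps.shape[1])
    for j in range(comps.shape[0]):
        if comps[j] @ ref < 0:
            comps[j] = -comps[j]
            scores[:, j] = -scores[:, j]
    sd = scores.std(axis=0, ddof=0)
    ratio = pca.explained_variance_ratio_[:m_eff].copy()
    return TrajectoryAtlas(
        mean_baseline=mean_baseline.to_vector(),
        mean_trajectory=pca.mean_.copy(),
        components=comps,
        explained_variance=ev[:m_eff].copy(),
        explained_variance_ratio=ratio / ratio.sum(),
        score_sd=sd, n_subjects=n, reference_shape=mean_baseline)


def project_scores(atlas: TrajectoryAtlas, trajectory) -> np.ndarray:
    """Z-scored atlas loadings of one trajectory (or raw transported vector).

    score_m = <transported - mean_trajectory, component_m> / score_sd_m.
    Components with zero training-score SD are degenerate: their score is
    set to 0 with a warning.
    """
    vec = trajectory.transported if isinstance(trajectory, Trajectory) \
        else np.asarray(trajectory, float)
    if vec.shape != (atlas.components.shape[1],):
        raise ValueError("trajectory length does not match the atlas")
    raw = atlas.components @ (vec - atlas.mean_trajectory)
    degenerate = atlas.score_sd <= 0
    if degenerate.any():
        warnings.warn(f"{int(degenerate.sum())} degenerate atlas component(s) "
                      "with zero score SD; their z-scores are set to 0")
    out = np.zeros_like(raw)
    ok = ~degenerate
    out[ok] = raw[ok] / atlas.score_sd[ok]
    return out


def scores_table(atlas: TrajectoryAtlas,
                 trajectories: Sequence[Trajectory]) -> pd.DataFrame:
    """Subject-indexed z-score matrix (columns score_1..score_M)."""
    data = {t.subject_id: project_scores(atlas, t) for t in trajectories}
    df = pd.DataFrame.from_dict(data, orient="index")
    df.columns = [f"score_{j + 1}" for j in range(atlas.n_components)]
    df.index.name = "subject_id"
    return df.sort_index()
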