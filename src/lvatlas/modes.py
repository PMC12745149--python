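"""Risk-related remodeling modes from multivariate regression on atlas scores.

Each retained atlas component's z-scores are regressed (ordinary least
squares, shared design) on baseline age, BSA change, continuous risk
measures, race/ethnicity dummies and the binary risk factors. A factor's
*remodeling mode* is the 3D displacement field obtained by propagating its
coefficient row back through the atlas (coefficients x score SDs x
components), all other predictors held at reference. Modes are summarized
as percent changes of the conventional measures on the mean shape and as
AHA-17 regional wall-thickening changes, with below-SEM entries masked.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .association import derive_risk_labels
from .atlas import TrajectoryAtlas
from .geometry import DerivedMeasures, LVShape, aha17_segment_map, \
    derived_measures, per_point_wall_thickness

CONTINUOUS_PREDICTORS = ("age_baseline", "delta_bsa", "sbp", "dbp", "bmi",
                         "hdl", "ldl")
RACE_DUMMIES = ("race_asian", "race_african_american", "race_hispanic")
BINARY_PREDICTORS = ("smoking", "sex_male", "diabetes", "statins",
                     "htn_medication")
DEFAULT_PREDICTORS = CONTINUOUS_PREDICTORS + RACE_DUMMIES + BINARY_PREDICTORS


@dataclass
class ModeRegressionFit:
    predictors: List[str]
    coefficients: pd.DataFrame      # predictor x component (z-score units)
    standard_errors: pd.DataFrame   # same shape
    n: int
    standardized: bool
    scale: pd.Series                # per-predictor divisor applied (1 if none)

    def coef_row(self, factor: str) -> np.ndarray:
        if factor not in self.coefficients.index:
            raise KeyError(f"unknown predictor {factor!r}; available: "
                           f"{list(self.coefficients.index)}")
        return self.coefficients.loc[factor].to_numpy()


def build_design(covariates: pd.DataFrame,
                 predictors: Sequence[str] = DEFAULT_PREDICTORS,
                 labels: Optional[pd.DataFrame] = None) -> pd.DataFrame:
    """Subject-indexed design matrix for the mode regression.

    Continuous risk measures are taken at baseline; ``delta_bsa`` is the
    follow-up minus baseline body-surface-area change; binary factors are
    follow-up presence indicators (1 if the longitudinal label is positive);
    race dummies use white as the reference category.
    """
    base = covariates[covariates["exam"] == "baseline"].set_index("subject_id")
    fu = covariates[covariates["exam"] == "followup"].set_index("subject_id")
    subjects = base.index.intersection(fu.index).sort_values()
    base, fu = base.loc[subjects], fu.loc[subjects]
    if labels is None:
        labels = derive_risk_labels(covariates)
    labels = labels.loc[subjects]

    cols = {}
    for p in predictors:
        if p == "age_baseline":
            cols[p] = base["age"].astype(float)
        elif p == "delta_bsa":
            cols[p] = (fu["bsa"] - base["bsa"]).astype(float)
        elif p in ("sbp", "dbp", "bmi", "hdl", "ldl"):
            cols[p] = base[p].astype(float)
        elif p.startswith("race_"):
            cols[p] = (base["race_ethnicity"] == p[5:]).astype(float)
        elif p == "sex_male":
            cols[p] = (base["sex"] == "male").astype(float)
        elif p in ("smoking", "diabetes", "statins", "htn_medication",
                   "obesity", "hypertension", "high_cholesterol"):
            cols[p] = (labels[p] == "positive").astype(float)
        else:
            raise KeyError(f"unknown predictor {p!r}")
    return pd.DataFrame(cols, index=subjects)


def fit_mode_regression(scores: pd.DataFrame, covariates: pd.DataFrame,
                        predictors: Sequence[str] = DEFAULT_PREDICTORS,
                        standardize: bool = True,
                        labels: Optional[pd.DataFrame] = None,
                        ) -> ModeRegressionFit:
    """OLS of each atlas score component on the common design.

    Continuous predictors are standardized by default so coefficients are
    per-SD effects. Raises on a rank-deficient design, naming the collinear
    columns.
    """
    design = build_design(covariates, predictors, labels=labels)
    common = design.index.intersection(scores.index).sort_values()
    design = design.loc[common]
    y = scores.loc[common].to_numpy(float)
    n, m = y.shape
    if n <= len(predictors) + 1:
        raise ValueError(f"n={n} too small for {len(predictors)} predictors")

    scale = pd.Series(1.0, index=design.columns)
    if standardize:
        for p in design.columns:
            if p in CONTINUOUS_PREDICTORS:
                sd = design[p].std(ddof=0)
                if sd > 0:
                    design[p] = (design[p] - design[p].mean()) / sd
                    scale[p] = sd

    x = np.column_stack([np.ones(n), design.to_numpy(float)])
    names = ["intercept"] + list(design.columns)
    rank = np.linalg.matrix_rank(x)
    if rank < x.shape[1]:
        # name columns involved in the deficiency via QR diagonal
        _, r = np.linalg.qr(x)
        bad = [names[j] for j in range(x.shape[1])
               if abs(r[j, j]) < 1e-8 * abs(r[0, 0])]
        raise ValueError(f"rank-deficient design (rank {rank} < {x.shape[1]}); "
                         f"collinear columns: {bad}")

    xtx_inv = np.linalg.inv(x.T @ x)
    beta = xtx_inv @ x.T @ y                     # (p+1, M)
    resid = y - x @ beta
    dof = n - x.shape[1]
    sigma2 = (resid ** 2).sum(axis=0) / dof      # (M,)
    se = np.sqrt(np.outer(np.diag(xtx_inv), sigma2))

    cols = list(scores.columns)
    return ModeRegressionFit(
        predictors=list(design.columns),
        coefficients=pd.DataFrame(beta, index=names, columns=cols),
        standard_errors=pd.DataFrame(se, index=names, columns=cols),
        n=n, standardized=standardize, scale=scale)


@dataclass
class RemodelingMode:
    factor: str
    delta: float                       # predictor contrast (1 = present/+1 SD)
    displacement: np.ndarray           # (2*P*3,) mm
    measure_deltas: Optional[pd.Series] = None     # % of baseline value
    regional_thickening_delta: Optional[np.ndarray] = None   # (17,) % points
    sem: Optional[pd.Series] = None
    masked: Optional[pd.Series] = None


def reconstruct_mode(fit: ModeRegressionFit, atlas: TrajectoryAtlas,
                     factor: str, delta: float = 1.0,
                     with_measures: bool = True) -> RemodelingMode:
    """Displacement field and measure deltas for one predictor.

    displacement = delta * sum_m beta_{factor,m} * score_sd_m * component_m.
    Measure deltas compare the mean baseline shape displaced by the mean
    trajectory with and without the mode, as percent of the baseline value
    (regional thickening as percentage-point differences).
    """
    beta = fit.coef_row(factor)
    m = len(beta)
    if m > atlas.n_components:
        raise ValueError("fit has more components than the atlas")
    disp = delta * (beta * atlas.score_sd[:m]) @ atlas.components[:m]
    mode = RemodelingMode(factor=factor, delta=delta, displacement=disp)
    if with_measures:
        _attach_measures(mode, atlas)
    return mode


def _measure_series(meas: DerivedMeasures) -> pd.Series:
    return pd.Series({k: getattr(meas, k)
                      for k in DerivedMeasures.SCALAR_FIELDS})


def mode_measure_deltas(atlas: TrajectoryAtlas,
                        displacement: np.ndarray) -> pd.Series:
    """Percent change of each conventional measure caused by a displacement
    field, evaluated on the mean shape at the end of the mean trajectory and
    referenced to the mean baseline value."""
    ref_shape = atlas.shape_from_vector(atlas.mean_trajectory)
    mode_shape = atlas.shape_from_vector(atlas.mean_trajectory + displacement)
    base_shape = atlas.shape_from_vector(atlas.mean_baseline)
    m_ref = _measure_series(derived_measures(ref_shape))
    m_mode = _measure_series(derived_measures(mode_shape))
    m_base = _measure_series(derived_measures(base_shape))
    return 100.0 * (m_mode - m_ref) / m_base.abs()


def regional_mode_map(atlas: TrajectoryAtlas,
                      displacement: np.ndarray) -> np.ndarray:
    """AHA-17 wall-thickening change (percentage points) of a mode.

    Thickening per segment is computed on the mean shape at the end of the
    mean trajectory, with and without the mode displacement; the difference
    per segment is returned.
    """
    ref_shape = atlas.shape_from_vector(atlas.mean_trajectory)
    mode_shape = atlas.shape_from_vector(atlas.mean_trajectory + displacement)

    def thickening(shape: LVShape) -> np.ndarray:
        seg = aha17_segment_map(shape, "ED")[: shape.topology.n_endo]
        wt_ed = per_point_wall_thickness(shape, "ED")
        wt_es = per_point_wall_thickness(shape, "ES")
        out = np.full(17, np.nan)
        for s in range(1, 18):
            mask = seg == s
            if mask.any():
                out[s - 1] = 100.0 * (wt_es[mask].mean() - wt_ed[mask].mean()) \
                    / wt_ed[mask].mean()
        return out

    return thickening(mode_shape) - thickening(ref_shape)


def _attach_measures(mode: RemodelingMode, atlas: TrajectoryAtlas) -> None:
    mode.measure_deltas = mode_measure_deltas(atlas, mode.displacement)
    mode.regional_thickening_delta = regional_mode_map(atlas,
                                                       mode.displacement)


def sem_filter(values, sd, n: int):
    """Mask entries not exceeding the standard error of the mean (sd/sqrt n).

    Returns ``(masked_values, sem, mask)`` where masked entries are NaN and
    ``mask`` is True where a value is suppressed (|value| <= SEM).
    """
    if n <= 1:
        raise ValueError("SEM needs n > 1")
    values = pd.Series(values, dtype=float)
    sd = pd.Series(sd, dtype=float).reindex(values.index)
    sem = sd / np.sqrt(n)
    mask = values.abs() <= sem
    shown = values.where(~mask)
    return shown, sem, mask


def measure_change_sd(measures: pd.DataFrame) -> Tuple[pd.Series, int]:
    """Per-measure SD of the per-subject percent change, for SEM masking.

    ``measures`` is the output of :func:`lvatlas.geometry.measures_table`
    for both exams; subjects missing either exam are dropped.
    """
    piv = {}
    for exam in ("baseline", "followup"):
        piv[exam] = measures[measures["exam"] == exam].set_index("subject_id")
    common = piv["baseline"].index.intersection(piv["followup"].index)
    base = piv["baseline"].loc[common]
    fu = piv["followup"].loc[common]
    fields = list(DerivedMeasures.SCALAR_FIELDS)
    pct = 100.0 * (fu[fields] - base[fields]) / base[fields].abs()
    return pct.std(ddof=1), len(common)
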