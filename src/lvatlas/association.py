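"""Risk-factor labels and Atlas vs Mass-Volume model comparison.

Binary risk-factor labels follow the longitudinal scheme: a subject is
*positive* if the factor is present at follow-up, *negative* if absent at
both exams, and *excluded* otherwise (e.g., a smoker who quit).

The model comparison trains, per risk factor, two penalized (elastic-net)
logistic regressions — one on trajectory-atlas scores, one on mass/volume/EF
changes, both adjusted for sex and baseline age — over ten stratified 80/20
shuffle splits with shared seeds, tuning hyperparameters by randomized search
in an inner stratified 5-fold CV, and scores them by balanced accuracy with
a paired t-test (Bonferroni-corrected) between the two models.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field as dc_field
from typing import Dict, Iterable, List, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import (RandomizedSearchCV, StratifiedKFold,
                                     StratifiedShuffleSplit)
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler

RISK_FACTORS = ("obesity", "high_cholesterol", "hypertension", "smoking",
                "diabetes", "htn_medication", "statins")

#: thresholds of the categorical risk-factor definitions
BMI_OBESE = 30.0
SBP_HIGH = 140.0
DBP_HIGH = 90.0
TC_HIGH = 240.0
LDL_HIGH = 160.0
HDL_LOW = 40.0
TG_HIGH = 150.0


def _factor_present(row: pd.Series, factor: str, chol_rule: str,
                    bp_rule: str) -> bool:
    if factor == "obesity":
        return row["bmi"] > BMI_OBESE
    if factor == "high_cholesterol":
        parts = [row["total_cholesterol"] > TC_HIGH, row["ldl"] > LDL_HIGH,
                 row["hdl"] < HDL_LOW, row["triglycerides"] > TG_HIGH]
        return all(parts) if chol_rule == "all" else any(parts)
    if factor == "hypertension":
        bp = ((row["sbp"] > SBP_HIGH) and (row["dbp"] > DBP_HIGH)
              if bp_rule == "and"
              else (row["sbp"] > SBP_HIGH) or (row["dbp"] > DBP_HIGH))
        return bool(row["htn_diagnosis"]) or bp
    if factor == "smoking":
        return bool(row["smoker"])
    if factor == "diabetes":
        return row["diabetes_status"] != "none"
    if factor == "htn_medication":
        return bool(row["htn_medication"])
    if factor == "statins":
        return bool(row["statins"])
    raise KeyError(f"unknown risk factor {factor!r}")


_REQUIRED = {
    "obesity": ["bmi"],
    "high_cholesterol": ["total_cholesterol", "ldl", "hdl", "triglycerides"],
    "hypertension": ["htn_diagnosis", "sbp", "dbp"],
    "smoking": ["smoker"],
    "diabetes": ["diabetes_status"],
    "htn_medication": ["htn_medication"],
    "statins": ["statins"],
}


def derive_risk_labels(covariates: pd.DataFrame, chol_rule: str = "any",
                       bp_rule: str = "and") -> pd.DataFrame:
    """Longitudinal risk labels from the per-exam covariate table.

    ``chol_rule`` selects whether the four lipid thresholds combine by "any"
    (default; the clinically plausible reading) or "all"; ``bp_rule`` selects
    the SBP/DBP conjunction ("and", default, the printed rule) or "or" for
    the blood-pressure part of the hypertension definition.

    Returns a subject-indexed frame of "positive"/"negative"/"excluded"
    per factor; subjects missing a required field are excluded for that
    factor only.
    """
    if chol_rule not in ("any", "all") or bp_rule not in ("and", "or"):
        raise ValueError("chol_rule must be any/all and bp_rule and/or")
    wide = {e: g.set_index("subject_id")
            for e, g in covariates.groupby("exam")}
    for exam in ("baseline", "followup"):
        if exam not in wide:
            raise ValueError(f"covariate table lacks exam {exam!r}")
    base, fu = wide["baseline"], wide["followup"]
    subjects = sorted(set(base.index) & set(fu.index))

    out = {}
    for factor in RISK_FACTORS:
        col = []
        for sid in subjects:
            rows = (base.loc[sid], fu.loc[sid])
            if any(pd.isna(r.get(c)) for r in rows
                   for c in _REQUIRED[factor]):
                col.append("excluded")
                continue
            at_base, at_fu = (
                _factor_present(r, factor, chol_rule, bp_rule) for r in rows)
            if at_fu:
                col.append("positive")
            elif not at_base:
                col.append("negative")
            else:
                col.append("excluded")   # present at baseline, absent at follow-up
        out[factor] = col
    return pd.DataFrame(out, index=pd.Index(subjects, name="subject_id"))


def balanced_accuracy(labels, predictions) -> float:
    """Mean of per-class recalls (1 = perfect, 0.5 = chance on two classes)."""
    y = np.asarray(labels)
    p = np.asarray(predictions)
    if y.shape != p.shape:
        raise ValueError("labels and predictions must have the same shape")
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("balanced accuracy needs both classes in the labels")
    recalls = [np.mean(p[y == c] == c) for c in classes]
    return float(np.mean(recalls))


@dataclass
class CVSettings:
    n_splits: int = 10
    test_size: float = 0.2
    n_iter: int = 50                      # randomized-search draws
    inner_folds: int = 5
    l1_ratios: Sequence[float] = tuple(np.round(np.arange(0, 1.01, 0.1), 1))
    log_c_range: Sequence[float] = (1e-2, 1e4)   # C = 1/lambda
    max_iter: int = 2000
    tol: float = 1e-3
    min_labeled: int = 40
    min_class: int = 10


@dataclass
class CVResult:
    folds: pd.DataFrame      # factor, model, fold, balanced_accuracy, params
    summary: pd.DataFrame    # factor, per-model mean/sd, p_raw, p_bonferroni
    skipped: Dict[str, str]


def _search_estimator(settings: CVSettings, seed: int):
    base = Pipeline([
        ("scale", StandardScaler()),
        ("clf", LogisticRegression(solver="saga", l1_ratio=0.5,
                                   max_iter=settings.max_iter,
                                   tol=settings.tol, random_state=seed)),
    ])
    lo, hi = settings.log_c_range
    params = {"clf__l1_ratio": list(settings.l1_ratios),
              "clf__C": stats.loguniform(lo, hi)}
    inner = StratifiedKFold(settings.inner_folds, shuffle=True,
                            random_state=seed)
    return RandomizedSearchCV(base, params, n_iter=settings.n_iter, cv=inner,
                              scoring="balanced_accuracy", random_state=seed,
                              n_jobs=1, refit=True)


def _model_features(scores: pd.DataFrame, mv: pd.DataFrame,
                    adjusters: pd.DataFrame, response: str):
    adj = adjusters.copy()
    if response == "sex":
        adj = adj.drop(columns=["sex_male"])
    atlas_x = scores.join(adj, how="inner")
    mv_x = mv.join(adj, how="inner")
    return {"Atlas": atlas_x, "Mass-Volume": mv_x}


def cv_compare(atlas_scores: pd.DataFrame, mv_features: pd.DataFrame,
               labels: pd.DataFrame, covariates: pd.DataFrame,
               seed: int = 0, settings: Optional[CVSettings] = None,
               responses: Optional[Sequence[str]] = None,
               include_sex_response: bool = True) -> CVResult:
    """Compare Atlas and Mass-Volume logistic models per risk factor.

    ``atlas_scores``: subject-indexed trajectory z-scores (already truncated
    to the variance fraction the caller wants). ``mv_features``:
    subject-indexed Delta-EDV/ESV/mass/EF. ``labels``: output of
    :func:`derive_risk_labels`. ``covariates``: per-exam table supplying sex
    and baseline age adjusters. Fold seeds are shared between the two models
    so balanced accuracies are paired per split.
    """
    settings = settings or CVSettings()
    base_cov = covariates[covariates["exam"] == "baseline"] \
        .set_index("subject_id")
    adjusters = pd.DataFrame({
        "age_baseline": base_cov["age"].astype(float),
        "sex_male": (base_cov["sex"] == "male").astype(float),
    })

    if responses is None:
        responses = [f for f in RISK_FACTORS if f in labels.columns]
        if include_sex_response:
            responses = responses + ["sex"]
    n_responses = len(responses)

    root = np.random.SeedSequence(seed)
    fold_rows: List[dict] = []
    summary_rows: List[dict] = []
    skipped: Dict[str, str] = {}

    for r_idx, response in enumerate(responses):
        # one deterministic seed stream per response, shared by both models
        states = np.random.SeedSequence((seed, r_idx)).generate_state(
            settings.n_splits + 1)
        split_seed = int(states[0] % (2 ** 31))
        if response == "sex":
            y = adjusters["sex_male"]
        else:
            lab = labels[response]
            y = lab[lab != "excluded"].map({"positive": 1.0, "negative": 0.0})
        feats = _model_features(atlas_scores, mv_features, adjusters, response)
        common = feats["Atlas"].index.intersection(
            feats["Mass-Volume"].index).intersection(y.index)
        y = y.loc[common]
        counts = y.value_counts()
        if len(y) < settings.min_labeled or counts.min() < settings.min_class \
                or len(counts) < 2:
            skipped[response] = (f"insufficient labeled subjects "
                                 f"(n={len(y)}, class counts={counts.to_dict()})")
            continue

        sss = StratifiedShuffleSplit(n_splits=settings.n_splits,
                                     test_size=settings.test_size,
                                     random_state=split_seed)
        accs: Dict[str, List[float]] = {m: [] for m in feats}
        yv = y.to_numpy()
        for fold, (tr, te) in enumerate(sss.split(np.zeros(len(y)), yv)):
            fold_seed = int(states[fold + 1] % (2 ** 31))
            for model_name, x in feats.items():
                xv = x.loc[common].to_numpy(float)
                search = _search_estimator(settings, fold_seed)
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore", ConvergenceWarning)
                    search.fit(xv[tr], yv[tr])
                pred = search.predict(xv[te])
                acc = balanced_accuracy(yv[te], pred)
                accs[model_name].append(acc)
                fold_rows.append({
                    "factor": response, "model": model_name, "fold": fold,
                    "balanced_accuracy": acc,
                    "l1_ratio": search.best_params_["clf__l1_ratio"],
                    "C": search.best_params_["clf__C"],
                })
        a = np.array(accs["Atlas"])
        m = np.array(accs["Mass-Volume"])
        diffs = a - m
        if np.ptp(diffs) == 0:
            # degenerate paired test: constant fold-wise difference
            p_raw = 1.0 if diffs[0] == 0 else 0.0
        else:
            p_raw = float(stats.ttest_rel(a, m).pvalue)
        summary_rows.append({
            "factor": response,
            "atlas_mean": a.mean(), "atlas_sd": a.std(ddof=1),
            "mv_mean": m.mean(), "mv_sd": m.std(ddof=1),
            "difference": a.mean() - m.mean(),
            "p_raw": p_raw,
            "p_bonferroni": min(1.0, p_raw * n_responses),
        })

    return CVResult(folds=pd.DataFrame(fold_rows),
                    summary=pd.DataFrame(summary_rows), skipped=skipped)
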