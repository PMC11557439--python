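"""CRASH-style 14-day mortality models augmented with imaging features.

The CRASH prognostic model family predicts 14-day in-hospital mortality
after TBI.  Four nested feature sets are supported:

* ``CRASH_BASIC`` — Box-Cox-transformed age, GCS, pupil reactivity
  (two dummies, both-reactive as reference), major extracranial injury;
* ``CRASH_CT`` — adds the CT findings petechiae, effaced basal
  cisterns, subarachnoid bleeding, midline shift, non-evacuated
  hematoma;
* ``CRASH_CT_VOL`` — adds automatically measured hematoma volume (mL);
* ``CRASH_CT_VOL_SUB`` — adds the five subtype indicators.

Models are refit on the cohort at hand (logistic regression by maximum
likelihood, or a random forest) under stratified 5-fold
cross-validation, with two outcome schemes: A = death, B = death or
coma.  Diagnostics include the Box-Tidwell linearity test and a
profile-likelihood Box-Cox transform for age.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import (
    accuracy_score,
    f1_score,
    precision_score,
    recall_score,
    roc_auc_score,
)
from sklearn.model_selection import StratifiedKFold

from .image_io import SUBTYPE_NAMES

FEATURE_SETS = ("CRASH_BASIC", "CRASH_CT", "CRASH_CT_VOL", "CRASH_CT_VOL_SUB")

_BASIC_COLS = [
    "age_bc",
    "gcs",
    "pupils_one_reactive",
    "pupils_both_nonreactive",
    "major_extracranial_injury",
]
_CT_COLS = [
    "petechiae",
    "effaced_basal_cistern",
    "sah_present",
    "midline_shift",
    "nonevacuated_hematoma",
]

_REQUIRED = [
    "age_years",
    "gcs",
    "pupils",
    "major_extracranial_injury",
    "petechiae",
    "effaced_basal_cistern",
    "midline_shift",
    "sah_present",
    "evacuated_hematoma",
]

_SCHEME_OUTCOME = {"A": "death14", "B": "death_or_coma14"}


class ConvergenceError(RuntimeError):
    """A maximum-likelihood fit failed to converge."""


def feature_columns(name: str) -> List[str]:
    """Fixed, documented column order of each nested feature set."""
    if name not in FEATURE_SETS:
        raise ValueError(f"unknown feature set {name!r}; choose from {FEATURE_SETS}")
    cols = list(_BASIC_COLS)
    if name != "CRASH_BASIC":
        cols += _CT_COLS
    if name in ("CRASH_CT_VOL", "CRASH_CT_VOL_SUB"):
        cols.append("volume_ml")
    if name == "CRASH_CT_VOL_SUB":
        cols += list(SUBTYPE_NAMES)
    return cols


def box_cox(x: np.ndarray, lam: Optional[float] = None) -> Tuple[np.ndarray, float]:
    """Box-Cox power transform with profile-ML lambda on a fixed grid.

    lambda is chosen by maximizing the normal profile log-likelihood
    over the grid [-3, 3] in steps of 0.01; pass ``lam`` to force a
    value.  The transform is (x^lam - 1)/lam, or ln x at lam = 0.
    """
    x = np.asarray(x, dtype=np.float64)
    if x.size == 0 or (x <= 0).any():
        raise ValueError("Box-Cox requires strictly positive inputs")

    def transform(l: float) -> np.ndarray:
        if abs(l) < 1e-12:
            return np.log(x)
        return (x**l - 1.0) / l

    if lam is not None:
        return transform(lam), float(lam)

    logx_sum = float(np.log(x).sum())
    n = x.size
    grid = np.arange(-3.0, 3.0 + 1e-9, 0.01)
    best_ll, best_lam = -np.inf, 1.0
    for l in grid:
        y = transform(l)
        var = y.var()
        if var <= 0:
            continue
        ll = -0.5 * n * np.log(var) + (l - 1.0) * logx_sum
        if ll > best_ll:
            best_ll, best_lam = ll, float(l)
    return transform(best_lam), best_lam


def build_features(
    records: pd.DataFrame,
    spec: str,
    scheme: Optional[str] = None,
    boxcox_lambda: Optional[float] = None,
) -> Tuple[pd.DataFrame, Optional[pd.Series], float]:
    """Design matrix (fixed column order) + outcome vector for a scheme.

    Pupil reactivity is dummy-coded against a both-reactive reference
    and "non-evacuated hematoma" is the negation of the evacuated flag.
    Returns ``(X, y, lambda)`` where ``y`` is None when no scheme is
    requested and ``lambda`` is the Box-Cox exponent used for age.
    """
    if len(records) == 0:
        raise ValueError("no records")
    cols = feature_columns(spec)
    needed = list(_REQUIRED)
    if spec in ("CRASH_CT_VOL", "CRASH_CT_VOL_SUB"):
        needed.append("volume_ml")
    if spec == "CRASH_CT_VOL_SUB":
        needed += list(SUBTYPE_NAMES)
    missing = [c for c in needed if c not in records.columns]
    if missing:
        raise ValueError(f"records are missing required columns: {missing}")

    age_bc, lam = box_cox(records["age_years"].to_numpy(), lam=boxcox_lambda)
    pupils = records["pupils"].astype(str)
    full = pd.DataFrame(
        {
            "age_bc": age_bc,
            "gcs": records["gcs"].astype(float).to_numpy(),
            "pupils_one_reactive": (pupils == "one_reactive").astype(float).to_numpy(),
            "pupils_both_nonreactive": (pupils == "both_nonreactive")
            .astype(float)
            .to_numpy(),
            "major_extracranial_injury": records["major_extracranial_injury"]
            .astype(float)
            .to_numpy(),
            "petechiae": records["petechiae"].astype(float).to_numpy(),
            "effaced_basal_cistern": records["effaced_basal_cistern"]
            .astype(float)
            .to_numpy(),
            "sah_present": records["sah_present"].astype(float).to_numpy(),
            "midline_shift": records["midline_shift"].astype(float).to_numpy(),
            "nonevacuated_hematoma": 1.0
            - records["evacuated_hematoma"].astype(float).to_numpy(),
        },
        index=records.index,
    )
    if "volume_ml" in needed:
        full["volume_ml"] = records["volume_ml"].astype(float).to_numpy()
    for s in SUBTYPE_NAMES:
        if s in needed:
            full[s] = records[s].astype(float).to_numpy()

    y = None
    if scheme is not None:
        if scheme not in _SCHEME_OUTCOME:
            raise ValueError("scheme must be 'A' or 'B'")
        outcome_col = _SCHEME_OUTCOME[scheme]
        if outcome_col not in records.columns:
            raise ValueError(f"records lack outcome column {outcome_col!r}")
        y = records[outcome_col].astype(int)
    return full[cols], y, lam


def box_tidwell(
    x: np.ndarray,
    covariates: Optional[np.ndarray],
    y: np.ndarray,
) -> float:
    """Wald p-value for the x*ln(x) term in an augmented logistic model.

    A small p rejects linearity of ``x`` in the logit.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if (x <= 0).any():
        raise ValueError("Box-Tidwell requires strictly positive x")
    if np.ptp(x) == 0:
        raise ValueError("x is constant; the x*ln(x) term is collinear")
    design = [x, x * np.log(x)]
    if covariates is not None:
        cov = np.asarray(covariates, dtype=np.float64)
        if cov.ndim == 1:
            cov = cov[:, None]
        design.append(cov)
    X = sm.add_constant(np.column_stack(design))
    try:
        fit = sm.Logit(y, X).fit(disp=0, maxiter=200)
    except Exception as exc:  # separation / singular Hessian
        raise ConvergenceError(f"Box-Tidwell logistic fit failed: {exc}") from exc
    if not fit.mle_retvals.get("converged", True):
        raise ConvergenceError(
            f"Box-Tidwell fit did not converge: {fit.mle_retvals}"
        )
    return float(fit.pvalues[2])  # const, x, x*ln(x), covariates...


@dataclass
class CVResult:
    """Per-fold and mean cross-validation metrics for one model."""

    spec: str
    algorithm: str
    scheme: str
    fold_metrics: List[Dict[str, float]]
    fold_test_indices: List[np.ndarray]
    fold_probabilities: List[np.ndarray]
    models: list
    importances: Optional[np.ndarray] = None  # RF only, normalized, mean over folds
    feature_names: List[str] = field(default_factory=list)

    def mean(self, key: str) -> float:
        vals = [m[key] for m in self.fold_metrics if not np.isnan(m[key])]
        return float(np.mean(vals))

    def summary(self) -> Dict[str, float]:
        return {k: self.mean(k) for k in ("accuracy", "precision", "recall", "f1", "auc")}


def _fold_metrics(y_true, probs, threshold=0.5) -> Dict[str, float]:
    preds = (probs >= threshold).astype(int)
    auc = (
        roc_auc_score(y_true, probs)
        if len(np.unique(y_true)) > 1
        else float("nan")
    )
    return {
        "accuracy": accuracy_score(y_true, preds),
        "precision": precision_score(y_true, preds, zero_division=0),
        "recall": recall_score(y_true, preds, zero_division=0),
        "f1": f1_score(y_true, preds, zero_division=0),
        "auc": float(auc),
    }


def fit_predict_cv(
    records: pd.DataFrame,
    spec: str,
    algorithm: str = "logistic",
    scheme: str = "A",
    k: int = 5,
    seed: int = 0,
    rf_trees: int = 500,
    threshold: float = 0.5,
) -> CVResult:
    """Stratified k-fold CV of one feature set / algorithm / scheme."""
    if algorithm not in ("logistic", "random_forest"):
        raise ValueError("algorithm must be 'logistic' or 'random_forest'")
    if len(records) < 4 * k:
        raise ValueError(f"need at least {4 * k} records for {k}-fold CV")
    X, y, _ = build_features(records, spec, scheme=scheme)
    yv = y.to_numpy()
    if len(np.unique(yv)) < 2:
        raise ValueError("both outcome classes must be present")

    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    fold_metrics, models, test_idx, fold_probs, fold_imps = [], [], [], [], []
    for train, test in skf.split(X, yv):
        if len(np.unique(yv[train])) < 2 or len(np.unique(yv[test])) < 2:
            continue  # skipped single-class fold
        Xtr, Xte = X.iloc[train].to_numpy(), X.iloc[test].to_numpy()
        if algorithm == "logistic":
            # unpenalized maximum likelihood
            clf = LogisticRegression(C=np.inf, solver="lbfgs", max_iter=2000)
        else:
            clf = RandomForestClassifier(
                n_estimators=rf_trees, max_features="sqrt", random_state=seed
            )
        clf.fit(Xtr, yv[train])
        probs = clf.predict_proba(Xte)[:, 1]
        fold_metrics.append(_fold_metrics(yv[test], probs, threshold))
        models.append(clf)
        test_idx.append(test)
        fold_probs.append(probs)
        if algorithm == "random_forest":
            fold_imps.append(clf.feature_importances_)
    if not fold_metrics:
        raise ValueError("all folds were single-class; cannot cross-validate")

    importances = None
    if fold_imps:
        imp = np.mean(fold_imps, axis=0)
        importances = imp / imp.sum()
    return CVResult(
        spec=spec,
        algorithm=algorithm,
        scheme=scheme,
        fold_metrics=fold_metrics,
        fold_test_indices=test_idx,
        fold_probabilities=fold_probs,
        models=models,
        importances=importances,
        feature_names=list(X.columns),
    )


def recover_coefficients(
    records: pd.DataFrame,
    spec: str,
    scheme: str = "A",
    boxcox_lambda: Optional[float] = None,
) -> pd.DataFrame:
    """Full-data ML logistic fit: estimates with 95% Wald intervals.

    Serves as the estimation oracle against cohorts generated with a
    known logistic truth.
    """
    X, y, _ = build_features(records, spec, scheme=scheme, boxcox_lambda=boxcox_lambda)
    Xc = sm.add_constant(X.to_numpy())
    try:
        fit = sm.Logit(y.to_numpy(), Xc).fit(disp=0, maxiter=500)
    except Exception as exc:
        raise ConvergenceError(f"logistic fit failed: {exc}") from exc
    if not fit.mle_retvals.get("converged", True):
        raise ConvergenceError(f"logistic fit did not converge: {fit.mle_retvals}")
    names = ["intercept"] + list(X.columns)
    ci = fit.conf_int(alpha=0.05)
    return pd.DataFrame(
        {
            "coef": fit.params,
            "se": fit.bse,
            "ci_low": ci[:, 0],
            "ci_high": ci[:, 1],
        },
        index=names,
    )


def feature_importance(cv: CVResult) -> List[Tuple[str, float]]:
    """Random-forest mean-decrease-in-impurity shares, descending."""
    if cv.algorithm != "random_forest" or cv.importances is None:
        raise ValueError("feature_importance requires random-forest CV results")
    order = np.argsort(cv.importances)[::-1]
    return [(cv.feature_names[i], float(cv.importances[i])) for i in order]
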