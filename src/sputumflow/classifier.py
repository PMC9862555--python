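"""Logistic cancer/non-cancer classifier, training harness and cutoff choice.

The model is an unpenalized logistic regression on four unnormalized
predictors plus one interaction:

    logit P(cancer) = b0 + b1*age + b2*tcpp_r3 + b3*fvs_r2
                      + b4*cd206low_linmid + b5*(age * fvs_r2)

``LungFlowClassifier`` is a scikit-learn-style estimator (fit /
predict_proba / predict, ``get_params``/``set_params``, fitted attributes
with a trailing underscore) wrapping a maximum-likelihood fit with Wald
statistics; the module-level functions are thin wrappers over it.

The decision rule is deliberately asymmetric at the boundary: a sample is
called cancer only when its probability exceeds the cutoff; equality is
called non-cancer.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.special import expit
from scipy.stats import norm as _norm
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.metrics import auc as _trapezoid_auc
from sklearn.metrics import roc_curve as _sk_roc_curve

__all__ = [
    "PREDICTORS",
    "ModelCoefficients",
    "Prediction",
    "LungFlowClassifier",
    "IneligibleSampleError",
    "predict_probability",
    "classify",
    "fit_logistic",
    "stepwise_select",
    "choose_cutoff",
]

#: main-effect predictor columns, in model order
PREDICTORS = ["age", "tcpp_r3_per10k", "fvs_r2_per10k", "cd206low_linmid_per10k"]
INTERACTION = ("age", "fvs_r2_per10k")
COEF_NAMES = ["b0", "b1", "b2", "b3", "b4", "b5"]


class IneligibleSampleError(RuntimeError):
    """QC refusal: a sample that failed eligibility cannot be scored."""


@dataclass
class ModelCoefficients:
    """Fitted coefficients b0..b5 with Wald statistics."""

    values: Dict[str, float]
    std_errors: Dict[str, float] = field(default_factory=dict)
    wald_p: Dict[str, float] = field(default_factory=dict)
    penalized_fallback: bool = False

    def __post_init__(self) -> None:
        missing = [n for n in COEF_NAMES if n not in self.values]
        if missing:
            raise ValueError(f"missing coefficients: {missing}")
        if not all(np.isfinite(v) for v in self.values.values()):
            raise ValueError("coefficients must be finite")

    def linear_predictor(self, age, tcpp_r3, fvs_r2, cd206low_linmid):
        b = self.values
        return (b["b0"] + b["b1"] * age + b["b2"] * tcpp_r3 + b["b3"] * fvs_r2
                + b["b4"] * cd206low_linmid + b["b5"] * age * fvs_r2)

    def to_json(self, path=None, **metadata) -> str:
        doc = {
            "schema": "sputumflow.model/1",
            "coefficients": self.values,
            "std_errors": self.std_errors,
            "wald_p": self.wald_p,
            "penalized_fallback": self.penalized_fallback,
            "metadata": metadata,
        }
        text = json.dumps(doc, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, path) -> "ModelCoefficients":
        with open(path) as fh:
            doc = json.load(fh)
        return cls(values=doc["coefficients"], std_errors=doc.get("std_errors", {}),
                   wald_p=doc.get("wald_p", {}),
                   penalized_fallback=doc.get("penalized_fallback", False))


@dataclass
class Prediction:
    probability: float
    cutoff: float

    @property
    def call(self) -> str:
        return "cancer" if self.probability > self.cutoff else "non-cancer"


def _design(X: pd.DataFrame) -> np.ndarray:
    cols = [np.ones(len(X))]
    for c in PREDICTORS:
        cols.append(np.asarray(X[c], dtype=float))
    cols.append(np.asarray(X[INTERACTION[0]], dtype=float)
                * np.asarray(X[INTERACTION[1]], dtype=float))
    return np.column_stack(cols)


class LungFlowClassifier(BaseEstimator, ClassifierMixin):
    """Unpenalized logistic cancer/non-cancer model with a probability cutoff.

    Parameters
    ----------
    cutoff : float, default 0.28
        Predicted-probability threshold; a sample is called cancer only
        when its probability strictly exceeds it.
    """

    def __init__(self, cutoff: float = 0.28):
        self.cutoff = cutoff

    # -- sklearn API ------------------------------------------------------
    def fit(self, X, y) -> "LungFlowClassifier":
        X = self._as_frame(X)
        y = np.asarray(y, dtype=float)
        if X.shape[0] != y.shape[0]:
            raise ValueError("X and y length mismatch")
        keep = np.isfinite(y)  # status-unknown samples are excluded from the fit
        X, y = X.loc[keep], y[keep]
        if len(np.unique(y)) != 2:
            raise ValueError("need both classes present")
        if min((y == 0).sum(), (y == 1).sum()) < 2:
            raise ValueError("need at least 2 samples per class")
        design = _design(X)
        spans = design[:, 1:].max(axis=0) - design[:, 1:].min(axis=0)
        if np.any(spans == 0):
            raise ValueError("constant predictor in design matrix")
        self.model_ = _ml_logit(design, y)
        self.coef_ = np.array([self.model_.values[n] for n in COEF_NAMES])
        self.classes_ = np.array([0, 1])
        self.n_features_in_ = len(PREDICTORS)
        return self

    def predict_proba(self, X) -> np.ndarray:
        self._check_fitted()
        X = self._as_frame(X)
        lp = self.model_.linear_predictor(
            X["age"].to_numpy(float), X["tcpp_r3_per10k"].to_numpy(float),
            X["fvs_r2_per10k"].to_numpy(float),
            X["cd206low_linmid_per10k"].to_numpy(float))
        p1 = expit(lp)
        return np.column_stack([1.0 - p1, p1])

    def predict(self, X) -> np.ndarray:
        p = self.predict_proba(X)[:, 1]
        return (p > self.cutoff).astype(int)

    # -- helpers ----------------------------------------------------------
    def _check_fitted(self) -> None:
        if not hasattr(self, "model_"):
            raise RuntimeError("classifier is not fitted")

    @staticmethod
    def _as_frame(X) -> pd.DataFrame:
        if isinstance(X, pd.DataFrame):
            missing = [c for c in PREDICTORS if c not in X.columns]
            if missing:
                raise ValueError(f"missing predictor columns: {missing}")
            return X
        arr = np.asarray(X, dtype=float)
        if arr.ndim != 2 or arr.shape[1] != len(PREDICTORS):
            raise ValueError(f"expected columns {PREDICTORS}")
        return pd.DataFrame(arr, columns=PREDICTORS)


def _ml_logit(design: np.ndarray, y: np.ndarray) -> ModelCoefficients:
    """Maximum-likelihood logistic fit; penalized fallback on separation.

    The predictors are deliberately unnormalized (coefficients stay
    interpretable on raw units), so the design is standardized internally
    for the optimizer only and the estimates and their covariance mapped
    back exactly -- the ML solution is identical either way.
    """
    mu = design.mean(axis=0)
    sd = design.std(axis=0)
    mu[0], sd[0] = 0.0, 1.0  # intercept column untouched
    z = (design - mu) / sd
    # raw = A @ standardized: b_j = b'_j / sd_j, b0 absorbs the centering
    a_mat = np.diag(1.0 / sd)
    a_mat[0, :] = -mu / sd
    a_mat[0, 0] = 1.0

    fallback = False
    with warnings.catch_warnings():
        warnings.simplefilter("error", category=sm.tools.sm_exceptions.PerfectSeparationWarning)
        try:
            res = sm.Logit(y, z).fit(disp=0, maxiter=200)
            if not res.mle_retvals.get("converged", False) or \
                    not np.all(np.isfinite(res.bse)):
                raise sm.tools.sm_exceptions.PerfectSeparationError("no Wald stats")
            params = a_mat @ res.params
            cov = a_mat @ res.cov_params() @ a_mat.T
            bse = np.sqrt(np.diag(cov))
            pvals = 2.0 * _norm.sf(np.abs(params / bse))
        except (sm.tools.sm_exceptions.PerfectSeparationError,
                sm.tools.sm_exceptions.PerfectSeparationWarning,
                np.linalg.LinAlgError):
            fallback = True
    if fallback:
        warnings.warn("perfect separation detected; returning penalized fit "
                      "(no Wald statistics)")
        res = sm.Logit(y, z).fit_regularized(alpha=1.0, L1_wt=0.0, disp=0)
        params = a_mat @ np.asarray(res.params)
        bse = np.full_like(params, np.nan)
        pvals = np.full_like(params, np.nan)
    return ModelCoefficients(
        values={n: float(v) for n, v in zip(COEF_NAMES, params)},
        std_errors={n: float(v) for n, v in zip(COEF_NAMES, bse)},
        wald_p={n: float(v) for n, v in zip(COEF_NAMES, pvals)},
        penalized_fallback=fallback,
    )


# ---------------------------------------------------------------------------
# thin functional wrappers

def predict_probability(m: ModelCoefficients, features, eligible: bool = True) -> float:
    """Score one sample; refuses QC-ineligible samples."""
    if hasattr(features, "tcpp_r3"):  # FeatureVector
        args = (features.age, features.tcpp_r3, features.fvs_r2,
                features.cd206low_linmid)
    else:
        args = tuple(float(features[k]) for k in
                     ("age", "tcpp_r3_per10k", "fvs_r2_per10k", "cd206low_linmid_per10k"))
    if not eligible:
        raise IneligibleSampleError(
            "sample failed QC eligibility; no probability is reported"
        )
    return float(expit(m.linear_predictor(*args)))


def classify(p: float, cutoff: float) -> str:
    """Cancer iff p > cutoff; the boundary value is called non-cancer."""
    if not (0.0 <= p <= 1.0 and 0.0 <= cutoff <= 1.0):
        raise ValueError("probability and cutoff must be in [0, 1]")
    return "cancer" if p > cutoff else "non-cancer"


def fit_logistic(features: pd.DataFrame, labels) -> ModelCoefficients:
    """Fit the five-term model on a cohort table; returns coefficients."""
    clf = LungFlowClassifier().fit(features, labels)
    return clf.model_


# ---------------------------------------------------------------------------
# stepwise predictor selection over repeated training splits

def _wald_fit(design: np.ndarray, y: np.ndarray):
    # slope Wald p-values are invariant to column scaling, so the design is
    # standardized (excluding the intercept) for numerical stability only
    z = design.copy()
    sd = z[:, 1:].std(axis=0)
    sd[sd == 0] = 1.0
    z[:, 1:] = (z[:, 1:] - z[:, 1:].mean(axis=0)) / sd
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.Logit(y, z).fit(disp=0, maxiter=100)
    except Exception:
        return None
    if not np.all(np.isfinite(res.bse)):
        return None
    return res


def _stepwise_once(X: pd.DataFrame, y: np.ndarray, candidates: List[str],
                   enter_p: float, remove_p: float) -> List[str]:
    """Forward/backward stepwise by Wald p-value on one training split.

    Interaction candidates (``"a:b"``) obey the hierarchy principle: they
    may enter only while both parents are in the model.
    """
    def col(name: str) -> np.ndarray:
        if ":" in name:
            a, b = name.split(":")
            return X[a].to_numpy(float) * X[b].to_numpy(float)
        return X[name].to_numpy(float)

    selected: List[str] = []
    while True:
        changed = False
        # forward step: best eligible candidate below the entry p
        best_name, best_p = None, enter_p
        for name in candidates:
            if name in selected:
                continue
            if ":" in name and not all(p in selected for p in name.split(":")):
                continue
            design = np.column_stack(
                [np.ones(len(X))] + [col(s) for s in selected] + [col(name)])
            res = _wald_fit(design, y)
            if res is None:
                continue
            p = res.pvalues[-1]
            if p < best_p:
                best_name, best_p = name, p
        if best_name is not None:
            selected.append(best_name)
            changed = True
        # backward step: drop the worst term at/above the removal p
        while selected:
            design = np.column_stack([np.ones(len(X))] + [col(s) for s in selected])
            res = _wald_fit(design, y)
            if res is None:
                break
            pvals = res.pvalues[1:]
            # a parent of an in-model interaction is not removable
            locked = set()
            for name in selected:
                if ":" in name:
                    locked.update(name.split(":"))
            removable = [i for i, s in enumerate(selected) if s not in locked]
            if not removable:
                break
            worst = max(removable, key=lambda i: pvals[i])
            if pvals[worst] >= remove_p:
                selected.pop(worst)
                changed = True
            else:
                break
        if not changed:
            return selected


def stepwise_select(candidates: pd.DataFrame, labels, n_splits: int = 200,
                    split_size: int = 100, cancer_per_split: int = 20,
                    seed: int = 0, enter_p: float = 0.05,
                    remove_p: float = 0.05, freq_threshold: float = 0.5
                    ) -> Tuple[pd.Series, List[str]]:
    """Stepwise selection frequencies over repeated stratified training splits.

    Each split holds ``split_size`` samples including ``cancer_per_split``
    cancers (the 20% training ratio); forward/backward stepwise runs per
    split and per-variable selection frequencies are reported together
    with the predictors retained above ``freq_threshold``.
    """
    y = np.asarray(labels, dtype=float)
    X = candidates.reset_index(drop=True)
    cancer_idx = np.flatnonzero(y == 1)
    control_idx = np.flatnonzero(y == 0)
    n_controls = split_size - cancer_per_split
    if len(cancer_idx) < cancer_per_split or len(control_idx) < n_controls:
        raise ValueError(
            f"infeasible split: need {cancer_per_split} cancers and "
            f"{n_controls} non-cancers, have {len(cancer_idx)}/{len(control_idx)}"
        )
    names = list(X.columns)
    rng = np.random.default_rng(seed)
    freq = pd.Series(0.0, index=names)
    for _ in range(n_splits):
        rows = np.concatenate([
            rng.choice(cancer_idx, size=cancer_per_split, replace=False),
            rng.choice(control_idx, size=n_controls, replace=False),
        ])
        chosen = _stepwise_once(X.iloc[rows].reset_index(drop=True), y[rows],
                                names, enter_p, remove_p)
        for name in chosen:
            freq[name] += 1.0
    freq /= n_splits
    final = [n for n in names if freq[n] >= freq_threshold]
    return freq, final


# ---------------------------------------------------------------------------
# ablation harness: impact of dropping each predictor group

ABLATION_GROUPS = {
    "none": [],
    "age": ["age", "age:fvs_r2_per10k"],
    "tcpp_r3": ["tcpp_r3_per10k"],
    "cd206low_linmid": ["cd206low_linmid_per10k"],
    "fvs_r2": ["fvs_r2_per10k", "age:fvs_r2_per10k"],
    "interaction": ["age:fvs_r2_per10k"],
}


def ablation_misclassifications(train_X: pd.DataFrame, train_y,
                                test_X: pd.DataFrame, test_y) -> Dict[str, int]:
    """Misclassification counts when each predictor group is dropped.

    For the full model and for each reduced model (a predictor dropped
    together with any interaction it parents), fit on the training cohort,
    choose a Youden cutoff there, and count test-set errors.
    """
    train_y = np.asarray(train_y, dtype=int)
    test_y = np.asarray(test_y, dtype=int)
    all_terms = PREDICTORS + ["age:fvs_r2_per10k"]

    def design(X: pd.DataFrame, terms: List[str]) -> np.ndarray:
        cols = [np.ones(len(X))]
        for t in terms:
            if ":" in t:
                a, b = t.split(":")
                cols.append(X[a].to_numpy(float) * X[b].to_numpy(float))
            else:
                cols.append(X[t].to_numpy(float))
        return np.column_stack(cols)

    out: Dict[str, int] = {}
    for group, dropped in ABLATION_GROUPS.items():
        terms = [t for t in all_terms if t not in dropped]
        d_tr, d_te = design(train_X, terms), design(test_X, terms)
        mu = d_tr.mean(axis=0)
        sd = d_tr.std(axis=0)
        mu[0], sd[0] = 0.0, 1.0
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.Logit(train_y, (d_tr - mu) / sd).fit(disp=0, maxiter=200)
        p_tr = expit((d_tr - mu) / sd @ res.params)
        cutoff, _, _ = choose_cutoff(p_tr, train_y)
        p_te = expit((d_te - mu) / sd @ res.params)
        out[group] = int(((p_te > cutoff).astype(int) != test_y).sum())
    return out


# ---------------------------------------------------------------------------
# ROC-based cutoff

def choose_cutoff(probabilities, labels) -> Tuple[float, pd.DataFrame, float]:
    """Step through cutoffs; pick the Youden-J maximizer.

    Candidate cutoffs are midpoints between consecutive distinct
    probabilities (plus end points), honouring the strict "cancer iff
    p > cutoff" rule.  Returns (cutoff, ROC grid, trapezoid AUC).
    """
    p = np.asarray(probabilities, dtype=float)
    y = np.asarray(labels, dtype=int)
    if len(np.unique(y)) != 2:
        raise ValueError("both classes must be present")
    uniq = np.unique(p)
    mids = (uniq[:-1] + uniq[1:]) / 2.0 if uniq.size > 1 else np.array([])
    grid = np.concatenate(([uniq[0] - 1e-12], mids, [uniq[-1]]))
    pos, neg = (y == 1), (y == 0)
    sens = np.array([(p[pos] > c).mean() for c in grid])
    spec = np.array([(p[neg] <= c).mean() for c in grid])
    j = sens + spec - 1.0
    best = int(np.argmax(j))
    roc = pd.DataFrame({"cutoff": grid, "sensitivity": sens,
                        "specificity": spec, "youden_j": j})
    fpr, tpr, _ = _sk_roc_curve(y, p)
    auc_value = float(_trapezoid_auc(fpr, tpr))
    return float(np.clip(grid[best], 0.0, 1.0)), roc, auc_value
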