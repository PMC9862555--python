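"""Diagnostic-accuracy statistics for the cancer/non-cancer classifier.

Confusion-matrix rates with Wilson score intervals, prevalence-adjusted
predictive values with logit-transformed confidence intervals (Mercaldo),
the positive diagnostic likelihood ratio (PDLR = sensitivity / (1 -
specificity)), the ATS minimal-accuracy PDLR bound, trapezoid AUC with a
stratified bootstrap CI, and the training-split combinatorics used to size
the repeated-randomization harness.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.stats import norm
from sklearn.metrics import roc_auc_score
from statsmodels.stats.proportion import proportion_confint

__all__ = [
    "ConfusionCounts",
    "rates",
    "wilson_ci",
    "predictive_values",
    "predictive_value_cis",
    "pdlr",
    "ats_min_pdlr",
    "auc_bootstrap_ci",
    "training_split_count",
    "diagnostic_report",
    "report_to_frame",
]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fn: int
    tn: int
    fp: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fn, self.tn, self.fp) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def n_positive(self) -> int:
        return self.tp + self.fn

    @property
    def n_negative(self) -> int:
        return self.tn + self.fp

    @property
    def total(self) -> int:
        return self.n_positive + self.n_negative

    @classmethod
    def from_calls(cls, labels, calls) -> "ConfusionCounts":
        y = np.asarray(labels, dtype=int)
        c = np.asarray(calls, dtype=int)
        return cls(tp=int(((y == 1) & (c == 1)).sum()),
                   fn=int(((y == 1) & (c == 0)).sum()),
                   tn=int(((y == 0) & (c == 0)).sum()),
                   fp=int(((y == 0) & (c == 1)).sum()))


def rates(c: ConfusionCounts) -> Dict[str, float]:
    """Sensitivity, specificity, accuracy, PPV and NPV from raw counts."""
    for margin, name in ((c.n_positive, "sensitivity"), (c.n_negative, "specificity"),
                         (c.tp + c.fp, "ppv"), (c.tn + c.fn, "npv")):
        if margin == 0:
            raise ZeroDivisionError(f"{name} undefined: zero margin")
    return {
        "sensitivity": c.tp / c.n_positive,
        "specificity": c.tn / c.n_negative,
        "accuracy": (c.tp + c.tn) / c.total,
        "ppv": c.tp / (c.tp + c.fp),
        "npv": c.tn / (c.tn + c.fn),
    }


def wilson_ci(k: int, n: int, confidence: float = 0.95) -> Tuple[float, float]:
    """Wilson score interval for a binomial proportion."""
    if not (0 <= k <= n) or n <= 0:
        raise ValueError("require 0 <= k <= n and n > 0")
    lo, hi = proportion_confint(k, n, alpha=1 - confidence, method="wilson")
    return float(lo), float(hi)


def predictive_values(sensitivity: float, specificity: float,
                      prevalence: float) -> Tuple[float, float]:
    """PPV and NPV at an external prevalence (Bayes' rule)."""
    for name, v in (("sensitivity", sensitivity), ("specificity", specificity),
                    ("prevalence", prevalence)):
        if not 0.0 < v < 1.0:
            if name == "prevalence" or not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in (0, 1); got {v}")
    ppv = sensitivity * prevalence / (
        sensitivity * prevalence + (1 - specificity) * (1 - prevalence))
    npv = specificity * (1 - prevalence) / (
        specificity * (1 - prevalence) + (1 - sensitivity) * prevalence)
    return ppv, npv


def predictive_value_cis(c: ConfusionCounts, prevalence: float,
                         confidence: float = 0.95
                         ) -> Dict[str, Tuple[float, float, float]]:
    """Prevalence-adjusted PPV/NPV with logit-transformed CIs (Mercaldo).

    A 0.5 continuity correction is applied to any zero cell before the
    variance computation.
    """
    tp, fn, tn, fp = c.tp, c.fn, c.tn, c.fp
    if 0 in (tp, fn, tn, fp):
        tp, fn, tn, fp = (v + 0.5 for v in (tp, fn, tn, fp))
    n1, n0 = tp + fn, tn + fp
    se, sp = tp / n1, tn / n0
    ppv, npv = predictive_values(se, sp, prevalence)
    z = norm.ppf(0.5 + confidence / 2.0)

    logit_ppv = math.log(prevalence / (1 - prevalence)) + math.log(se / (1 - sp))
    var_ppv = (1 - se) / (se * n1) + sp / ((1 - sp) * n0)
    lo_p = _expit(logit_ppv - z * math.sqrt(var_ppv))
    hi_p = _expit(logit_ppv + z * math.sqrt(var_ppv))

    logit_npv = math.log((1 - prevalence) / prevalence) + math.log(sp / (1 - se))
    var_npv = se / ((1 - se) * n1) + (1 - sp) / (sp * n0)
    lo_n = _expit(logit_npv - z * math.sqrt(var_npv))
    hi_n = _expit(logit_npv + z * math.sqrt(var_npv))
    return {"ppv": (ppv, lo_p, hi_p), "npv": (npv, lo_n, hi_n)}


def _expit(x: float) -> float:
    return 1.0 / (1.0 + math.exp(-x))


def pdlr(sensitivity: float, specificity: float) -> float:
    """Positive diagnostic likelihood ratio sensitivity / (1 - specificity).

    A perfectly specific test has an infinite PDLR; that case is flagged
    with a warning and returns ``inf``.
    """
    if specificity >= 1.0:
        warnings.warn("specificity = 1: PDLR is infinite")
        return math.inf
    return sensitivity / (1.0 - specificity)


def ats_min_pdlr(prevalence: float, harm_threshold: float) -> float:
    """Minimal clinically useful PDLR: ((1-prev)/prev) * (R/(1-R)).

    ``harm_threshold`` (R) is the post-test probability above which an
    invasive follow-up is considered worthwhile.
    """
    for name, v in (("prevalence", prevalence), ("harm_threshold", harm_threshold)):
        if not 0.0 < v < 1.0:
            raise ValueError(f"{name} must be in (0, 1); got {v}")
    return ((1.0 - prevalence) / prevalence) * (harm_threshold / (1.0 - harm_threshold))


def auc_bootstrap_ci(probabilities, labels, n_boot: int = 2000, seed: int = 0,
                     confidence: float = 0.95) -> Tuple[float, float, float]:
    """Trapezoid AUC with a class-stratified percentile bootstrap CI."""
    p = np.asarray(probabilities, dtype=float)
    y = np.asarray(labels, dtype=int)
    if len(np.unique(y)) != 2:
        raise ValueError("both classes must be present")
    if n_boot < 100:
        raise ValueError("n_boot must be at least 100")
    point = float(roc_auc_score(y, p))
    rng = np.random.default_rng(seed)
    pos, neg = np.flatnonzero(y == 1), np.flatnonzero(y == 0)
    stats = np.empty(n_boot)
    for b in range(n_boot):
        rows = np.concatenate([rng.choice(pos, size=pos.size, replace=True),
                               rng.choice(neg, size=neg.size, replace=True)])
        stats[b] = roc_auc_score(y[rows], p[rows])
    alpha = (1 - confidence) / 2.0
    lo, hi = np.quantile(stats, [alpha, 1 - alpha])
    return point, float(lo), float(hi)


def training_split_count(n_cancer_total: int, n_cancer_per_split: int) -> int:
    """Exact binomial coefficient C(n, k): distinct cancer strata of splits."""
    if n_cancer_per_split > n_cancer_total:
        raise ValueError("k must not exceed n")
    return math.comb(n_cancer_total, n_cancer_per_split)


# ---------------------------------------------------------------------------
# report assembly

def diagnostic_report(labels, probabilities, cutoff: float,
                      external_prevalences: Sequence[float] = (0.0083, 0.029),
                      n_boot: int = 2000, seed: int = 0) -> dict:
    """Full diagnostic-accuracy report for a labelled, scored cohort.

    Rows mirror the standard performance-table layout: sensitivity,
    specificity and accuracy with Wilson CIs, bootstrap AUC, PPV/NPV at
    dataset prevalence and at the supplied external prevalences, and the
    PDLR.  Rates are reported at full precision; round for display.
    """
    p = np.asarray(probabilities, dtype=float)
    y = np.asarray(labels, dtype=int)
    calls = (p > cutoff).astype(int)
    c = ConfusionCounts.from_calls(y, calls)
    r = rates(c)
    auc, auc_lo, auc_hi = auc_bootstrap_ci(p, y, n_boot=n_boot, seed=seed)
    dataset_prev = c.n_positive / c.total
    report = {
        "schema": "sputumflow.diagnostics/1",
        "counts": {"tp": c.tp, "fn": c.fn, "tn": c.tn, "fp": c.fp},
        "cutoff": cutoff,
        "prevalence_dataset": dataset_prev,
        "sensitivity": {"value": r["sensitivity"],
                        "ci": wilson_ci(c.tp, c.n_positive)},
        "specificity": {"value": r["specificity"],
                        "ci": wilson_ci(c.tn, c.n_negative)},
        "accuracy": {"value": r["accuracy"],
                     "ci": wilson_ci(c.tp + c.tn, c.total)},
        "auc": {"value": auc, "ci": (auc_lo, auc_hi)},
        "pdlr": pdlr(r["sensitivity"], r["specificity"])
        if r["specificity"] < 1.0 else math.inf,
        "predictive_values": {},
    }
    for prev, label in [(dataset_prev, "dataset")] + [
            (pv, f"prevalence_{pv:g}") for pv in external_prevalences]:
        cis = predictive_value_cis(c, prev)
        report["predictive_values"][label] = {
            "prevalence": prev,
            "ppv": cis["ppv"], "npv": cis["npv"],
        }
    return report


def report_to_frame(report: dict) -> pd.DataFrame:
    """Performance-table-shaped frame (one metric per row, value + CI)."""
    rows = []
    for key in ("sensitivity", "specificity", "accuracy", "auc"):
        entry = report[key]
        rows.append({"metric": key, "value": entry["value"],
                     "ci_lo": entry["ci"][0], "ci_hi": entry["ci"][1]})
    for label, pv in report["predictive_values"].items():
        for which in ("ppv", "npv"):
            val, lo, hi = pv[which]
            rows.append({"metric": f"{which}_{label}", "value": val,
                         "ci_lo": lo, "ci_hi": hi})
    rows.append({"metric": "pdlr", "value": report["pdlr"],
                 "ci_lo": np.nan, "ci_hi": np.nan})
    return pd.DataFrame(rows)
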