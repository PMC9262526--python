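"""Diagnostic-threshold calibration and model-vs-clinician agreement.

Per syndrome element, the standardized CAT score is evaluated against the
clinician gold-standard label with an ROC curve; the cut-point maximizing the
Youden index (sensitivity + specificity - 1) becomes the diagnostic
threshold, with a positive call defined as score >= threshold. Agreement of
the dichotomized model diagnosis with the clinician is quantified with
Cohen's kappa (banded at 0.75 / 0.40) and McNemar's paired test (continuity-
corrected chi-square for >= 25 discordant pairs, exact binomial otherwise).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ROCCurve",
    "BinaryAgreement",
    "AgreementStats",
    "roc_curve",
    "youden_threshold",
    "dichotomize_diagnosis",
    "cohens_kappa",
    "mcnemar_test",
    "agreement_table",
    "diagnostic_table",
]

KAPPA_EXCELLENT = 0.75
KAPPA_FAIR = 0.40
MCNEMAR_EXACT_LIMIT = 25  # discordant pairs below this use the exact binomial


@dataclass
class ROCCurve:
    element: str | None
    thresholds: np.ndarray  # ascending candidate cut-points (+inf sentinel last)
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float
    youden_max: float
    youden_threshold: float


@dataclass(frozen=True)
class BinaryAgreement:
    """2x2 table of model (rows) vs clinician (columns) binary diagnoses:
    a = both positive, b = model+/clin-, c = model-/clin+, d = both negative."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self):
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("cell counts must be non-negative")
        if self.a + self.b + self.c + self.d == 0:
            raise ValueError("empty agreement table")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d


@dataclass
class AgreementStats:
    kappa: float
    kappa_band: str
    mcnemar_statistic: float
    mcnemar_p: float
    mcnemar_method: str


def roc_curve(scores, labels, element: str | None = None) -> ROCCurve:
    """ROC over all unique score cut-points (plus an all-negative sentinel).

    A positive call is score >= threshold. The AUC is the trapezoidal area,
    which equals the Mann-Whitney probability P(score+ > score-) + 0.5 P(tie).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise ValueError("scores and labels must be aligned 1-D arrays")
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both classes must be present")
    thresholds = np.concatenate([np.unique(scores), [np.inf]])
    sens = np.array([(pos >= t).mean() for t in thresholds])
    spec = np.array([(neg < t).mean() for t in thresholds])
    fpr, tpr = 1.0 - spec, sens
    order = np.lexsort((tpr, fpr))
    auc = float(np.trapezoid(tpr[order], fpr[order]))
    j = sens + spec - 1.0
    finite = np.isfinite(thresholds)
    best = int(np.argmax(j[finite]))  # thresholds ascending: first max = lowest cut
    return ROCCurve(
        element=element,
        thresholds=thresholds,
        sensitivity=sens,
        specificity=spec,
        auc=auc,
        youden_max=float(j[finite][best]),
        youden_threshold=float(thresholds[finite][best]),
    )


def youden_threshold(roc: ROCCurve) -> float:
    """Diagnostic threshold: the cut-point at the Youden-index maximum (ties
    resolved toward the lower, more sensitive cut)."""
    return roc.youden_threshold


def dichotomize_diagnosis(standardized_score, threshold: float):
    """Model diagnosis is positive iff standardized score >= threshold."""
    x = np.asarray(standardized_score, dtype=float)
    out = (x >= threshold).astype(int)
    return int(out) if out.ndim == 0 else out


def agreement_table(model_dx, clinician_dx) -> BinaryAgreement:
    m = np.asarray(model_dx, dtype=int)
    c = np.asarray(clinician_dx, dtype=int)
    if m.shape != c.shape:
        raise ValueError("diagnosis vectors must align")
    return BinaryAgreement(
        a=int(np.sum((m == 1) & (c == 1))),
        b=int(np.sum((m == 1) & (c == 0))),
        c=int(np.sum((m == 0) & (c == 1))),
        d=int(np.sum((m == 0) & (c == 0))),
    )


def _kappa_band(kappa: float) -> str:
    if np.isnan(kappa):
        return "undefined"
    # tiny tolerance so a kappa that is exactly a band boundary up to float
    # roundoff (e.g. 0.4 computed as 0.3999...9) lands in the inclusive band
    if kappa >= KAPPA_EXCELLENT - 1e-12:
        return "excellent"
    if kappa >= KAPPA_FAIR - 1e-12:
        return "fair_to_good"
    return "poor"


def cohens_kappa(table: BinaryAgreement) -> tuple[float, str]:
    """Chance-corrected agreement kappa = (p_o - p_e) / (1 - p_e).

    Degenerate marginals (expected agreement 1) make kappa undefined; NaN is
    returned with band "undefined".
    """
    n = table.total
    p_o = (table.a + table.d) / n
    p_e = (
        (table.a + table.b) * (table.a + table.c)
        + (table.c + table.d) * (table.b + table.d)
    ) / (n * n)
    if p_e >= 1.0 - 1e-15:
        return float("nan"), "undefined"
    kappa = (p_o - p_e) / (1.0 - p_e)
    return float(kappa), _kappa_band(kappa)


def mcnemar_test(table: BinaryAgreement) -> tuple[float, float, str]:
    """Paired test on the discordant cells (b, c).

    Returns (statistic, p, method). With >= 25 discordant pairs, the
    continuity-corrected chi-square (|b - c| - 1)^2 / (b + c) on 1 df;
    otherwise the exact two-sided binomial test of b out of b + c at 1/2.
    """
    b, c = table.b, table.c
    m = b + c
    if m == 0:
        return 0.0, 1.0, "exact_binomial"
    if m >= MCNEMAR_EXACT_LIMIT:
        stat = (abs(b - c) - 1.0) ** 2 / m
        return float(stat), float(stats.chi2.sf(stat, df=1)), "chi2_corrected"
    p = min(1.0, 2.0 * stats.binom.sf(max(b, c) - 1, m, 0.5))
    return float(max(b, c)), float(p), "exact_binomial"


def evaluate_agreement(table: BinaryAgreement) -> AgreementStats:
    kappa, band = cohens_kappa(table)
    stat, p, method = mcnemar_test(table)
    return AgreementStats(kappa, band, stat, p, method)


def diagnostic_table(
    standardized_scores: pd.DataFrame, clinician_dx: pd.DataFrame
) -> pd.DataFrame:
    """Per-element calibration + agreement summary.

    ``standardized_scores`` and ``clinician_dx`` are aligned frames with one
    column per element. Returns one row per element: AUC, Youden threshold
    and maximum, kappa with band, and McNemar statistic/p/method.
    """
    rows = []
    for element in standardized_scores.columns:
        scores = standardized_scores[element].to_numpy()
        labels = clinician_dx[element].to_numpy()
        roc = roc_curve(scores, labels, element=element)
        model = dichotomize_diagnosis(scores, roc.youden_threshold)
        ag = evaluate_agreement(agreement_table(model, labels))
        rows.append(
            {
                "element": element,
                "auc": roc.auc,
                "youden_threshold": roc.youden_threshold,
                "youden_max": roc.youden_max,
                "kappa": ag.kappa,
                "kappa_band": ag.kappa_band,
                "mcnemar_statistic": ag.mcnemar_statistic,
                "mcnemar_p": ag.mcnemar_p,
                "mcnemar_method": ag.mcnemar_method,
            }
        )
    return pd.DataFrame(rows)
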