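"""Responder classification and logistic linkage of syndrome-score changes.

A patient is a responder on a QoL domain when their oriented change d
(follow-up minus baseline, higher = better) meets or exceeds the domain
MCID. Per domain, a logistic regression of the binary outcome on the six
per-element standardized score changes (oriented so positive = improvement,
i.e. baseline minus follow-up) is fitted by unpenalized maximum likelihood
(IRLS), reporting the SPSS-style columns B, S.E., Wald, df, P and Exp(B).
Quasi-separation (|B| > 15) is flagged, not penalized. No multiplicity
correction is applied within the 9x6 grid; a Benjamini-Hochberg adjustment
is available as supplementary output.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit

from ._util import ELEMENTS
from .mcid_estimation import ALL_DOMAINS
from .synthetic_cohort import PatientRecord

__all__ = [
    "LogisticFit",
    "classify_outcomes",
    "fit_logistic",
    "linkage_report",
    "format_linkage_table",
    "bh_adjust",
    "element_change_frame",
]

SEPARATION_B = 15.0


@dataclass
class LogisticFit:
    domain: str
    table: pd.DataFrame  # index: predictors + "Constant"; columns B..ExpB
    n: int
    converged: bool
    n_iter: int
    separation: bool


def classify_outcomes(
    records: Sequence[PatientRecord], mcid: Mapping[str, float] | pd.DataFrame
) -> pd.DataFrame:
    """One outcome label per non-dropped patient per domain (8 + total).

    ``changed`` is 1 iff d >= MCID(domain), with the boundary inclusive.
    """
    if isinstance(mcid, pd.DataFrame):
        mcid = dict(zip(mcid["domain"], mcid["weighted"]))
    missing = [d for d in ALL_DOMAINS if d not in mcid]
    if missing:
        raise KeyError(f"missing MCID for domains: {missing}")
    rows = []
    for r in records:
        if r.dropped:
            continue
        diffs = r.qol_followup - r.qol_baseline
        for j, domain in enumerate(ALL_DOMAINS):
            d = float(diffs[j])
            rows.append(
                {
                    "patient_id": r.patient_id,
                    "domain": domain,
                    "d": d,
                    "changed": int(d >= mcid[domain]),
                }
            )
    return pd.DataFrame(rows)


def _check_design(X: np.ndarray, names: Sequence[str]) -> None:
    Xc = np.column_stack([X, np.ones(len(X))])
    rank = np.linalg.matrix_rank(Xc)
    if rank < Xc.shape[1]:
        # identify aliased columns: those whose removal does not drop the rank
        aliased = [
            names[j]
            for j in range(X.shape[1])
            if np.linalg.matrix_rank(np.delete(Xc, j, axis=1)) == rank
        ]
        raise ValueError(f"rank-deficient design; aliased columns: {aliased}")


def fit_logistic(
    element_changes,
    outcomes,
    feature_names: Sequence[str] | None = None,
    domain: str = "",
    max_iter: int = 100,
    tol: float = 1e-8,
) -> LogisticFit:
    """Maximum-likelihood logistic regression with intercept via IRLS.

    Converges when the score (gradient) max-norm falls below ``tol``. SEs are
    from the inverse observed information; Wald = (B/SE)^2 on 1 df with the
    upper chi-square tail P, and Exp(B) = exp(B).
    """
    if isinstance(element_changes, pd.DataFrame):
        feature_names = feature_names or list(element_changes.columns)
        X = element_changes.to_numpy(dtype=float)
    else:
        X = np.asarray(element_changes, dtype=float)
        feature_names = list(feature_names or [f"x{j + 1}" for j in range(X.shape[1])])
    y = np.asarray(outcomes, dtype=float)
    if X.ndim != 2 or len(X) != len(y):
        raise ValueError("design matrix and outcomes must align")
    if len(y) <= 20:
        raise ValueError("need n > 20 observations")
    if y.min() == y.max():
        raise ValueError("outcome has a single class")
    _check_design(X, feature_names)

    Xc = np.column_stack([X, np.ones(len(X))])
    beta = np.zeros(Xc.shape[1])
    converged = False
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        eta = Xc @ beta
        p = expit(eta)
        score = Xc.T @ (y - p)
        if np.max(np.abs(score)) < tol:
            converged = True
            break
        w = np.maximum(p * (1.0 - p), 1e-10)
        H = (Xc * w[:, None]).T @ Xc
        beta = beta + np.linalg.solve(H, score)

    p = expit(Xc @ beta)
    w = np.maximum(p * (1.0 - p), 1e-10)
    H = (Xc * w[:, None]).T @ Xc
    cov = np.linalg.inv(H)
    se = np.sqrt(np.diag(cov))
    wald = (beta / se) ** 2
    pvals = stats.chi2.sf(wald, df=1)
    names = list(feature_names) + ["Constant"]
    table = pd.DataFrame(
        {
            "B": beta,
            "S.E.": se,
            "Wald": wald,
            "df": 1,
            "P": pvals,
            "Exp(B)": np.exp(beta),
        },
        index=names,
    )
    return LogisticFit(
        domain=domain,
        table=table,
        n=len(y),
        converged=converged,
        n_iter=n_iter,
        separation=bool(np.any(np.abs(beta[:-1]) > SEPARATION_B)),
    )


def element_change_frame(
    std_baseline: pd.DataFrame, std_followup: pd.DataFrame
) -> pd.DataFrame:
    """Per-patient standardized element change, oriented so positive =
    improvement (scores decrease with treatment, hence baseline - follow-up)."""
    common = std_baseline.index.intersection(std_followup.index)
    return (std_baseline.loc[common] - std_followup.loc[common])[list(ELEMENTS)]


def _null_fit(domain: str, names: Sequence[str], n: int) -> LogisticFit:
    table = pd.DataFrame(
        {c: np.nan for c in ("B", "S.E.", "Wald", "df", "P", "Exp(B)")},
        index=list(names) + ["Constant"],
    )
    return LogisticFit(domain=domain, table=table, n=n, converged=False, n_iter=0, separation=False)


def linkage_report(
    element_changes: pd.DataFrame,
    outcomes: pd.DataFrame,
    predictor_coding: str = "continuous",
    binary_cutoffs: Mapping[str, float] | None = None,
    on_unfittable: str = "raise",
) -> dict[str, LogisticFit]:
    """One logistic fit per QoL domain plus the total score (9 tables).

    ``element_changes`` is indexed by patient_id with one column per element;
    ``outcomes`` is the long frame from :func:`classify_outcomes`. With
    ``predictor_coding="binary"`` each element change is dichotomized at the
    supplied per-element cutoff (default 0: any improvement). A domain whose
    outcome has a single class cannot be fitted; with
    ``on_unfittable="null"`` it yields an all-NaN table instead of aborting.
    """
    if predictor_coding not in ("continuous", "binary"):
        raise ValueError(f"unknown predictor_coding {predictor_coding!r}")
    if on_unfittable not in ("raise", "null"):
        raise ValueError(f"unknown on_unfittable {on_unfittable!r}")
    X = element_changes[list(ELEMENTS)]
    if predictor_coding == "binary":
        cuts = binary_cutoffs or {}
        X = pd.DataFrame(
            {e: (X[e] >= cuts.get(e, 0.0)).astype(float) for e in ELEMENTS},
            index=X.index,
        )
    fits: dict[str, LogisticFit] = {}
    for domain in ALL_DOMAINS:
        sub = outcomes[outcomes["domain"] == domain].set_index("patient_id")
        y = sub.loc[X.index, "changed"]
        try:
            fits[domain] = fit_logistic(X, y.to_numpy(), domain=domain)
        except ValueError:
            if on_unfittable == "raise":
                raise
            fits[domain] = _null_fit(domain, list(ELEMENTS), len(y))
    return fits


def _fmt_p(p: float) -> str:
    return "<0.001" if p < 0.0005 else f"{p:.3f}"


def format_linkage_table(fit: LogisticFit) -> pd.DataFrame:
    """Report view with the published column layout, 3-decimal rounding and
    the "<0.001" convention for P."""
    t = fit.table
    return pd.DataFrame(
        {
            "Independent variables": list(t.index),
            "B": [f"{v:.3f}" for v in t["B"]],
            "S.E.": [f"{v:.3f}" for v in t["S.E."]],
            "Wald": [f"{v:.3f}" for v in t["Wald"]],
            "df": t["df"].to_numpy(),
            "P": [_fmt_p(v) for v in t["P"]],
            "Exp(B)": [f"{v:.3f}" for v in t["Exp(B)"]],
        }
    )


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (supplementary output only)."""
    p = np.asarray(pvals, dtype=float)
    n = p.size
    order = np.argsort(p)
    ranked = p[order] * n / np.arange(1, n + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(ranked, 1.0)
    return out
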