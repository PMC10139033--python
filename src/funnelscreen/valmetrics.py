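"""External-validation statistics and acceptance rules for QSAR regressions.

Implements the full battery of regression-validation metrics used to decide
whether a QSAR model is fit for screening: the determination coefficient
(Q²/R²), regression-through-origin slopes and coefficients (k, k′, R0², R′0²),
Lin's concordance correlation coefficient, the external Q²F1/Q²F2/Q²F3
functions, the r²m family, MAE, and a threshold-classification AUC — together
with the Golbraikh–Tropsha and Chirico–Gramatica decision rules built on top
of them.

Symbols follow the QSAR-validation literature: Y observed, Ŷ predicted,
Ȳ_TR the training-set mean, EXT the external test set.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._stats import mann_whitney_auc
from .datatypes import PredictionSet

__all__ = [
    "ValidationReport",
    "DecisionOutcome",
    "regression_metrics",
    "gtr_decision",
    "cg_decision",
    "classification_auc",
]


@dataclass
class ValidationReport:
    """Every regression-validation statistic for one prediction set.

    ``r2`` is the determination coefficient of the set itself: for a
    cross-validated set it plays the role of Q², for an external set the role
    of R²_external.  ``rm2_flag`` marks that R² − R0² (or the primed variant)
    was numerically negative and the absolute value was used under the root.
    """

    r2: float
    mae: float
    k_slope: float
    k_prime: float
    r2_0: float
    r2_0_prime: float
    ccc: float
    qf1: float | None
    qf2: float
    qf3: float | None
    rm2: float
    rm2_prime: float
    rm2_bar: float
    n: int
    kind: str = "external"
    q2_cv: float | None = None
    auc: float | None = None
    rm2_flag: bool = False
    extras: dict = field(default_factory=dict)

    @property
    def r2_external(self) -> float:
        return self.r2


@dataclass
class DecisionOutcome:
    """Per-criterion values and the overall verdict of a decision rule."""

    rule: str
    criteria: list[tuple[str, float | None, str, bool]]
    overall: bool

    def __bool__(self) -> bool:
        return self.overall

    def failed(self) -> list[str]:
        return [name for name, _, _, ok in self.criteria if not ok]


def regression_metrics(ps: PredictionSet) -> ValidationReport:
    """Compute the full validation-metric battery for one prediction set.

    All statistics are direct sums over the paired (Y, Ŷ) values:

    - ``Q²/R² = 1 − Σ(Y−Ŷ)² / Σ(Y−Ȳ)²``
    - ``k = ΣYŶ/ΣŶ²``, ``k′ = ΣYŶ/ΣY²`` (regression-through-origin slopes)
    - ``R0² = 1 − Σ(Y−kŶ)²/Σ(Y−Ȳ)²``;
      ``R′0² = 1 − Σ(Ŷ−k′Y)²/Σ(Ŷ−Ŷ̄)²``
    - ``CCC = 2Σ(Y−Ȳ)(Ŷ−Ŷ̄) / [Σ(Y−Ȳ)² + Σ(Ŷ−Ŷ̄)² + n(Ȳ−Ŷ̄)²]``
    - ``Q²F1 = 1 − Σ(Y−Ŷ)²/Σ(Y−Ȳ_TR)²``; ``Q²F2`` uses the external mean
      (identical to R²); ``Q²F3`` compares per-compound mean squared error
      with the training-set variance.
    - ``r²m = R²(1 − √(R²−R0²))`` and its primed/averaged variants.

    Raises
    ------
    ValueError
        If the observed values have zero variance (the denominators of the
        determination coefficients vanish).
    """
    if ps.n < 3:
        raise ValueError("need at least 3 paired values")
    y = ps.observed
    yhat = ps.predicted
    n = ps.n
    y_mean = y.mean()
    yhat_mean = yhat.mean()
    ss_obs = float(np.sum((y - y_mean) ** 2))
    if ss_obs <= 0.0:
        raise ValueError("observed values have zero variance; metrics undefined")
    ss_pred = float(np.sum((yhat - yhat_mean) ** 2))
    press = float(np.sum((y - yhat) ** 2))

    r2 = 1.0 - press / ss_obs
    mae = float(np.mean(np.abs(y - yhat)))

    sum_cross = float(np.sum(y * yhat))
    sum_yhat2 = float(np.sum(yhat**2))
    sum_y2 = float(np.sum(y**2))
    k = sum_cross / sum_yhat2 if sum_yhat2 > 0 else np.nan
    k_prime = sum_cross / sum_y2

    r2_0 = 1.0 - float(np.sum((y - k * yhat) ** 2)) / ss_obs
    # primed variant uses predicted-side deviations in the denominator
    if ss_pred > 0:
        r2_0_prime = 1.0 - float(np.sum((yhat - k_prime * y) ** 2)) / ss_pred
    else:
        r2_0_prime = np.nan

    ccc = (
        2.0 * float(np.sum((y - y_mean) * (yhat - yhat_mean)))
        / (ss_obs + ss_pred + n * (y_mean - yhat_mean) ** 2)
    )

    qf2 = r2  # identical once the same (external) mean is used
    qf1 = qf3 = None
    if ps.train_mean is not None:
        ss_about_train_mean = float(np.sum((y - ps.train_mean) ** 2))
        if ss_about_train_mean > 0:
            qf1 = 1.0 - press / ss_about_train_mean
    if ps.train_ss is not None and ps.n_train:
        train_var = ps.train_ss / ps.n_train
        if train_var > 0:
            qf3 = 1.0 - (press / n) / train_var

    rm2, flag1 = _rm2(r2, r2_0)
    rm2_prime, flag2 = _rm2(r2, r2_0_prime)
    rm2_bar = (rm2 + rm2_prime) / 2.0

    return ValidationReport(
        r2=r2,
        mae=mae,
        k_slope=k,
        k_prime=k_prime,
        r2_0=r2_0,
        r2_0_prime=r2_0_prime,
        ccc=ccc,
        qf1=qf1,
        qf2=qf2,
        qf3=qf3,
        rm2=rm2,
        rm2_prime=rm2_prime,
        rm2_bar=rm2_bar,
        n=n,
        kind=ps.kind,
        q2_cv=r2 if ps.kind in ("cv", "loo") else None,
        rm2_flag=flag1 or flag2,
    )


def _rm2(r2: float, r2_0: float) -> tuple[float, bool]:
    """r²m = R²(1 − √(R² − R0²)); |·| under the root when numerically
    negative (near-perfect fits), flagged."""
    if not np.isfinite(r2_0):
        return np.nan, True
    diff = r2 - r2_0
    flagged = diff < 0
    return r2 * (1.0 - np.sqrt(abs(diff))), flagged


def gtr_decision(report: ValidationReport, q2_cv: float) -> DecisionOutcome:
    """Golbraikh–Tropsha acceptance rule for an externally validated model.

    Criteria (all must hold):

    1. cross-validated ``Q² > 0.5``
    2. external ``R² > 0.6``
    3. ``(R²−R0²)/R² < 0.1`` or ``(R²−R′0²)/R² < 0.1``
    4. ``0.85 ≤ k ≤ 1.15`` or ``0.85 ≤ k′ ≤ 1.15``
    5. ``|R0² − R′0²| < 0.3``

    A non-positive R² marks the ratio criteria as failed rather than
    dividing by zero.
    """
    r2 = report.r2
    crit: list[tuple[str, float | None, str, bool]] = []
    crit.append(("Q2_cv", q2_cv, "> 0.5", q2_cv > 0.5))
    crit.append(("R2_external", r2, "> 0.6", r2 > 0.6))

    if r2 > 0:
        ratio = (r2 - report.r2_0) / r2
        ratio_p = (r2 - report.r2_0_prime) / r2
        ratio_ok = ratio < 0.1 or ratio_p < 0.1
        crit.append(("min RTO ratio", min(ratio, ratio_p), "< 0.1 (either)", bool(ratio_ok)))
    else:
        crit.append(("min RTO ratio", None, "< 0.1 (either)", False))

    k_ok = 0.85 <= report.k_slope <= 1.15 or 0.85 <= report.k_prime <= 1.15
    crit.append(("k or k'", report.k_slope, "in [0.85, 1.15] (either)", bool(k_ok)))

    gap = abs(report.r2_0 - report.r2_0_prime)
    crit.append(("|R0^2 - R'0^2|", gap, "< 0.3", bool(gap < 0.3)))

    return DecisionOutcome("golbraikh-tropsha", crit, all(ok for *_, ok in crit))


def cg_decision(report: ValidationReport) -> DecisionOutcome:
    """Chirico–Gramatica acceptance rule: CCC ≥ 0.85, each Q²Fn ≥ 0.70 and
    r̄²m ≥ 0.65.  Missing Q²F1/Q²F3 (no training moments supplied) fail the
    rule explicitly rather than being skipped."""
    crit: list[tuple[str, float | None, str, bool]] = [
        ("CCC", report.ccc, ">= 0.85", report.ccc >= 0.85)
    ]
    for name, value in (("QF1^2", report.qf1), ("QF2^2", report.qf2), ("QF3^2", report.qf3)):
        ok = value is not None and value >= 0.70
        crit.append((name, value, ">= 0.70", bool(ok)))
    crit.append(("rm2_bar", report.rm2_bar, ">= 0.65", bool(report.rm2_bar >= 0.65)))
    return DecisionOutcome("chirico-gramatica", crit, all(ok for *_, ok in crit))


def classification_auc(ps: PredictionSet, activity_threshold: float = 6.0) -> float:
    """ROC AUC of the predicted activity as a score for the observed class.

    A compound is active iff its observed pIC50 is ≥ ``activity_threshold``
    (default 6.0, i.e. IC50 ≤ 1 µM).  Ties are handled by midranks.
    """
    labels = ps.observed >= activity_threshold
    return mann_whitney_auc(ps.predicted, labels)
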