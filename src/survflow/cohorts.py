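"""Risk-score (prognostic-index) models and risk-group stratification.

A multivariate Cox fit on the selected features yields a per-subject risk
score eta = beta' (x - xbar); subjects are split into low/high-risk cohorts at
the median score (the same strictly-below vs at-or-above convention used for
single-feature splits), or at an explicit cut, or into q quantile groups. The
stratified dataset feeds straight back into KM estimation and the log-rank
test for validation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cox import CoxModel, cox_fit, predict_linear
from .data import SurvivalDataset
from .errors import DegenerateScoreError, EmptyGroupError, ParseError
from .km import KaplanMeierCurve, km_by_group
from .logrank import LogRankResult, logrank_test

__all__ = [
    "RiskStratification",
    "build_risk_model",
    "stratify_by_risk",
    "evaluate_stratification",
    "LOW_RISK",
    "HIGH_RISK",
]

LOW_RISK = "low_risk"
HIGH_RISK = "high_risk"


@dataclass(frozen=True)
class RiskStratification:
    feature_names: tuple[str, ...]
    model: CoxModel
    scores: np.ndarray
    threshold: float | None  # None in quantile mode
    labels: np.ndarray
    dataset: SurvivalDataset  # copy of the input with risk-group labels set


def stratify_by_risk(
    scores: np.ndarray,
    rule: str = "median",
    cutoff: float | None = None,
    quantiles: int | None = None,
) -> tuple[np.ndarray, float | None]:
    """Label scores low/high risk (or q ordinal groups); returns (labels, threshold).

    rule: 'median' (default), 'explicit' (requires ``cutoff``) or 'quantiles'
    (requires ``quantiles`` >= 2). Median/explicit use the (<, >=) convention.
    """
    s = np.asarray(scores, dtype=float)
    if rule in ("median", "explicit"):
        if np.unique(s).size <= 1:
            raise DegenerateScoreError("all risk scores coincide")
        thr = float(np.median(s)) if rule == "median" else float(cutoff)
        labels = np.where(s < thr, LOW_RISK, HIGH_RISK).astype(object)
        if (s < thr).sum() == 0 or (s >= thr).sum() == 0:
            raise EmptyGroupError(f"threshold {thr} leaves an empty risk group")
        return labels, thr
    if rule == "quantiles":
        q = int(quantiles or 0)
        if q < 2:
            raise ParseError("quantile rule requires quantiles >= 2")
        edges = np.quantile(s, np.linspace(0, 1, q + 1)[1:-1])
        bins = np.searchsorted(edges, s, side="left")
        width = len(str(q - 1))
        labels = np.array([f"risk_Q{b + 1:0{width}d}" for b in bins], dtype=object)
        if len(set(labels)) < 2:
            raise EmptyGroupError("quantile binning produced fewer than 2 risk groups")
        return labels, None
    raise ParseError(f"unknown risk rule {rule!r}")


def build_risk_model(
    dataset: SurvivalDataset,
    features,
    rule: str = "median",
    cutoff: float | None = None,
    quantiles: int | None = None,
    ties_method: str = "efron",
) -> RiskStratification:
    """Fit a multivariate Cox model and stratify the training subjects by score."""
    model = cox_fit(dataset, features=features, ties_method=ties_method)
    X = dataset.select_features(model.feature_names).covariates
    scores = predict_linear(model, X)
    labels, thr = stratify_by_risk(scores, rule=rule, cutoff=cutoff, quantiles=quantiles)
    return RiskStratification(
        feature_names=model.feature_names,
        model=model,
        scores=scores,
        threshold=thr,
        labels=labels,
        dataset=dataset.with_groups(labels),
    )


@dataclass(frozen=True)
class StratificationEvaluation:
    curves: dict[object, KaplanMeierCurve]
    logrank: LogRankResult


def evaluate_stratification(dataset: SurvivalDataset) -> StratificationEvaluation:
    """Per-group KM curves plus the log-rank test on risk-labelled data."""
    return StratificationEvaluation(
        curves=km_by_group(dataset), logrank=logrank_test(dataset)
    )
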