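"""Composed analysis pipelines: the multi-stage workflows built from the
single-purpose stages, as pure functions of their recorded parameters.

``pipeline_km_compare`` is the single-variable prognosis workflow: stratify on
one feature (median split by default), estimate per-group KM curves, test the
difference by log-rank, and fit a Cox model of the group indicator optionally
adjusted for other features.

``pipeline_biomarker_screen`` is the discovery workflow: rank candidate
features by univariate Cox, select the top k, build a multivariate risk-score
model, stratify into risk cohorts, validate by KM + log-rank, and report the
training-set concordance index (labelled optimistic — it is computed on the
data the model was fit to).

Reports are plain nested dicts, serialised deterministically so a rerun with
identical parameters produces byte-identical JSON.
"""

from __future__ import annotations

import json

import numpy as np

from . import __version__ as _version
from .cohorts import build_risk_model, evaluate_stratification
from .cox import cox_fit, hazard_ratio_table, model_to_dict
from .data import StratificationRule, SurvivalDataset, stratify
from .errors import SurvFlowError
from .evaluation import cindex_of_model
from .km import KaplanMeierCurve, km_by_group
from .logrank import logrank_test
from .ranking import rank_survival_features, select_top

__all__ = ["pipeline_km_compare", "pipeline_biomarker_screen", "run_report"]

REPORT_SCHEMA_VERSION = 1


def _curve_record(curve: KaplanMeierCurve) -> dict:
    return {
        "n_total": curve.n_total,
        "n_events_total": curve.n_events_total,
        "median_survival": curve.median_survival,
        "life_table": {
            "time": curve.event_times.tolist(),
            "n_at_risk": curve.n_at_risk.tolist(),
            "n_events": curve.n_events.tolist(),
            "n_censored_in_interval": curve.n_censored_in_interval.tolist(),
            "survival": curve.survival.tolist(),
            "greenwood_se": curve.greenwood_se.tolist(),
            "ci_lower": curve.ci_lower.tolist(),
            "ci_upper": curve.ci_upper.tolist(),
        },
    }


def _logrank_record(res) -> dict:
    return {
        "chi_square": res.chi_square,
        "degrees_of_freedom": res.degrees_of_freedom,
        "p_value": res.p_value,
        "group_labels": [str(g) for g in res.group_labels],
        "observed": res.per_group_observed.tolist(),
        "expected": res.per_group_expected.tolist(),
    }


def _hr_record(model) -> list[dict]:
    return hazard_ratio_table(model).to_dict(orient="records")


def _stage(name: str, fn):
    try:
        return fn()
    except SurvFlowError as exc:
        raise type(exc)(f"[stage {name}] {exc}") from exc


def pipeline_km_compare(
    dataset: SurvivalDataset,
    feature: str,
    rule: StratificationRule | None = None,
    adjust_features=(),
    confidence_level: float = 0.95,
    provenance: dict | None = None,
) -> dict:
    """Median-split (or custom-rule) single-feature prognosis workflow."""
    rule = rule or StratificationRule(feature_name=feature)
    strat = _stage("stratify", lambda: stratify(dataset, rule))
    curves = _stage("km", lambda: km_by_group(strat, confidence_level))
    lr = _stage("logrank", lambda: logrank_test(strat))

    # Cox fit of the group indicator (1 = high group), adjusted when requested
    indicator = (strat.groups == rule.label_high).astype(float)
    aug = SurvivalDataset(
        subject_ids=strat.subject_ids,
        time=strat.time,
        event=strat.event,
        covariates=np.column_stack([indicator, *[strat.feature(f) for f in adjust_features]])
        if adjust_features
        else indicator.reshape(-1, 1),
        feature_names=(f"{feature}_{rule.label_high}", *adjust_features),
        groups=strat.groups,
    )
    model = _stage(
        "cox",
        lambda: cox_fit(aug, confidence_level=confidence_level),
    )
    return {
        "schema_version": REPORT_SCHEMA_VERSION,
        "pipeline_name": "km_compare",
        "stage_outputs": {
            "stratification": {
                "feature": feature,
                "mode": rule.mode,
                "group_sizes": {
                    str(lab): int((strat.groups == lab).sum())
                    for lab in strat.group_labels()
                },
            },
            "km": {str(lab): _curve_record(c) for lab, c in curves.items()},
            "logrank": _logrank_record(lr),
            "cox": {
                "hazard_ratios": _hr_record(model),
                "model": model_to_dict(model),
            },
        },
        "provenance": {
            "tool_version": _version,
            "parameters": {
                "feature": feature,
                "mode": rule.mode,
                "cutoff": rule.cutoff,
                "adjust_features": list(adjust_features),
                "confidence_level": confidence_level,
            },
            **(provenance or {}),
        },
    }


def pipeline_biomarker_screen(
    dataset: SurvivalDataset,
    candidate_features=None,
    top_k: int = 5,
    risk_rule: str = "median",
    cutoff: float | None = None,
    quantiles: int | None = None,
    provenance: dict | None = None,
) -> dict:
    """Rank -> select top-k -> risk model -> cohorts -> KM/log-rank -> C-index."""
    candidates = tuple(candidate_features) if candidate_features else dataset.feature_names
    table = _stage(
        "rank", lambda: rank_survival_features(dataset, features=candidates)
    )
    selected = select_top(table, top_k)
    risk = _stage(
        "risk_model",
        lambda: build_risk_model(
            dataset, selected, rule=risk_rule, cutoff=cutoff, quantiles=quantiles
        ),
    )
    ev = _stage("evaluate", lambda: evaluate_stratification(risk.dataset))
    ci = _stage("cindex", lambda: cindex_of_model(risk.model, dataset))
    return {
        "schema_version": REPORT_SCHEMA_VERSION,
        "pipeline_name": "biomarker_screen",
        "stage_outputs": {
            "ranking": table.to_frame().to_dict(orient="records"),
            "selected_features": list(selected),
            "risk_model": {
                "hazard_ratios": _hr_record(risk.model),
                "threshold": risk.threshold,
                "model": model_to_dict(risk.model),
            },
            "cohorts": {
                "subject_ids": [str(s) for s in dataset.subject_ids],
                "scores": risk.scores.tolist(),
                "labels": [str(l) for l in risk.labels],
            },
            "km": {str(lab): _curve_record(c) for lab, c in ev.curves.items()},
            "logrank": _logrank_record(ev.logrank),
            "c_index": {
                "value": ci.c_index,
                "concordant": ci.concordant,
                "discordant": ci.discordant,
                "tied_score": ci.tied_score,
                "usable_pairs": ci.usable_pairs,
                "kind": "training (optimistic)",
            },
        },
        "provenance": {
            "tool_version": _version,
            "parameters": {
                "candidate_features": list(candidates),
                "top_k": top_k,
                "risk_rule": risk_rule,
                "cutoff": cutoff,
                "quantiles": quantiles,
            },
            **(provenance or {}),
        },
    }


def report_json(report: dict) -> str:
    """Deterministic JSON serialisation (sorted keys, fixed separators)."""
    return json.dumps(report, sort_keys=True, separators=(",", ":"), allow_nan=True)


def run_report(report: dict, path: str, tables: bool = True) -> list[str]:
    """Write the JSON report (and TSV side tables); returns written paths."""
    import pandas as pd

    written = [str(path)]
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(report_json(report))
    if tables:
        stem = str(path).rsplit(".", 1)[0]
        so = report["stage_outputs"]
        if "ranking" in so:
            p = f"{stem}.ranking.tsv"
            pd.DataFrame(so["ranking"]).to_csv(p, sep="\t", index=False)
            written.append(p)
        if "cohorts" in so:
            p = f"{stem}.cohorts.tsv"
            pd.DataFrame(
                {
                    "id": so["cohorts"]["subject_ids"],
                    "score": so["cohorts"]["scores"],
                    "label": so["cohorts"]["labels"],
                }
            ).to_csv(p, sep="\t", index=False)
            written.append(p)
    return written
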