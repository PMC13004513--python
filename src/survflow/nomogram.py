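"""Nomogram construction from a fitted Cox model.

A nomogram turns a linear risk model into a paper-and-pencil device: each
covariate value maps to points on a 0-100 scale, the points sum to a total,
and the total maps through the baseline hazard to survival probabilities at
chosen horizons. The 0-point reference for each feature is the end of its
observed range that minimises beta * x (the low-risk end), and the global
scale is chosen so the single most influential feature spans exactly 100
points. Points are kept continuous (never rounded) so the nomogram prediction
is algebraically identical to the model prediction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cox import CoxModel, baseline_hazard_at
from .errors import DegenerateRangeError, FlatModelError, ParseError, SchemaError

__all__ = ["NomogramSpec", "build_nomogram", "score_patient", "survival_from_total_points"]


@dataclass(frozen=True)
class NomogramSpec:
    feature_names: tuple[str, ...]
    reference_values: np.ndarray  # covariate value assigned 0 points
    observed_min: np.ndarray
    observed_max: np.ndarray
    points_per_unit: np.ndarray  # signed: beta_j * scale
    max_points: np.ndarray  # per-feature span over the observed range
    scale: float  # points per unit of linear predictor
    horizons: tuple[float, ...]
    # eta = total_points / scale + eta_offset reconstructs the centered
    # linear predictor from a total-points reading
    eta_offset: float


def build_nomogram(
    model: CoxModel,
    observed_ranges: dict[str, tuple[float, float]] | None = None,
    horizons=(),
) -> NomogramSpec:
    """Lay out point axes for a fitted model over each feature's observed range.

    ``observed_ranges`` maps feature name -> (min, max); binary covariates
    naturally use (0, 1). When omitted for a feature, the range must be
    supplied — there is no dataset attached to a model — so omission raises.
    """
    names = model.feature_names
    beta = model.coefficients
    if np.all(beta == 0):
        raise FlatModelError("all coefficients are zero; no nomogram scale exists")
    observed_ranges = observed_ranges or {}
    lo = np.empty(len(names))
    hi = np.empty(len(names))
    for j, name in enumerate(names):
        if name not in observed_ranges:
            raise SchemaError(f"no observed range supplied for feature {name!r}")
        a, b = observed_ranges[name]
        if not (np.isfinite(a) and np.isfinite(b) and a < b):
            raise DegenerateRangeError(f"feature {name!r} needs finite min < max")
        lo[j], hi[j] = a, b

    span = np.abs(beta) * (hi - lo)  # linear-predictor span per feature
    scale = 100.0 / span.max()
    # reference = range end minimising beta * x
    ref = np.where(beta >= 0, lo, hi)
    horizons = tuple(float(h) for h in horizons)
    if any(h < 0 for h in horizons):
        raise ParseError("horizons must be >= 0")
    eta_offset = float(beta @ (ref - model.covariate_means))
    return NomogramSpec(
        feature_names=names,
        reference_values=ref,
        observed_min=lo,
        observed_max=hi,
        points_per_unit=beta * scale,
        max_points=span * scale,
        scale=scale,
        horizons=horizons,
        eta_offset=eta_offset,
    )


def observed_ranges_from(dataset, feature_names) -> dict[str, tuple[float, float]]:
    """(min, max) of each named feature as observed in a dataset."""
    out = {}
    for name in feature_names:
        x = dataset.feature(name)
        x = x[np.isfinite(x)]
        out[name] = (float(x.min()), float(x.max()))
    return out


def feature_points(nomogram: NomogramSpec, covariates: np.ndarray) -> np.ndarray:
    """Per-feature points for one or more subjects (rows)."""
    X = np.atleast_2d(np.asarray(covariates, dtype=float))
    if X.shape[1] != len(nomogram.feature_names):
        raise SchemaError(
            f"expected {len(nomogram.feature_names)} covariates, got {X.shape[1]}"
        )
    return (X - nomogram.reference_values) * nomogram.points_per_unit


def survival_from_total_points(
    nomogram: NomogramSpec, model: CoxModel, total_points
) -> np.ndarray:
    """The total-points axis: map totals to survival at each horizon."""
    tp = np.atleast_1d(np.asarray(total_points, dtype=float))
    eta = tp / nomogram.scale + nomogram.eta_offset
    H = baseline_hazard_at(model, np.asarray(nomogram.horizons, dtype=float))
    return np.exp(-np.outer(np.exp(eta), H))


def score_patient(
    nomogram: NomogramSpec, model: CoxModel, covariates: np.ndarray
) -> dict:
    """Read a patient off the nomogram: per-feature points, total, survival.

    Out-of-range covariates extrapolate linearly and are flagged.
    """
    x = np.asarray(covariates, dtype=float).ravel()
    pts = feature_points(nomogram, x)[0]
    out_of_range = bool(
        ((x < nomogram.observed_min) | (x > nomogram.observed_max)).any()
    )
    total = float(pts.sum())
    surv = survival_from_total_points(nomogram, model, total)[0]
    return {
        "per_feature_points": pts,
        "total_points": total,
        "survival": {h: float(s) for h, s in zip(nomogram.horizons, surv)},
        "out_of_range": out_of_range,
    }
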