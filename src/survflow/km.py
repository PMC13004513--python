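"""Kaplan-Meier product-limit estimation with Greenwood variances.

The estimator is Ŝ(t) = prod_{t_i <= t} (1 - d_i / n_i) over the distinct
event times t_i, with the events-before-censoring tie convention: a subject
censored at t_i is still part of the risk set at t_i. Pointwise confidence
intervals use the complementary log-log transform, which respects the [0, 1]
range of a survival probability. Ŝ(t) = 1 before the first event time; when
the largest observed time is censored the curve is left incomplete (never
forced to zero).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .data import SurvivalDataset
from .errors import NoEventsError, ParseError

__all__ = ["KaplanMeierCurve", "km_fit", "km_summary", "km_by_group"]


@dataclass(frozen=True)
class KaplanMeierCurve:
    """Step-function survival estimate with its life table.

    ``n_censored_in_interval`` has one entry per event time: entry i counts
    subjects censored in [t_i, t_{i+1}) (the last interval is unbounded);
    ``n_censored_before_first`` counts censorings strictly before the first
    event time.
    """

    event_times: np.ndarray
    n_at_risk: np.ndarray
    n_events: np.ndarray
    n_censored_in_interval: np.ndarray
    n_censored_before_first: int
    survival: np.ndarray
    greenwood_se: np.ndarray
    ci_lower: np.ndarray
    ci_upper: np.ndarray
    confidence_level: float
    median_survival: float | None
    n_total: int
    n_events_total: int

    @property
    def median_is_reached(self) -> bool:
        return self.median_survival is not None

    def survival_at(self, t: float) -> float:
        """Right-continuous step-function lookup of Ŝ(t); Ŝ = 1 before the
        first event time."""
        if t < 0:
            raise ParseError("negative time")
        idx = np.searchsorted(self.event_times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


def km_fit(
    times: np.ndarray,
    events: np.ndarray,
    confidence_level: float = 0.95,
) -> KaplanMeierCurve:
    """Fit the product-limit estimator to right-censored data.

    Parameters
    ----------
    times : nonnegative follow-up times
    events : 1 = event observed, 0 = right-censored
    confidence_level : pointwise CI level, in (0, 1)
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events)
    if times.shape != events.shape or times.ndim != 1:
        raise ParseError("times and events must be equal-length 1-d arrays")
    if not (np.isfinite(times).all() and (times >= 0).all()):
        raise ParseError("every time must be finite and >= 0")
    if not np.isin(events, (0, 1)).all():
        raise ParseError("every event value must be 0 or 1")
    if not 0 < confidence_level < 1:
        raise ParseError("confidence_level must lie in (0, 1)")
    events = events.astype(np.int8)
    if events.sum() == 0:
        raise NoEventsError("all subjects are censored; no event times to estimate at")

    n = len(times)
    order = np.argsort(times, kind="stable")
    t_sorted, e_sorted = times[order], events[order]

    event_times = np.unique(t_sorted[e_sorted == 1])
    # risk set at t_i: all subjects with observed time >= t_i (censored at t_i included)
    n_at_risk = n - np.searchsorted(t_sorted, event_times, side="left")
    evt_times_all = t_sorted[e_sorted == 1]  # sorted
    d = (
        np.searchsorted(evt_times_all, event_times, side="right")
        - np.searchsorted(evt_times_all, event_times, side="left")
    ).astype(np.int64)

    frac = 1.0 - d / n_at_risk
    survival = np.cumprod(frac)

    # Greenwood: Var[S] = S^2 * cumsum d / (n (n - d)); the final term is
    # infinite when d == n (curve hits 0); report se = 0 there by convention.
    with np.errstate(divide="ignore"):
        terms = d / (n_at_risk * (n_at_risk - d).astype(float))
    cum = np.cumsum(terms)
    se = np.where(survival > 0, survival * np.sqrt(np.where(np.isfinite(cum), cum, 0)), 0.0)
    se = np.where(np.isfinite(se), se, 0.0)

    z = stats.norm.ppf(0.5 + confidence_level / 2)
    lo = np.zeros_like(survival)
    hi = np.ones_like(survival)
    inner = (survival > 0) & (survival < 1)
    s_in = survival[inner]
    # cloglog scale: se(log(-log S)) = sqrt(cum) / |log S|
    se_theta = np.sqrt(cum[inner]) / np.abs(np.log(s_in))
    lo[inner] = s_in ** np.exp(z * se_theta)
    hi[inner] = s_in ** np.exp(-z * se_theta)
    zero = survival == 0
    lo[zero], hi[zero] = 0.0, 0.0
    lo, hi = np.clip(lo, 0, 1), np.clip(hi, 0, 1)

    below = np.flatnonzero(survival <= 0.5)
    median = float(event_times[below[0]]) if below.size else None

    cens_times = t_sorted[e_sorted == 0]
    edges = np.searchsorted(event_times, cens_times, side="right")  # 0 = before first
    counts = np.bincount(edges, minlength=len(event_times) + 1)
    return KaplanMeierCurve(
        event_times=event_times,
        n_at_risk=n_at_risk.astype(np.int64),
        n_events=d,
        n_censored_in_interval=counts[1:].astype(np.int64),
        n_censored_before_first=int(counts[0]),
        survival=survival,
        greenwood_se=se,
        ci_lower=lo,
        ci_upper=hi,
        confidence_level=confidence_level,
        median_survival=median,
        n_total=n,
        n_events_total=int(d.sum()),
    )


def km_summary(curve: KaplanMeierCurve, horizons: np.ndarray | list | None = None) -> dict:
    """Summary record: totals, median, and survival at requested horizons.

    Horizon survival is the right-continuous step-function value; horizons
    beyond the last event time return the last estimate flagged as
    extrapolated.
    """
    last = float(curve.event_times[-1])
    horizon_rows = []
    for h in horizons if horizons is not None else []:
        h = float(h)
        if h < 0:
            raise ParseError(f"negative horizon {h}")
        horizon_rows.append(
            {
                "horizon": h,
                "survival": curve.survival_at(min(h, last)),
                "extrapolated": h > last,
            }
        )
    return {
        "n_total": curve.n_total,
        "n_events_total": curve.n_events_total,
        "median_survival": curve.median_survival,
        "median_is_reached": curve.median_is_reached,
        "horizons": horizon_rows,
    }


def km_by_group(
    dataset: SurvivalDataset, confidence_level: float = 0.95
) -> dict[object, KaplanMeierCurve]:
    """One independent KM curve per group label, in deterministic label order."""
    out: dict[object, KaplanMeierCurve] = {}
    for label in dataset.group_labels():
        mask = dataset.groups == label
        sub_events = dataset.event[mask]
        if sub_events.sum() == 0:
            raise NoEventsError(f"group {label!r} has zero observed events")
        out[label] = km_fit(dataset.time[mask], sub_events, confidence_level)
    return out


def life_table(curve: KaplanMeierCurve) -> "np.ndarray":
    """Life table as a structured record list (used by CLI/report writers)."""
    import pandas as pd

    return pd.DataFrame(
        {
            "time": curve.event_times,
            "n_at_risk": curve.n_at_risk,
            "n_events": curve.n_events,
            "n_censored_in_interval": curve.n_censored_in_interval,
            "survival": curve.survival,
            "greenwood_se": curve.greenwood_se,
            "ci_lower": curve.ci_lower,
            "ci_upper": curve.ci_upper,
        }
    )
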