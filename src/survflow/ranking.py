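"""Univariate-Cox screening of candidate features (biomarker ranking).

Each feature is fit alone in a single-covariate Cox model; features are
ordered by ascending Wald p-value (ties broken by descending |z|, then by
name). Benjamini-Hochberg q-values are reported alongside raw p-values:
screening thousands of gene-expression features without multiplicity control
is indefensible, but the adjustment is additive, never replacing raw p.

Constant features are recorded with fit_status='degenerate' and excluded from
ranking; separation-flagged fits are recorded as 'non_converged' and left
unranked because their p-values are unreliable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .cox import _SEPARATION_CAP, _MAX_ITER, _TOL_LL, _TOL_STEP, _PartialLikelihood
from .data import SurvivalDataset
from .errors import DegenerateFeatureError, NoEventsError, ParseError

__all__ = ["FeatureRankingTable", "rank_survival_features", "bh_adjust", "select_top"]


@dataclass(frozen=True)
class FeatureRankingTable:
    """Per-feature univariate statistics; ranked rows first, then unranked."""

    names: tuple[str, ...]
    beta: np.ndarray
    hazard_ratio: np.ndarray
    wald_z: np.ndarray
    wald_p: np.ndarray
    q_value: np.ndarray
    fit_status: tuple[str, ...]  # ok | degenerate | non_converged
    rank: np.ndarray  # 1-based over ok features; -1 for unranked

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "name": list(self.names),
                "beta": self.beta,
                "hr": self.hazard_ratio,
                "z": self.wald_z,
                "p": self.wald_p,
                "q": self.q_value,
                "status": list(self.fit_status),
                "rank": self.rank,
            }
        )

    @property
    def n_ok(self) -> int:
        return sum(s == "ok" for s in self.fit_status)


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, returned in the input order.

    q_(i) = min_{j >= i} m * p_(j) / j, capped at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size and ((p < 0) | (p > 1)).any():
        raise ParseError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum(np.minimum.accumulate(ranked[::-1])[::-1], 1.0)
    q = np.empty_like(q_sorted)
    q[order] = q_sorted
    return q


def _univariate_cox(pl: _PartialLikelihood, x_sorted: np.ndarray, ties: str):
    """Newton-Raphson for a single mean-centered covariate.

    A scalar-specialised twin of the general fit in :mod:`survflow.cox`,
    sharing its convergence criteria; returns (beta, se, converged).
    """
    xs = x_sorted
    d, first_idx = pl.d, pl.first_idx
    evt = pl.event_rows
    sum_x_events = xs[evt].sum()
    tied = pl.tied_groups

    def deriv(b: float):
        eta = b * xs
        shift = eta.max()
        w = np.exp(eta - shift)
        xw = xs * w
        xxw = xs * xw
        rw = np.cumsum(w[::-1])[::-1][first_idx]
        rxw = np.cumsum(xw[::-1])[::-1][first_idx]
        rxxw = np.cumsum(xxw[::-1])[::-1][first_idx]
        mu = rxw / rw
        ll = b * sum_x_events - float(d @ (np.log(rw) + shift))
        g = sum_x_events - float(d @ mu)
        h = float(d @ (rxxw / rw - mu * mu))
        if ties == "efron" and tied.size:
            E = np.zeros(len(pl.uet))
            E1 = np.zeros(len(pl.uet))
            E2 = np.zeros(len(pl.uet))
            np.add.at(E, pl.evt_group, w[evt])
            np.add.at(E1, pl.evt_group, xw[evt])
            np.add.at(E2, pl.evt_group, xxw[evt])
            for j in tied:
                dj = int(d[j])
                ll += dj * (np.log(rw[j]) + shift)
                g += dj * mu[j]
                h -= dj * (rxxw[j] / rw[j] - mu[j] ** 2)
                for l in range(dj):
                    f = l / dj
                    den = rw[j] - f * E[j]
                    muj = (rxw[j] - f * E1[j]) / den
                    ll -= np.log(den) + shift
                    g -= muj
                    h += (rxxw[j] - f * E2[j]) / den - muj**2
        return ll, g, h

    b = 0.0
    ll, g, h = deriv(b)
    converged = False
    for _ in range(_MAX_ITER):
        step = g / h
        scale = 1.0
        for _ in range(21):
            cand = b + scale * step
            ll_new, g_new, h_new = deriv(cand)
            if ll_new >= ll - 1e-14:
                break
            scale /= 2
        delta = abs(cand - b)
        rel = abs(ll_new - ll) / (abs(ll) + 1.0)
        b, ll, g, h = cand, ll_new, g_new, h_new
        if delta < _TOL_STEP or rel < _TOL_LL:
            converged = True
            break
        if abs(b) > _SEPARATION_CAP and abs(g) > 1e-4:
            return b, float(1 / np.sqrt(max(h, 1e-300))), False
    # a monotone-likelihood plateau can satisfy the gradient tolerance too
    return b, float(1 / np.sqrt(max(h, 1e-300))), converged and abs(b) <= _SEPARATION_CAP


def rank_survival_features(
    dataset: SurvivalDataset, features=None, ties_method: str = "efron"
) -> FeatureRankingTable:
    """Screen every feature by a single-covariate Cox fit and rank them."""
    names = tuple(features) if features is not None else dataset.feature_names
    if not names:
        raise ParseError("no features to rank")
    if dataset.n_events == 0:
        raise NoEventsError("ranking requires at least one event")

    m = len(names)
    beta = np.full(m, np.nan)
    se = np.full(m, np.nan)
    status = ["ok"] * m

    cols = {name: dataset.feature(name) for name in names}
    for i, name in enumerate(names):
        x = cols[name]
        finite = np.isfinite(x)
        if np.unique(x[finite]).size <= 1:
            status[i] = "degenerate"
            continue
        if finite.all():
            pl = _pl_cache_get(dataset)
            xs = (x - x.mean())[pl.order]
        else:
            t, e, xv = dataset.time[finite], dataset.event[finite], x[finite]
            pl = _PartialLikelihood(t, e)
            xs = (xv - xv.mean())[pl.order]
        b, s, conv = _univariate_cox(pl, xs, ties_method)
        beta[i], se[i] = b, s
        if not conv:
            status[i] = "non_converged"

    z = beta / se
    p = 2 * stats.norm.sf(np.abs(z))
    ok = np.array([s == "ok" for s in status])
    if not ok.any():
        raise DegenerateFeatureError("no feature yielded a valid fit")

    q = np.full(m, np.nan)
    q[ok] = bh_adjust(p[ok])

    # order: ascending p, then descending |z|, then name
    rank = np.full(m, -1, dtype=int)
    ok_idx = np.flatnonzero(ok)
    keyed = sorted(
        ok_idx, key=lambda i: (p[i], -abs(z[i]), names[i])
    )
    for r, i in enumerate(keyed, start=1):
        rank[i] = r
    return FeatureRankingTable(
        names=names,
        beta=beta,
        hazard_ratio=np.exp(beta),
        wald_z=z,
        wald_p=p,
        q_value=q,
        fit_status=tuple(status),
        rank=rank,
    )


# per-dataset risk-set structure cache (keyed by identity; datasets are frozen)
_pl_cache: dict[int, tuple[object, _PartialLikelihood]] = {}


def _pl_cache_get(dataset: SurvivalDataset) -> _PartialLikelihood:
    key = id(dataset)
    hit = _pl_cache.get(key)
    if hit is not None and hit[0] is dataset:
        return hit[1]
    pl = _PartialLikelihood(dataset.time, dataset.event)
    _pl_cache.clear()
    _pl_cache[key] = (dataset, pl)
    return pl


def select_top(table: FeatureRankingTable, k: int) -> list[str]:
    """Names of the min(k, m_ok) best-ranked features, in rank order."""
    if k < 1:
        raise ParseError("k must be >= 1")
    ranked = sorted(
        (i for i in range(len(table.names)) if table.rank[i] > 0),
        key=lambda i: table.rank[i],
    )
    return [table.names[i] for i in ranked[:k]]
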