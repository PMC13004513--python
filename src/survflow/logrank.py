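"""k-group log-rank test for comparing survival distributions.

At each distinct event time the observed event counts per group are compared
with their expectation under the null (events allocated to groups in
proportion to group risk-set sizes); the accumulated observed-minus-expected
vector is normalised by the accumulated hypergeometric covariance. Ties follow
the same convention as the KM estimator: events occur before censorings, so a
subject censored at an event time is counted in that risk set. Only the
unweighted log-rank is implemented.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy import stats

from .data import SurvivalDataset
from .errors import GroupingError, NoEventsError

__all__ = ["LogRankResult", "logrank_test", "pairwise_logrank", "PairwiseLogRank"]


@dataclass(frozen=True)
class LogRankResult:
    chi_square: float
    degrees_of_freedom: int
    p_value: float
    group_labels: tuple
    per_group_observed: np.ndarray
    per_group_expected: np.ndarray


def _logrank_arrays(
    times: np.ndarray, events: np.ndarray, group_idx: np.ndarray, k: int
) -> LogRankResult:
    n = len(times)
    order = np.argsort(times, kind="stable")
    t, e, g = times[order], events[order], group_idx[order]

    event_times = np.unique(t[e == 1])
    if event_times.size == 0:
        raise NoEventsError("zero events overall")

    # at-risk counts per group at each event time: n_gi = #{j in g : t_j >= t_i}
    first_idx = np.searchsorted(t, event_times, side="left")
    n_i = n - first_idx
    # per-group at-risk via cumulative counts from the right
    onehot = np.zeros((n, k), dtype=np.int64)
    onehot[np.arange(n), g] = 1
    suffix = np.cumsum(onehot[::-1], axis=0)[::-1]  # suffix[i] = counts of times >= t[i]
    n_gi = suffix[first_idx]  # (m, k)

    # events per group at each event time
    evt_mask = e == 1
    te, ge = t[evt_mask], g[evt_mask]
    m = len(event_times)
    ti = np.searchsorted(event_times, te)
    d_gi = np.zeros((m, k), dtype=np.int64)
    np.add.at(d_gi, (ti, ge), 1)
    d_i = d_gi.sum(axis=1)

    expected = d_i[:, None] * n_gi / n_i[:, None]

    # hypergeometric covariance, accumulated; times with n_i == 1 contribute 0
    V = np.zeros((k, k))
    frac = n_gi / n_i[:, None]  # (m, k)
    with np.errstate(divide="ignore", invalid="ignore"):
        mult = d_i * (n_i - d_i) / np.where(n_i > 1, n_i - 1.0, np.inf)
    diag = (mult[:, None] * frac * (1 - frac)).sum(axis=0)
    off = -(frac[:, :, None] * frac[:, None, :] * mult[:, None, None]).sum(axis=0)
    V = off
    V[np.diag_indices(k)] = diag

    O = d_gi.sum(axis=0).astype(float)
    E = expected.sum(axis=0)
    u = (O - E)[:-1]
    V_sub = V[:-1, :-1]
    # pseudo-inverse handles degenerate layouts (e.g. a group with no events)
    rank = np.linalg.matrix_rank(V_sub) if V_sub.size else 0
    chi2 = float(u @ np.linalg.pinv(V_sub) @ u) if V_sub.size else 0.0
    chi2 = max(chi2, 0.0)
    df = int(rank) if rank > 0 else k - 1
    p = float(stats.chi2.sf(chi2, df)) if df > 0 else 1.0
    return LogRankResult(
        chi_square=chi2,
        degrees_of_freedom=df,
        p_value=p,
        group_labels=(),
        per_group_observed=O,
        per_group_expected=E,
    )


def logrank_test(dataset: SurvivalDataset) -> LogRankResult:
    """Unweighted k-group log-rank test on the dataset's group labels."""
    if dataset.groups is None:
        raise GroupingError("dataset has no groups")
    labels = dataset.group_labels()
    k = len(labels)
    if k < 2:
        raise GroupingError(f"need >= 2 groups, found {k}")
    if any(not (dataset.groups == lab).any() for lab in labels):
        raise GroupingError("empty group")
    lookup = {lab: i for i, lab in enumerate(labels)}
    gidx = np.array([lookup[lab] for lab in dataset.groups], dtype=np.int64)
    res = _logrank_arrays(dataset.time, dataset.event.astype(np.int8), gidx, k)
    return LogRankResult(
        chi_square=res.chi_square,
        degrees_of_freedom=res.degrees_of_freedom,
        p_value=res.p_value,
        group_labels=tuple(labels),
        per_group_observed=res.per_group_observed,
        per_group_expected=res.per_group_expected,
    )


@dataclass(frozen=True)
class PairwiseLogRank:
    """All pairwise two-group log-rank results with Bonferroni companions."""

    group_labels: tuple
    pairs: tuple[tuple, ...]
    results: tuple[LogRankResult, ...]
    p_values: np.ndarray
    p_adjusted: np.ndarray  # Bonferroni, capped at 1

    def result_for(self, a, b) -> LogRankResult:
        key = tuple(sorted((a, b), key=str))
        return self.results[self.pairs.index(key)]


def pairwise_logrank(dataset: SurvivalDataset) -> PairwiseLogRank:
    """Two-group log-rank on every pair of groups (unadjusted + Bonferroni)."""
    labels = dataset.group_labels()
    if len(labels) < 2:
        raise GroupingError("need >= 2 groups")
    pairs, results = [], []
    for a, b in combinations(labels, 2):
        mask = (dataset.groups == a) | (dataset.groups == b)
        results.append(logrank_test(dataset.subset(mask)))
        pairs.append((a, b))
    p = np.array([r.p_value for r in results])
    return PairwiseLogRank(
        group_labels=tuple(labels),
        pairs=tuple(pairs),
        results=tuple(results),
        p_values=p,
        p_adjusted=np.minimum(p * len(pairs), 1.0),
    )
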