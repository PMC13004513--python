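"""Harrell's concordance index for validating risk-score discrimination.

A pair of subjects is usable when the data reveal which one failed first:
(i, j) with time_i < time_j is usable iff subject i had an event; a pair with
equal times is usable iff exactly one of the two had an event (the
event-bearer counts as the earlier member); two events at the same time carry
no order information and are unusable. A usable pair is concordant when the
earlier-event subject has the higher score (higher score = higher risk); score
ties count 0.5. C = 0.5 is random, 1 is perfect.

The implementation enumerates all pairs in O(n^2), vectorised in blocks for
transparency and exactness.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cox import CoxModel, predict_linear
from .data import SurvivalDataset
from .errors import NoPairsError, ParseError

__all__ = ["ConcordanceResult", "concordance_index", "cindex_of_model"]


@dataclass(frozen=True)
class ConcordanceResult:
    c_index: float
    concordant: int
    discordant: int
    tied_score: int
    usable_pairs: int


def concordance_index(times, events, scores, _block: int = 512) -> ConcordanceResult:
    """All-pairs Harrell concordance of risk scores against censored outcomes."""
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=np.int8)
    s = np.asarray(scores, dtype=float)
    if not (t.shape == e.shape == s.shape) or t.ndim != 1:
        raise ParseError("times, events and scores must be equal-length 1-d arrays")
    n = len(t)
    conc = disc = tied = 0
    for lo in range(0, n, _block):
        hi = min(lo + _block, n)
        ti, ei, si = t[lo:hi, None], e[lo:hi, None], s[lo:hi, None]
        # usable with i as the earlier member (strictly earlier time, or equal
        # time with i the sole event-bearer)
        earlier = (ei == 1) & ((ti < t[None, :]) | ((ti == t[None, :]) & (e[None, :] == 0)))
        # avoid double counting the diagonal/self pairs; pairs are directional
        # here: each unordered usable pair appears exactly once because the
        # "earlier" role is unique (ties with two events are excluded).
        idx_i, idx_j = np.nonzero(earlier)
        if idx_i.size == 0:
            continue
        # drop self-pairs (possible only via the equal-time branch, where
        # ei=1 and ej=0 cannot hold for i == j, so none arise)
        si_v = si[idx_i, 0]
        sj_v = s[idx_j]
        conc += int((si_v > sj_v).sum())
        disc += int((si_v < sj_v).sum())
        tied += int((si_v == sj_v).sum())
    usable = conc + disc + tied
    if usable == 0:
        raise NoPairsError("no usable pair (all times tied with events, or no events)")
    return ConcordanceResult(
        c_index=(conc + 0.5 * tied) / usable,
        concordant=conc,
        discordant=disc,
        tied_score=tied,
        usable_pairs=usable,
    )


def cindex_of_model(model: CoxModel, dataset: SurvivalDataset) -> ConcordanceResult:
    """Concordance of the model's linear predictor on a dataset."""
    X = dataset.select_features(model.feature_names).covariates
    return concordance_index(dataset.time, dataset.event, predict_linear(model, X))
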