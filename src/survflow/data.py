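"""Survival dataset container, TSV/CSV I/O and variable-based stratification.

The :class:`SurvivalDataset` is the common currency of every analysis stage:
one row per subject, a nonnegative follow-up time, a binary event indicator
(1 = event observed, 0 = right-censored), a numeric covariate matrix and an
optional categorical group label. Time units are opaque nonnegative reals;
no calendar parsing is attempted.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import (
    DegenerateFeatureError,
    EmptyDatasetError,
    EmptyGroupError,
    ParseError,
    SchemaError,
)

__all__ = [
    "SurvivalDataset",
    "StratificationRule",
    "ColumnSchema",
    "read_dataset",
    "write_dataset",
    "stratify",
    "EVENT_TRUTHY",
    "EVENT_FALSY",
]

# Truthy/falsy aliases accepted for the event column when alias mapping is on.
# Real clinical exports vary; the internal model is strictly {0, 1}.
EVENT_TRUTHY = frozenset({"1", "1.0", "true", "yes", "y", "t", "dead", "event", "deceased"})
EVENT_FALSY = frozenset({"0", "0.0", "false", "no", "n", "f", "alive", "censored", "living"})


@dataclass(frozen=True)
class SurvivalDataset:
    """Right-censored survival data for ``n`` subjects and ``p`` features.

    Attributes
    ----------
    subject_ids : array of str, unique labels, length n
    time : float array, finite and >= 0, length n
    event : int array of {0, 1}, length n (1 = event observed)
    covariates : float matrix, shape (n, p); NaN marks a missing value
    feature_names : unique nonempty names, length p
    groups : optional array of categorical labels, length n
    """

    subject_ids: np.ndarray
    time: np.ndarray
    event: np.ndarray
    covariates: np.ndarray
    feature_names: tuple[str, ...]
    groups: np.ndarray | None = None

    def __post_init__(self) -> None:
        ids = np.asarray(self.subject_ids, dtype=object)
        time = np.asarray(self.time, dtype=float)
        event = np.asarray(self.event)
        cov = np.asarray(self.covariates, dtype=float)
        if cov.ndim == 1:
            cov = cov.reshape(len(time), -1) if cov.size else cov.reshape(len(time), 0)
        names = tuple(str(n) for n in self.feature_names)
        groups = None if self.groups is None else np.asarray(self.groups, dtype=object)

        n = len(time)
        if n == 0:
            raise EmptyDatasetError("dataset has zero subjects")
        if not (np.isfinite(time).all() and (time >= 0).all()):
            raise ParseError("every time must be finite and >= 0")
        if not np.isin(event, (0, 1)).all():
            raise ParseError("every event value must be exactly 0 or 1")
        event = event.astype(np.int8)
        if len(ids) != n or len(event) != n or cov.shape[0] != n:
            raise SchemaError("subject_ids, time, event and covariates disagree in length")
        if groups is not None and len(groups) != n:
            raise SchemaError("groups length differs from number of subjects")
        if len(set(map(str, ids))) != n:
            raise SchemaError("subject_ids must be unique")
        if len(names) != cov.shape[1]:
            raise SchemaError("feature_names count differs from covariate columns")
        if len(set(names)) != len(names) or any(not s for s in names):
            raise SchemaError("feature_names must be unique and nonempty")

        object.__setattr__(self, "subject_ids", ids)
        object.__setattr__(self, "time", time)
        object.__setattr__(self, "event", event)
        object.__setattr__(self, "covariates", cov)
        object.__setattr__(self, "feature_names", names)
        object.__setattr__(self, "groups", groups)

    # -- convenience ----------------------------------------------------
    @property
    def n(self) -> int:
        return len(self.time)

    @property
    def p(self) -> int:
        return self.covariates.shape[1]

    @property
    def n_events(self) -> int:
        return int(self.event.sum())

    def feature(self, name: str) -> np.ndarray:
        """Column of covariate values for ``name``."""
        try:
            j = self.feature_names.index(name)
        except ValueError:
            raise SchemaError(f"unknown feature {name!r}") from None
        return self.covariates[:, j]

    def with_groups(self, groups: Sequence) -> "SurvivalDataset":
        """Copy of the dataset with a new group assignment."""
        return replace(self, groups=np.asarray(list(groups), dtype=object))

    def subset(self, mask: np.ndarray) -> "SurvivalDataset":
        """Row subset by boolean mask (groups carried along)."""
        mask = np.asarray(mask, dtype=bool)
        return SurvivalDataset(
            subject_ids=self.subject_ids[mask],
            time=self.time[mask],
            event=self.event[mask],
            covariates=self.covariates[mask],
            feature_names=self.feature_names,
            groups=None if self.groups is None else self.groups[mask],
        )

    def select_features(self, names: Sequence[str]) -> "SurvivalDataset":
        """Dataset restricted to the named covariate columns (order preserved)."""
        idx = []
        for name in names:
            if name not in self.feature_names:
                raise SchemaError(f"unknown feature {name!r}")
            idx.append(self.feature_names.index(name))
        return replace(
            self,
            covariates=self.covariates[:, idx],
            feature_names=tuple(names),
        )

    def to_frame(self) -> pd.DataFrame:
        """Tabular view: id, time, event, covariates, optional group."""
        df = pd.DataFrame({"id": self.subject_ids, "time": self.time, "event": self.event})
        for j, name in enumerate(self.feature_names):
            df[name] = self.covariates[:, j]
        if self.groups is not None:
            df["group"] = self.groups
        return df

    def group_labels(self) -> list:
        """Distinct group labels, deterministically sorted by string form."""
        if self.groups is None:
            raise SchemaError("dataset has no groups")
        return sorted(set(self.groups), key=str)


@dataclass(frozen=True)
class StratificationRule:
    """How to split subjects on one feature into labelled groups.

    mode 'median' splits strictly-below vs at-or-above the sample median
    (midpoint of the two central order statistics for even n); 'explicit_cutoff'
    uses the given ``cutoff`` with the same (<, >=) convention; 'quantile'
    assigns ``quantile_count`` ordinal bins.
    """

    feature_name: str
    mode: str = "median"
    cutoff: float | None = None
    quantile_count: int = 2
    label_low: str = "low"
    label_high: str = "high"

    def __post_init__(self) -> None:
        if self.mode not in ("median", "explicit_cutoff", "quantile"):
            raise SchemaError(f"unknown stratification mode {self.mode!r}")
        if self.mode == "explicit_cutoff" and (
            self.cutoff is None or not np.isfinite(self.cutoff)
        ):
            raise SchemaError("explicit_cutoff mode requires a finite cutoff")
        if self.mode == "quantile" and self.quantile_count < 2:
            raise SchemaError("quantile mode requires quantile_count >= 2")


@dataclass(frozen=True)
class ColumnSchema:
    """Column-role mapping for :func:`read_dataset`."""

    time_col: str
    event_col: str
    feature_cols: tuple[str, ...] = ()
    group_col: str | None = None
    id_col: str | None = None


def _parse_float_column(raw: pd.Series) -> tuple[np.ndarray, np.ndarray]:
    """Exact string->float parsing; returns (values, unparseable mask).

    Python's float() round-trips shortest-repr decimals exactly, which
    pandas.to_numeric does not guarantee.
    """
    vals = np.full(len(raw), np.nan)
    bad = np.zeros(len(raw), dtype=bool)
    for i, v in enumerate(raw.to_numpy()):
        if pd.isna(v) or (isinstance(v, str) and not v.strip()):
            continue
        try:
            vals[i] = float(v)
        except (TypeError, ValueError):
            bad[i] = True
    return vals, bad


def _parse_event_column(raw: pd.Series, aliases: bool) -> np.ndarray:
    out = np.empty(len(raw), dtype=float)
    for i, v in enumerate(raw.to_numpy()):
        if pd.isna(v):
            out[i] = np.nan
            continue
        s = str(v).strip().lower()
        if s in ("0", "1"):
            out[i] = float(s)
        elif aliases and s in EVENT_TRUTHY:
            out[i] = 1.0
        elif aliases and s in EVENT_FALSY:
            out[i] = 0.0
        else:
            try:
                f = float(s)
            except ValueError:
                raise ParseError(
                    f"row {i}: event value {v!r} not interpretable as 0/1"
                ) from None
            if f not in (0.0, 1.0):
                raise ParseError(f"row {i}: event value {v!r} not in {{0, 1}}")
            out[i] = f
    return out


def read_dataset(
    path: str | os.PathLike,
    schema: ColumnSchema | Mapping[str, object],
    *,
    delimiter: str | None = None,
    event_aliases: bool = True,
    drop_missing: bool = False,
) -> SurvivalDataset:
    """Read a delimited survival table into a validated :class:`SurvivalDataset`.

    Delimiter is auto-detected from the extension (``.csv`` -> comma, else tab)
    and overridable. Rows with missing time or event are rejected unless
    ``drop_missing`` is set, in which case they are dropped and their count is
    reported via a ``UserWarning`` (silent dropping would hide data loss).
    """
    import warnings

    if isinstance(schema, Mapping):
        schema = ColumnSchema(
            time_col=str(schema["time_col"]),
            event_col=str(schema["event_col"]),
            feature_cols=tuple(schema.get("feature_cols", ()) or ()),
            group_col=schema.get("group_col"),
            id_col=schema.get("id_col"),
        )
    if not os.path.exists(path):
        raise SchemaError(f"no such file: {path}")
    sep = delimiter or ("," if str(path).lower().endswith(".csv") else "\t")
    df = pd.read_csv(path, sep=sep, dtype=object, encoding="utf-8")

    needed = [schema.time_col, schema.event_col, *schema.feature_cols]
    if schema.group_col:
        needed.append(schema.group_col)
    if schema.id_col:
        needed.append(schema.id_col)
    for col in needed:
        if col not in df.columns:
            raise SchemaError(f"missing column {col!r} (file has {list(df.columns)})")

    time, bad_time = _parse_float_column(df[schema.time_col])
    if bad_time.any():
        i = int(np.flatnonzero(bad_time)[0])
        raise ParseError(f"row {i}: time value {df[schema.time_col].iloc[i]!r} not numeric")
    event = _parse_event_column(df[schema.event_col], aliases=event_aliases)

    missing = ~np.isfinite(time) | ~np.isfinite(event)
    if missing.any():
        if not drop_missing:
            i = int(np.flatnonzero(missing)[0])
            raise ParseError(
                f"row {i}: missing time or event (pass drop_missing=True to drop; "
                f"{int(missing.sum())} such rows)"
            )
        warnings.warn(
            f"dropped {int(missing.sum())} rows with missing time/event",
            UserWarning,
            stacklevel=2,
        )
        df = df.loc[~missing].reset_index(drop=True)
        time, event = time[~missing], event[~missing]
    if len(df) == 0:
        raise EmptyDatasetError("zero usable rows")

    neg = time < 0
    if neg.any():
        i = int(np.flatnonzero(neg)[0])
        raise ParseError(f"row {i}: negative time {time[i]}")

    if schema.feature_cols:
        cov = np.column_stack(
            [_parse_float_column(df[c])[0] for c in schema.feature_cols]
        )
    else:
        cov = np.empty((len(df), 0))
    ids = (
        df[schema.id_col].astype(str).to_numpy()
        if schema.id_col
        else np.array([f"S{i}" for i in range(len(df))], dtype=object)
    )
    groups = df[schema.group_col].astype(str).to_numpy() if schema.group_col else None
    return SurvivalDataset(
        subject_ids=ids,
        time=time,
        event=event.astype(int),
        covariates=cov,
        feature_names=tuple(schema.feature_cols),
        groups=groups,
    )


def write_dataset(dataset: SurvivalDataset, path: str | os.PathLike) -> None:
    """Write a TSV such that reading it back reproduces the dataset exactly.

    Floats are written with :func:`repr` precision so the round trip is exact.
    """
    df = dataset.to_frame()
    df.to_csv(path, sep="\t", index=False, float_format=None, encoding="utf-8")


def dataset_schema(dataset: SurvivalDataset) -> ColumnSchema:
    """Schema matching the column layout produced by :func:`write_dataset`."""
    return ColumnSchema(
        time_col="time",
        event_col="event",
        feature_cols=dataset.feature_names,
        group_col="group" if dataset.groups is not None else None,
        id_col="id",
    )


def stratify(dataset: SurvivalDataset, rule: StratificationRule) -> SurvivalDataset:
    """Assign group labels by splitting one feature; returns a new dataset.

    Median and explicit-cutoff modes use the strictly-below vs at-or-above
    convention (label_low where value < cut, label_high where value >= cut), so
    ties at the boundary land deterministically in the high group. Quantile
    mode assigns ``quantile_count`` ordinal labels by sample-quantile bins.
    """
    x = dataset.feature(rule.feature_name)
    finite = x[np.isfinite(x)]
    if finite.size == 0 or np.unique(finite).size <= 1:
        raise DegenerateFeatureError(
            f"feature {rule.feature_name!r} has <= 1 distinct finite value"
        )

    if rule.mode in ("median", "explicit_cutoff"):
        cut = float(np.median(finite)) if rule.mode == "median" else float(rule.cutoff)
        labels = np.where(x < cut, rule.label_low, rule.label_high).astype(object)
        n_low = int((x < cut).sum())
        n_high = int((x >= cut).sum())
        if n_low == 0 or n_high == 0:
            raise EmptyGroupError(
                f"cutoff {cut} leaves an empty group for {rule.feature_name!r}"
            )
    else:
        q = rule.quantile_count
        edges = np.quantile(finite, np.linspace(0, 1, q + 1)[1:-1])
        bins = np.searchsorted(edges, x, side="left")  # value < edge -> lower bin
        width = len(str(q - 1))
        labels = np.array([f"Q{b + 1:0{width}d}" for b in bins], dtype=object)
        if len(set(labels)) < 2:
            raise EmptyGroupError("quantile binning produced fewer than 2 groups")
    return dataset.with_groups(labels)
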