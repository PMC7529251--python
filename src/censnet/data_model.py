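"""Survival-data containers, Kaplan-Meier estimation and table I/O.

The basic observational unit is a pair ``(x, delta)`` per sample and event:
``x`` is the observed time (the event time if ``delta == 1``, the censoring
time if ``delta == 0``).  A dataset holds ``N`` samples by ``J`` events in
wide form, one ``time_<event>`` / ``status_<event>`` column pair per event,
which preserves the per-sample row alignment the network estimator needs.
"""

from __future__ import annotations

import dataclasses
import os
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "KMCurve",
    "SurvivalMatrix",
    "kaplan_meier",
    "censoring_rate",
    "read_survival_table",
    "write_survival_table",
    "write_edge_list",
    "write_adjacency",
]


@dataclasses.dataclass(frozen=True)
class KMCurve:
    """Product-limit estimate of a survival function.

    Attributes
    ----------
    event_times : ndarray
        Strictly increasing times at which at least one event occurred.
    survival : ndarray
        S(t) immediately after each event time (non-increasing, in [0, 1]).
    n_at_risk : ndarray
        Number of samples at risk at each event time.
    """

    event_times: np.ndarray
    survival: np.ndarray
    n_at_risk: np.ndarray

    def survival_at(self, t: float | np.ndarray) -> float | np.ndarray:
        """Right-continuous step evaluation S(t); S(t) = 1 before the first event."""
        idx = np.searchsorted(self.event_times, t, side="right")
        s = np.concatenate([[1.0], self.survival])
        out = s[idx]
        if np.isscalar(t):
            return float(out)
        return out

    def increments(self) -> np.ndarray:
        """Probability mass dropped at each event time, ``S(t-) - S(t)`` (>= 0)."""
        prev = np.concatenate([[1.0], self.survival[:-1]])
        return prev - self.survival


def kaplan_meier(times: np.ndarray, status: np.ndarray) -> KMCurve:
    """Kaplan-Meier product-limit estimator for one right-censored event.

    Ties between events and censorings at the same time are resolved with the
    standard convention that events precede censorings: a sample censored at
    ``t`` is still at risk for events occurring at ``t``.

    Parameters
    ----------
    times : array-like
        Observed times, non-negative.
    status : array-like
        1 where the event was observed, 0 where censored.

    Returns
    -------
    KMCurve
    """
    times = np.asarray(times, dtype=float)
    status = np.asarray(status)
    if times.size == 0:
        raise ValueError("kaplan_meier: empty input")
    if times.shape != status.shape:
        raise ValueError("kaplan_meier: times and status have different shapes")
    if np.any(times < 0):
        raise ValueError("kaplan_meier: negative time")
    _check_status(status)

    uniq = np.unique(times)
    surv, ev_t, ev_s, ev_n = 1.0, [], [], []
    for t in uniq:
        n_risk = int(np.sum(times >= t))
        d = int(np.sum((times == t) & (status == 1)))
        if d == 0:
            continue
        surv *= 1.0 - d / n_risk
        ev_t.append(t)
        ev_s.append(surv)
        ev_n.append(n_risk)
    return KMCurve(
        event_times=np.asarray(ev_t, dtype=float),
        survival=np.asarray(ev_s, dtype=float),
        n_at_risk=np.asarray(ev_n, dtype=int),
    )


def _check_status(status: np.ndarray) -> None:
    bad = ~np.isin(np.asarray(status), (0, 1))
    if np.any(bad):
        idx = np.argwhere(bad)[0]
        raise ValueError(
            f"status value {np.asarray(status)[tuple(idx)]!r} at index "
            f"{tuple(int(i) for i in idx)} is not in {{0, 1}}"
        )


@dataclasses.dataclass
class SurvivalMatrix:
    """Observed right-censored times for ``N`` samples and ``J`` events.

    ``times[n, j]`` is the observed time of event ``j`` for sample ``n`` and
    ``status[n, j]`` is 1 if the event was observed, 0 if right-censored.
    """

    times: np.ndarray
    status: np.ndarray
    event_names: list[str]

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.status = np.asarray(self.status, dtype=int)
        if self.times.ndim != 2:
            raise ValueError("times must be a 2-D (N x J) array")
        if self.times.shape != self.status.shape:
            raise ValueError(
                f"times shape {self.times.shape} != status shape {self.status.shape}"
            )
        if len(self.event_names) != self.times.shape[1]:
            raise ValueError("event_names length must equal the number of columns")
        if np.any(self.times < 0):
            n, j = np.argwhere(self.times < 0)[0]
            raise ValueError(
                f"negative time {self.times[n, j]} for sample {n}, "
                f"event {self.event_names[j]!r}"
            )
        _check_status(self.status)

    @property
    def n_samples(self) -> int:
        return self.times.shape[0]

    @property
    def n_events(self) -> int:
        return self.times.shape[1]

    def column(self, j: int) -> tuple[np.ndarray, np.ndarray]:
        """Return the ``(times, status)`` vectors of event ``j``."""
        return self.times[:, j], self.status[:, j]


def censoring_rate(sm: SurvivalMatrix) -> np.ndarray:
    """Per-event censoring rate ``1 - mean(status)``, a length-J vector in [0, 1]."""
    return 1.0 - sm.status.mean(axis=0)


# ---------------------------------------------------------------------------
# table I/O


def _infer_sep(path: str, sep: str | None) -> str:
    if sep is not None:
        return sep
    return "\t" if os.fspath(path).endswith((".tsv", ".txt")) else ","


def read_survival_table(
    path: str,
    mapping: Mapping[str, tuple[str, str]] | None = None,
    sep: str | None = None,
) -> SurvivalMatrix:
    """Read a wide survival table with paired time/status columns.

    Parameters
    ----------
    path : str
        Delimited text file.  The delimiter is taken from the extension
        (``.tsv``/``.txt`` -> tab, otherwise comma) unless ``sep`` is given.
    mapping : dict, optional
        Explicit ``{event_name: (time_column, status_column)}``.  When absent,
        pairing is inferred from ``time_<event>`` / ``status_<event>`` names.
    """
    try:
        df = pd.read_csv(path, sep=_infer_sep(path, sep), float_precision="round_trip")
    except pd.errors.EmptyDataError as exc:
        raise ValueError(f"empty survival table: {path}") from exc
    if df.shape[0] == 0:
        raise ValueError(f"survival table has no rows: {path}")

    if mapping is None:
        mapping = {}
        for col in df.columns:
            if col.startswith("time_"):
                name = col[len("time_"):]
                partner = f"status_{name}"
                if partner not in df.columns:
                    raise ValueError(
                        f"time column {col!r} has no status partner {partner!r}"
                    )
                mapping[name] = (col, partner)
        if not mapping:
            raise ValueError(
                "no time_*/status_* column pairs found; pass an explicit mapping"
            )

    names = list(mapping)
    times = np.column_stack([df[mapping[n][0]].to_numpy(dtype=float) for n in names])
    status_cols = []
    for n in names:
        col = df[mapping[n][1]].to_numpy()
        bad = ~np.isin(col, (0, 1))
        if np.any(bad):
            row = int(np.argwhere(bad)[0][0])
            raise ValueError(
                f"status value {col[row]!r} in column {mapping[n][1]!r}, row {row}"
            )
        status_cols.append(col.astype(int))
    status = np.column_stack(status_cols)
    return SurvivalMatrix(times=times, status=status, event_names=names)


def write_survival_table(sm: SurvivalMatrix, path: str, sep: str | None = None) -> None:
    """Write a :class:`SurvivalMatrix` in the paired wide format.

    Times are printed with 17 significant digits so float64 values round-trip
    bit-exactly through :func:`read_survival_table`.
    """
    data: dict[str, np.ndarray] = {}
    for j, name in enumerate(sm.event_names):
        data[f"time_{name}"] = sm.times[:, j]
        data[f"status_{name}"] = sm.status[:, j]
    pd.DataFrame(data).to_csv(
        path, sep=_infer_sep(path, sep), index=False, float_format="%.17g"
    )


def write_edge_list(
    scores: np.ndarray, event_names: Sequence[str], path: str, threshold: float = 0.0
) -> None:
    """Write upper-triangle scores as a TSV edge list ``event_a  event_b  score``."""
    rows = []
    j = len(event_names)
    for a in range(j):
        for b in range(a + 1, j):
            if scores[a, b] > threshold:
                rows.append((event_names[a], event_names[b], scores[a, b]))
    pd.DataFrame(rows, columns=["event_a", "event_b", "score"]).to_csv(
        path, sep="\t", index=False, float_format="%.10g"
    )


def write_adjacency(
    matrix: np.ndarray, event_names: Sequence[str], path: str
) -> None:
    """Write a square matrix (adjacency, scores, covariance) as a labelled CSV."""
    pd.DataFrame(matrix, index=list(event_names), columns=list(event_names)).to_csv(
        path, float_format="%.17g"
    )
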