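"""Pup-retrieval assay scoring from timestamped event logs.

A dam is introduced to a cage with her pups scattered outside the nest and
given ``test_duration`` seconds (default 300 s, the 5-min cutoff) to carry
them back.  The log records pup-directed outcomes (``retrieve``,
``approach_no_retrieve``, ``drop``) and non-pup-directed events (``rear``,
``sniff``).  Windows are half-open ``[0, window)``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from . import stats as _stats

EVENT_KINDS = ("approach_no_retrieve", "drop", "retrieve", "rear", "sniff")
FAILURE_KINDS = ("approach_no_retrieve", "drop")


@dataclass
class BehaviorLog:
    """Time-sorted event log of one retrieval assay."""

    events: pd.DataFrame             # columns: t_s, kind, pup_id (optional)
    n_pups: int = 4
    test_duration_s: float = 300.0

    def __post_init__(self) -> None:
        ev = self.events.copy()
        if "pup_id" not in ev.columns:
            ev["pup_id"] = pd.NA
        bad = set(ev["kind"]) - set(EVENT_KINDS)
        if bad:
            raise ValueError(f"unknown event kinds: {sorted(bad)}")
        if ((ev["t_s"] < 0) | (ev["t_s"] > self.test_duration_s)).any():
            raise ValueError("event times must lie within [0, test_duration]")
        n_ret = int((ev["kind"] == "retrieve").sum())
        if n_ret > self.n_pups:
            raise ValueError(f"{n_ret} retrieve events for {self.n_pups} pups")
        self.events = ev.sort_values("t_s", kind="stable").reset_index(drop=True)

    def count(self, kind: str) -> int:
        return int((self.events["kind"] == kind).sum())


@dataclass(frozen=True)
class RetrievalMetrics:
    latency_all_s: float
    latency_censored: bool
    relative_failure_index: float
    failure_index_defined: bool
    rearing_first_min: int
    sniffs_first_30s: int
    n_retrieved: int
    n_failures: int


def cumulative_retrieval(log: BehaviorLog):
    """Right-continuous step function of percent of pups retrieved by t.

    Returns ``(times, percents, percent_at)`` where ``times``/``percents``
    describe the step function and ``percent_at(t)`` evaluates it.
    """
    t_ret = np.sort(
        log.events.loc[log.events["kind"] == "retrieve", "t_s"].to_numpy())
    pct = 100.0 * np.arange(1, t_ret.size + 1) / log.n_pups if log.n_pups \
        else np.full(t_ret.size, np.nan)

    def percent_at(t: float) -> float:
        if log.n_pups == 0:
            return float("nan")
        return 100.0 * float(np.searchsorted(t_ret, t, side="right")) / log.n_pups

    return t_ret, pct, percent_at


def latency_all_pups(log: BehaviorLog) -> tuple[float, bool]:
    """Time of the n_pups-th retrieve; censored at test end when fewer occur."""
    if log.n_pups == 0:
        return 0.0, True
    t_ret = np.sort(
        log.events.loc[log.events["kind"] == "retrieve", "t_s"].to_numpy())
    if t_ret.size >= log.n_pups:
        return float(t_ret[log.n_pups - 1]), False
    return float(log.test_duration_s), True


def relative_failure_index(log: BehaviorLog,
                           mode: str = "relative") -> tuple[float, bool]:
    """Failed approaches (no-retrieve + drop) over all pup-directed outcomes.

    ``relative`` (default) normalizes by failures + retrieves, bounding the
    index in [0, 1]; ``raw`` returns the failure count.  Second element is
    False when no pup-directed event occurred (index undefined, reported 0).
    """
    n_fail = sum(log.count(k) for k in FAILURE_KINDS)
    n_ret = log.count("retrieve")
    if mode == "raw":
        return float(n_fail), True
    if mode != "relative":
        raise ValueError(f"unknown mode {mode!r}")
    total = n_fail + n_ret
    if total == 0:
        return 0.0, False
    return n_fail / total, True


def windowed_count(log: BehaviorLog, kind: str, window_s: float) -> int:
    """Events of ``kind`` with t in [0, window)."""
    if window_s > log.test_duration_s:
        raise ValueError("window exceeds test duration")
    ev = log.events
    return int(((ev["kind"] == kind) & (ev["t_s"] < window_s)).sum())


def metric_correlation(x: Sequence[float], y: Sequence[float]):
    """Spearman correlation between two per-animal metrics."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    if x.size != y.size:
        raise ValueError("paired samples required")
    if x.size < 4:
        raise ValueError("need n >= 4 pairs")
    return _stats.spearman(x, y)


def retrieval_metrics(log: BehaviorLog) -> RetrievalMetrics:
    latency, censored = latency_all_pups(log)
    rfi, defined = relative_failure_index(log)
    return RetrievalMetrics(
        latency_all_s=latency,
        latency_censored=censored,
        relative_failure_index=rfi,
        failure_index_defined=defined,
        rearing_first_min=windowed_count(log, "rear", 60.0),
        sniffs_first_30s=windowed_count(log, "sniff", 30.0),
        n_retrieved=log.count("retrieve"),
        n_failures=sum(log.count(k) for k in FAILURE_KINDS),
    )


def metrics_table(logs: dict[str, BehaviorLog]) -> pd.DataFrame:
    """Per-animal metric table over a dict of animal_id -> log."""
    rows = []
    for animal, log in logs.items():
        m = retrieval_metrics(log)
        _, _, pct_at = cumulative_retrieval(log)
        rows.append({"animal_id": animal,
                     "latency_all_s": m.latency_all_s,
                     "latency_censored": m.latency_censored,
                     "relative_failure_index": m.relative_failure_index,
                     "rearing_first_min": m.rearing_first_min,
                     "sniffs_first_30s": m.sniffs_first_30s,
                     "pct_retrieved_60s": pct_at(60.0),
                     "pct_retrieved_end": pct_at(log.test_duration_s),
                     "n_retrieved": m.n_retrieved,
                     "n_failures": m.n_failures})
    return pd.DataFrame(rows)
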