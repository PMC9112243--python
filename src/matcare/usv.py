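"""Ultrasonic-vocalization (USV) call metrics and six-way categorization.

Pup isolation calls are represented by their time-frequency contour (peak
frequency per time bin) plus a linear-amplitude trace.  Each call receives
exactly one of six categories -- short, flat, chevron, complex, upward,
downward -- through a decision tree on duration, total frequency
modulation, direction reversals of the smoothed contour, and net frequency
change.  Thresholds are configurable; defaults follow common rodent-call
classification conventions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

CATEGORIES = ("short", "flat", "chevron", "complex", "upward", "downward")


@dataclass
class USVCall:
    contour_t: np.ndarray            # seconds, increasing
    contour_f: np.ndarray            # Hz, > 0
    amplitude: np.ndarray            # linear amplitude, >= 0
    call_id: str = ""
    litter_id: str = ""
    pup_id: str = ""

    def __post_init__(self) -> None:
        self.contour_t = np.asarray(self.contour_t, dtype=float)
        self.contour_f = np.asarray(self.contour_f, dtype=float)
        self.amplitude = np.asarray(self.amplitude, dtype=float)
        if not (self.contour_t.size == self.contour_f.size
                == self.amplitude.size):
            raise ValueError("contour arrays must have equal length")
        if self.contour_t.size >= 2 and np.any(np.diff(self.contour_t) <= 0):
            raise ValueError("contour times must be increasing")
        if np.any(self.contour_f <= 0):
            raise ValueError("frequencies must be positive")


@dataclass(frozen=True)
class CallMetrics:
    duration_s: float
    mean_linear_amplitude: float
    freq_at_max_peak_hz: float
    category: str | None = None


@dataclass(frozen=True)
class USVThresholds:
    """Category decision-tree thresholds (all configurable)."""
    d_short_s: float = 0.005         # calls shorter than this are 'short'
    m_flat_hz: float = 3000.0        # total modulation below this is 'flat'
    m_dir_hz: float = 6000.0         # net change beyond this is up/downward
    smooth_window: int = 3           # moving-median window (points)
    hysteresis_hz: float = 1000.0    # band a reversal must exceed


def call_metrics(call: USVCall) -> CallMetrics:
    """Duration, mean linear amplitude and frequency at the amplitude peak.

    Amplitude ties resolve to the earliest time.
    """
    if call.contour_t.size < 2:
        raise ValueError("need at least 2 contour points")
    i_max = int(np.argmax(call.amplitude))       # first maximum on ties
    return CallMetrics(
        duration_s=float(call.contour_t[-1] - call.contour_t[0]),
        mean_linear_amplitude=float(call.amplitude.mean()),
        freq_at_max_peak_hz=float(call.contour_f[i_max]),
    )


def _moving_median(f: np.ndarray, window: int) -> np.ndarray:
    if window <= 1 or f.size < window:
        return f.copy()
    pad = window // 2
    fp = np.pad(f, pad, mode="edge")
    return np.array([np.median(fp[i:i + window]) for i in range(f.size)])


def count_reversals(f: np.ndarray, hysteresis_hz: float) -> int:
    """Direction reversals of a contour, with hysteresis.

    A reversal is counted when the contour retreats more than the
    hysteresis band from its running extremum in the current direction;
    the initial direction is not a reversal.
    """
    direction = 0
    ext = f[0]
    reversals = 0
    for v in f[1:]:
        if direction == 0:
            if v >= ext + hysteresis_hz:
                direction = 1
                ext = v
            elif v <= ext - hysteresis_hz:
                direction = -1
                ext = v
        elif direction == 1:
            if v > ext:
                ext = v
            elif v <= ext - hysteresis_hz:
                reversals += 1
                direction = -1
                ext = v
        else:
            if v < ext:
                ext = v
            elif v >= ext + hysteresis_hz:
                reversals += 1
                direction = 1
                ext = v
    return reversals


def classify_call(call: USVCall,
                  thresholds: USVThresholds = USVThresholds()) -> str:
    """Assign exactly one of the six call categories.

    Decision order: short (duration), flat (low total modulation), complex
    (>= 2 reversals), chevron (single reversal through an interior
    maximum), upward/downward (net frequency change), flat fallback.
    Invariant to uniform time shifts and to amplitude rescaling.
    """
    th = thresholds
    duration = float(call.contour_t[-1] - call.contour_t[0])
    if duration < th.d_short_s:
        return "short"
    f = _moving_median(call.contour_f, th.smooth_window)
    modulation = float(f.max() - f.min())
    if modulation < th.m_flat_hz:
        return "flat"
    reversals = count_reversals(f, th.hysteresis_hz)
    if reversals >= 2:
        return "complex"
    i_max = int(np.argmax(f))
    if reversals == 1 and 0 < i_max < f.size - 1:
        return "chevron"
    net = float(f[-1] - f[0])
    if net > th.m_dir_hz:
        return "upward"
    if net < -th.m_dir_hz:
        return "downward"
    return "flat"


def call_table(calls: Iterable[USVCall],
               thresholds: USVThresholds = USVThresholds()) -> pd.DataFrame:
    """Tidy per-call table of metrics and category."""
    rows = []
    for c in calls:
        m = call_metrics(c)
        rows.append({"call_id": c.call_id, "litter_id": c.litter_id,
                     "pup_id": c.pup_id, "duration_s": m.duration_s,
                     "mean_linear_amplitude": m.mean_linear_amplitude,
                     "freq_at_max_peak_hz": m.freq_at_max_peak_hz,
                     "category": classify_call(c, thresholds)})
    return pd.DataFrame(rows)


def litter_summary(calls: Iterable[USVCall],
                   thresholds: USVThresholds = USVThresholds()
                   ) -> pd.DataFrame:
    """Per-litter, per-category call counts and metric means.

    Every (litter, category) pair appears; empty categories carry count 0
    and NaN means.
    """
    tab = call_table(calls, thresholds)
    if tab.empty:
        return pd.DataFrame(columns=["litter_id", "category", "n_calls",
                                     "mean_duration_s", "mean_amplitude",
                                     "mean_freq_at_max_peak_hz"])
    litters = sorted(tab["litter_id"].unique())
    idx = pd.MultiIndex.from_product([litters, CATEGORIES],
                                     names=["litter_id", "category"])
    g = tab.groupby(["litter_id", "category"], observed=True)
    out = pd.DataFrame({
        "n_calls": g.size(),
        "mean_duration_s": g["duration_s"].mean(),
        "mean_amplitude": g["mean_linear_amplitude"].mean(),
        "mean_freq_at_max_peak_hz": g["freq_at_max_peak_hz"].mean(),
    }).reindex(idx)
    out["n_calls"] = out["n_calls"].fillna(0).astype(int)
    return out.reset_index()
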