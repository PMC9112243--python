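"""Plain-text I/O for every exchange format the pipeline consumes.

CSV for spike times (unit_id, t_s), waveforms (unit_id, dt_us, s0..sN),
epoch windows (epoch, start_s, end_s), behavior events (t_s, kind,
pup_id), USV contours (call_id, litter_id, pup_id, t_s, freq_hz, amp) and
cell tables; SWC for morphologies (see ``morphology``); counts either as
a plain CSV (cells x genes) or MatrixMarket + metadata CSV.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .behavior import BehaviorLog
from .ephys import EpochWindows, SpikeTrain
from .usv import USVCall


# --- spikes ----------------------------------------------------------------

def write_spikes_csv(trains: Iterable[SpikeTrain], path) -> None:
    rows = [(t.unit_id, s) for t in trains for s in t.spike_times]
    pd.DataFrame(rows, columns=["unit_id", "t_s"]).to_csv(path, index=False)


def write_waveforms_csv(trains: Iterable[SpikeTrain], path) -> None:
    recs = []
    for t in trains:
        recs.append({"unit_id": t.unit_id, "dt_us": t.dt_us,
                     **{f"s{i}": v for i, v in enumerate(t.waveform)}})
    pd.DataFrame(recs).to_csv(path, index=False)


def read_spike_trains(spikes_csv, waveforms_csv) -> list[SpikeTrain]:
    sp = pd.read_csv(spikes_csv)
    wf = pd.read_csv(waveforms_csv)
    scols = sorted((c for c in wf.columns if c.startswith("s")
                    and c[1:].isdigit()), key=lambda c: int(c[1:]))
    trains = []
    for _, row in wf.iterrows():
        uid = row["unit_id"]
        t = np.sort(sp.loc[sp["unit_id"] == uid, "t_s"].to_numpy(float))
        w = row[scols].to_numpy(float)
        trains.append(SpikeTrain(unit_id=str(uid), spike_times=t,
                                 waveform=w[~np.isnan(w)],
                                 dt_us=float(row["dt_us"])))
    return trains


def write_epochs_csv(windows: EpochWindows, path) -> None:
    windows.to_frame().to_csv(path, index=False)


def read_epochs_csv(path) -> EpochWindows:
    return EpochWindows.from_frame(pd.read_csv(path))


# --- behavior --------------------------------------------------------------

def write_events_csv(log: BehaviorLog, path) -> None:
    log.events.to_csv(path, index=False)


def read_behavior_log(path, n_pups: int = 4,
                      test_duration_s: float = 300.0) -> BehaviorLog:
    return BehaviorLog(events=pd.read_csv(path), n_pups=n_pups,
                       test_duration_s=test_duration_s)


# --- USV -------------------------------------------------------------------

def write_contours_csv(calls: Iterable[USVCall], path) -> None:
    rows = []
    for c in calls:
        for t, f, a in zip(c.contour_t, c.contour_f, c.amplitude):
            rows.append((c.call_id, c.litter_id, c.pup_id, t, f, a))
    pd.DataFrame(rows, columns=["call_id", "litter_id", "pup_id",
                                "t_s", "freq_hz", "amp"]
                 ).to_csv(path, index=False)


def read_usv_calls(path) -> list[USVCall]:
    df = pd.read_csv(path)
    calls = []
    for cid, sub in df.groupby("call_id", sort=False):
        sub = sub.sort_values("t_s")
        calls.append(USVCall(
            contour_t=sub["t_s"].to_numpy(float),
            contour_f=sub["freq_hz"].to_numpy(float),
            amplitude=sub["amp"].to_numpy(float),
            call_id=str(cid), litter_id=str(sub["litter_id"].iloc[0]),
            pup_id=str(sub["pup_id"].iloc[0])))
    return calls


# --- counts ----------------------------------------------------------------

def write_counts(counts: pd.DataFrame, meta: pd.DataFrame, prefix) -> None:
    prefix = Path(prefix)
    counts.to_csv(prefix.with_suffix(".counts.csv"))
    meta.to_csv(prefix.with_suffix(".meta.csv"))


def read_counts(prefix) -> tuple[pd.DataFrame, pd.DataFrame]:
    prefix = Path(prefix)
    counts = pd.read_csv(prefix.with_suffix(".counts.csv"), index_col=0)
    meta = pd.read_csv(prefix.with_suffix(".meta.csv"), index_col=0)
    return counts, meta
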