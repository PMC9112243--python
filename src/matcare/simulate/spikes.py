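"""Synthetic single-unit spike trains with known ground truth.

Emulates a recording session of a 10-min baseline followed by a 15-min
pup-retrieval assay: three unit classes (narrow-spiking, wide-spiking,
fast-firing), bimodal spike-width populations, Poisson tonic firing with
epoch-modulated rates, and -- for wide-spiking units -- injected bursts
that are unambiguous under the ISI < 80 ms burst rule (the tonic process
of wide units carries an 80-ms dead time, rate-compensated, and tonic
spikes near an injected burst are cleared), so detector output can be
compared to ground truth exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..config import BEHAVIORAL_EPOCHS, SimConfig
from ..ephys import BURST_ISI_MAX_S, BURST_SPAN_MAX_S, EpochWindows, SpikeTrain
from ._rng import substream

#: 10 %-amplitude full width of a Gaussian lobe is WIDTH_FACTOR * sigma.
_W10 = 2.0 * np.sqrt(2.0 * np.log(10.0))          # ~4.29193
#: distance from a 0.4-amplitude Gaussian's centre to its 0.1 crossing.
_W_UNDER = np.sqrt(2.0 * np.log(4.0))             # ~1.66511

UNDERSHOOT_AMP = 0.4                              # fraction of main peak
MAIN_SIGMA_MS = 0.12                              # wide-unit main lobe
UNDER_SIGMA_MS = 0.25                             # wide-unit undershoot lobe
_CLEAR_S = BURST_ISI_MAX_S + 0.0005               # clearance around bursts


@dataclass(frozen=True)
class SpikeUnitTruth:
    unit_id: str
    klass: str                                    # narrow | wide | fast
    width_ms: float
    rate_tonic_hz: float
    rate_per_epoch: dict                          # epoch -> tonic rate (Hz)
    burst_spike_indices: tuple = ()               # tuple of index tuples
    n_spikes: int = 0


@dataclass(frozen=True)
class SpikeGroundTruth:
    units: list
    windows: EpochWindows
    by_id: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(self, "by_id", {u.unit_id: u for u in self.units})


def gen_epoch_windows(cfg: SimConfig) -> EpochWindows:
    """Deterministic epoch layout: baseline, then one retrieval trial per
    pup (10-s approach, 5-s retrieval, 20-s post-interaction) evenly
    spaced through the assay."""
    tb, ta = cfg.baseline_duration_s, cfg.assay_duration_s
    windows = {"baseline": [(0.0, tb)], "approach": [],
               "retrieval": [], "post_interaction": []}
    block = ta / max(cfg.n_pups, 1)
    for k in range(cfg.n_pups):
        s = tb + k * block
        windows["approach"].append((s, s + 10.0))
        windows["retrieval"].append((s + 10.0, s + 15.0))
        windows["post_interaction"].append((s + 15.0, s + 35.0))
    return EpochWindows(windows)


def make_waveform(width_ms: float, klass: str, dt_us: float = 25.0,
                  n_samples: int = 120) -> np.ndarray:
    """Parametric mean waveform whose 10 %-crossing full width is
    ``width_ms`` by construction (closed form, no fitting).

    narrow/fast: single Gaussian lobe, sigma = width / (2*sqrt(2*ln 10)).
    wide: 0.12-ms main lobe plus a -0.4-amplitude, 0.25-ms-sigma
    undershoot placed so the outermost 10 % crossings span ``width_ms``;
    the undershoot is deeper than 20 % of the peak for ~0.59 ms, carrying
    the waveform signature used for dead-zone assignment.
    """
    dt_ms = dt_us / 1000.0
    t = np.arange(n_samples) * dt_ms
    if klass in ("narrow", "fast"):
        sigma = width_ms / _W10
        t0 = 0.35 * n_samples * dt_ms
        return np.exp(-0.5 * ((t - t0) / sigma) ** 2)
    if klass == "wide":
        sm, su = MAIN_SIGMA_MS, UNDER_SIGMA_MS
        t0 = 0.25 * n_samples * dt_ms
        first = t0 - 0.5 * _W10 * sm
        tu = first + width_ms - _W_UNDER * su
        if tu <= t0:
            raise ValueError(f"width {width_ms} ms too small for the "
                             "wide-unit template")
        v = np.exp(-0.5 * ((t - t0) / sm) ** 2)
        v -= UNDERSHOOT_AMP * np.exp(-0.5 * ((t - tu) / su) ** 2)
        return v
    raise ValueError(f"unknown unit class {klass!r}")


def _piecewise_segments(cfg: SimConfig, windows: EpochWindows
                        ) -> list[tuple[float, float, float]]:
    """(start, end, gain) covering [0, baseline+assay); un-annotated assay
    time keeps gain 1."""
    total = cfg.baseline_duration_s + cfg.assay_duration_s
    marks = [(a, b, cfg.epoch_gain.get(e, 1.0))
             for e in BEHAVIORAL_EPOCHS for a, b in windows[e]]
    marks.sort()
    segs, cur = [], 0.0
    for a, b, g in marks:
        if a > cur:
            segs.append((cur, a, 1.0))
        segs.append((a, b, g))
        cur = b
    if cur < total:
        segs.append((cur, total, 1.0))
    return segs


def _poisson_segment(rng, a: float, b: float, rate: float) -> np.ndarray:
    n = rng.poisson(rate * (b - a))
    return np.sort(rng.uniform(a, b, size=n))


def _deadtime_segment(rng, a: float, b: float, rate: float,
                      dead: float = BURST_ISI_MAX_S) -> np.ndarray:
    """Renewal process with dead time: ISI = dead + Exp(lam), with lam
    chosen so the mean rate equals ``rate`` (requires rate < 1/dead)."""
    if rate <= 0:
        return np.empty(0)
    if rate * dead >= 1:
        raise ValueError("rate too high for the dead-time process")
    lam = 1.0 / (1.0 / rate - dead)
    n_est = int(rate * (b - a) * 1.5) + 20
    isis = dead + rng.exponential(1.0 / lam, size=n_est)
    t = a + rng.uniform(0, 1.0 / rate) + np.cumsum(isis)
    t = t[t < b]
    while t.size and t[-1] < b - 5 * (dead + 1.0 / lam):   # rare under-draw
        more = t[-1] + np.cumsum(dead + rng.exponential(1.0 / lam, n_est))
        t = np.concatenate([t, more[more < b]])
    return t


def _inject_bursts(rng, cfg: SimConfig, tonic: np.ndarray, total_s: float
                   ) -> tuple[np.ndarray, list[np.ndarray]]:
    """Place bursts uniformly in time, cleared of tonic spikes and of each
    other by more than the burst ISI threshold."""
    isi = cfg.intra_burst_isi_ms / 1000.0
    n_bursts = rng.poisson(cfg.burst_rate * total_s)
    starts = np.sort(rng.uniform(0.0, total_s, size=n_bursts))
    ks = rng.integers(cfg.burst_spikes_min, cfg.burst_spikes_max + 1,
                      size=n_bursts)
    bursts, last_end = [], -np.inf
    for s, k in zip(starts, ks):
        span = (k - 1) * isi
        if span > BURST_SPAN_MAX_S:
            raise ValueError("configured burst span exceeds the 160-ms cap")
        if s <= last_end + _CLEAR_S or s + span >= total_s:
            continue
        bursts.append(s + np.arange(k) * isi)
        last_end = s + span
    keep = np.ones(tonic.size, dtype=bool)
    for b in bursts:
        keep &= (tonic < b[0] - _CLEAR_S) | (tonic > b[-1] + _CLEAR_S)
    merged = np.sort(np.concatenate([tonic[keep]] + bursts)) if bursts \
        else tonic[keep]
    idx = [tuple(int(i) for i in np.searchsorted(merged, b)) for b in bursts]
    return merged, idx


def gen_spike_dataset(cfg: SimConfig
                      ) -> tuple[list[SpikeTrain], SpikeGroundTruth]:
    """Generate all units of one session with per-unit ground truth."""
    rng = substream(cfg.seed, "spikes")
    windows = gen_epoch_windows(cfg)
    segs = _piecewise_segments(cfg, windows)
    total = cfg.baseline_duration_s + cfg.assay_duration_s
    class_rates = {"narrow": cfg.fr_narrow, "wide": cfg.fr_wide,
                   "fast": cfg.fr_fast}
    trains, truths = [], []
    for klass in ("narrow", "wide", "fast"):
        for j in range(cfg.n_units_per_class):
            base = class_rates[klass]
            if cfg.fr_cv > 0:
                sigma = np.sqrt(np.log1p(cfg.fr_cv ** 2))
                base = base * rng.lognormal(-0.5 * sigma ** 2, sigma)
            width = rng.normal(cfg.width_means[klass], cfg.width_sds[klass])
            wf = make_waveform(width, klass, cfg.waveform_dt_us,
                               cfg.waveform_n_samples)
            pieces = []
            for a, b, g in segs:
                r = base * g
                if r <= 0:
                    continue
                if klass == "wide":
                    pieces.append(_deadtime_segment(rng, a, b, r))
                else:
                    pieces.append(_poisson_segment(rng, a, b, r))
            t = np.sort(np.concatenate(pieces)) if pieces else np.empty(0)
            burst_idx: list = []
            if klass == "wide" and cfg.burst_rate > 0:
                t, burst_idx = _inject_bursts(rng, cfg, t, total)
            unit_id = f"{klass}_{j:03d}"
            trains.append(SpikeTrain(unit_id=unit_id, spike_times=t,
                                     waveform=wf, dt_us=cfg.waveform_dt_us))
            rate_per_epoch = {"baseline": base}
            for e in BEHAVIORAL_EPOCHS:
                rate_per_epoch[e] = base * cfg.epoch_gain.get(e, 1.0)
            truths.append(SpikeUnitTruth(
                unit_id=unit_id, klass=klass, width_ms=float(width),
                rate_tonic_hz=float(base), rate_per_epoch=rate_per_epoch,
                burst_spike_indices=tuple(burst_idx), n_spikes=int(t.size)))
    return trains, SpikeGroundTruth(units=truths, windows=windows)
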