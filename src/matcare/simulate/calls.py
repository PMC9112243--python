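"""Synthetic USV call contours drawn from six archetypes.

Archetype shapes (frequency against time, small Gaussian jitter on top):
flat -- constant; upward/downward -- monotone ramps well past the
direction threshold; chevron -- symmetric rise then fall (interior peak);
complex -- 1.25-cycle sinusoid (>= 2 direction reversals); short --
a flat contour shorter than the short-call duration threshold.
"""

from __future__ import annotations

import numpy as np

from ..config import SimConfig
from ..usv import CATEGORIES, USVCall
from ._rng import substream

_JITTER_HZ = 200.0


def _contour(rng, category: str, duration_s: float, n: int,
             base_hz: float) -> np.ndarray:
    x = np.linspace(0.0, 1.0, n)
    if category in ("flat", "short"):
        f = np.full(n, base_hz)
    elif category == "upward":
        f = base_hz + rng.uniform(9000.0, 14000.0) * x
    elif category == "downward":
        f = base_hz - rng.uniform(9000.0, 14000.0) * x
    elif category == "chevron":
        amp = rng.uniform(8000.0, 12000.0)
        f = base_hz + amp * np.sin(np.pi * x)          # interior peak
    elif category == "complex":
        amp = rng.uniform(5000.0, 8000.0)
        f = base_hz + amp * np.sin(2.0 * np.pi * 1.25 * x)
    else:
        raise ValueError(f"unknown category {category!r}")
    return f + rng.normal(0.0, _JITTER_HZ, size=n)


def gen_usv_calls(cfg: SimConfig,
                  rng: np.random.Generator | None = None,
                  n_litters: int = 4
                  ) -> tuple[list[USVCall], list[str]]:
    """``usv_n_per_category`` calls per archetype, with true labels.

    Calls are assigned to litters (and four pups per litter) round-robin.
    """
    if rng is None:
        rng = substream(cfg.seed, "usv")
    calls: list[USVCall] = []
    labels: list[str] = []
    dt = cfg.usv_contour_dt_s
    k = 0
    for category in CATEGORIES:
        for _ in range(cfg.usv_n_per_category):
            if category == "short":
                duration = rng.uniform(0.002, 0.004)
            else:
                duration = rng.uniform(0.020, 0.060)
            n = max(int(round(duration / dt)) + 1, 3)
            base = rng.uniform(60000.0, 80000.0)
            f = _contour(rng, category, duration, n, base)
            t = np.linspace(0.0, duration, n)
            amp = rng.uniform(0.5, 1.5) * (0.8 + 0.4 * rng.random(n))
            calls.append(USVCall(
                contour_t=t, contour_f=np.clip(f, 1000.0, None),
                amplitude=amp, call_id=f"call{k:05d}",
                litter_id=f"litter{k % n_litters}",
                pup_id=f"pup{(k // n_litters) % 4}"))
            labels.append(category)
            k += 1
    return calls, labels
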