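"""Synthetic pup-retrieval event logs with known ground truth.

For each pup the dam makes repeated approaches (exponential waiting
times); each approach independently fails with probability ``p_fail``
(half ``approach_no_retrieve``, half ``drop``), otherwise the pup is
retrieved.  Rearing and sniffing are homogeneous Poisson processes over
the whole test.  The test ends at ``test_duration_s``; pups not retrieved
by then censor the latency.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ..behavior import BehaviorLog
from ..config import SimConfig
from ._rng import substream


@dataclass(frozen=True)
class BehaviorTruth:
    n_retrieved: int
    n_failures: int
    retrieve_times: tuple
    latency_all_s: float
    latency_censored: bool
    rear_times: tuple
    sniff_times: tuple


def gen_behavior_log(cfg: SimConfig,
                     rng: np.random.Generator | None = None
                     ) -> tuple[BehaviorLog, BehaviorTruth]:
    if cfg.n_pups < 1:
        raise ValueError("need n_pups >= 1")
    if rng is None:
        rng = substream(cfg.seed, "behavior")
    T = cfg.test_duration_s
    rows = []
    retrieve_times = []
    n_failures = 0
    t = 0.0
    ended = False
    for pup in range(cfg.n_pups):
        if ended:
            break
        while True:
            t += rng.exponential(cfg.approach_interval_mean_s)
            if t >= T:
                ended = True
                break
            if rng.random() < cfg.p_fail:
                kind = "drop" if rng.random() < 0.5 else "approach_no_retrieve"
                rows.append((t, kind, f"pup{pup}"))
                n_failures += 1
            else:
                rows.append((t, "retrieve", f"pup{pup}"))
                retrieve_times.append(t)
                break
    for kind, rate_per_min in (("rear", cfg.rear_rate),
                               ("sniff", cfg.sniff_rate)):
        n = rng.poisson(rate_per_min / 60.0 * T)
        for tt in np.sort(rng.uniform(0.0, T, size=n)):
            rows.append((float(tt), kind, None))
    ev = pd.DataFrame(rows, columns=["t_s", "kind", "pup_id"])
    log = BehaviorLog(events=ev, n_pups=cfg.n_pups, test_duration_s=T)
    censored = len(retrieve_times) < cfg.n_pups
    latency = T if censored else retrieve_times[-1]
    truth = BehaviorTruth(
        n_retrieved=len(retrieve_times), n_failures=n_failures,
        retrieve_times=tuple(retrieve_times), latency_all_s=float(latency),
        latency_censored=censored,
        rear_times=tuple(ev.loc[ev["kind"] == "rear", "t_s"]),
        sniff_times=tuple(ev.loc[ev["kind"] == "sniff", "t_s"]))
    return log, truth
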