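#!/usr/bin/env python
"""Generate one synthetic recording session's raw input files.

Writes spike times, mean waveforms, epoch windows, a behavior event log
and USV contours for a single dam under scratch/session/ (raw event-level
files are large; every downstream script regenerates what it needs from
the seed, so these files are illustrative, not a dependency).
"""

from pathlib import Path

from matcare import io
from matcare.config import SimConfig
from matcare.simulate import (gen_behavior_log, gen_spike_dataset,
                              gen_usv_calls)

OUT = Path(__file__).resolve().parent.parent / "scratch" / "session"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    cfg = SimConfig(seed=1, n_units_per_class=4, usv_n_per_category=10)
    trains, truth = gen_spike_dataset(cfg)
    io.write_spikes_csv(trains, OUT / "spikes.csv")
    io.write_waveforms_csv(trains, OUT / "waveforms.csv")
    io.write_epochs_csv(truth.windows, OUT / "epochs.csv")
    log, _ = gen_behavior_log(cfg)
    io.write_events_csv(log, OUT / "events.csv")
    calls, _ = gen_usv_calls(cfg)
    io.write_contours_csv(calls, OUT / "contours.csv")
    cfg.to_json(OUT / "sim_config.json")
    n_spikes = sum(t.n_spikes for t in trains)
    print(f"session written to {OUT}")
    print(f"  {len(trains)} units, {n_spikes} spikes, "
          f"{len(log.events)} behavior events, {len(calls)} USV calls")


if __name__ == "__main__":
    main()
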