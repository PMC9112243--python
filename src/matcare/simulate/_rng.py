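"""Seed-substream management for the generators.

One global seed fans out into fixed, named substreams so that adding a new
generator (or re-running one) never perturbs the draws of the others.
"""

from __future__ import annotations

import numpy as np

#: Fixed registry: stream name -> spawn key.  Append only; never reorder.
_STREAMS = {
    "spikes": 1,
    "behavior": 2,
    "morphology": 3,
    "usv": 4,
    "cells": 5,
    "expression": 6,
    "pipeline": 7,
}


def substream(seed: int, name: str) -> np.random.Generator:
    if name not in _STREAMS:
        raise KeyError(f"unknown RNG stream {name!r}; register it first")
    ss = np.random.SeedSequence(entropy=int(seed),
                                spawn_key=(_STREAMS[name],))
    return np.random.default_rng(ss)
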