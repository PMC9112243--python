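"""Simulation and experiment configuration.

``SimConfig`` collects every tunable of the synthetic-data generators in one
place so that a single seed fixes all outputs bit-for-bit.  Defaults mirror
the assay constants of the study design this package models: a 10-min
baseline recording followed by a 15-min pup-retrieval assay with four foster
pups, a 5-min (300-s) retrieval cutoff, slow-firing unit classes straddling
the 1.2/1.4-ms spike-width cutoffs, and 20-µm Sholl shells.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Mapping

#: Gene panel used for the cluster-level expression summaries.
DEFAULT_GENE_PANEL: tuple[str, ...] = (
    "Il6r", "Il1r1", "Jak1", "Jak2",
    "Stat1", "Stat2", "Stat3", "Stat4", "Stat5a", "Stat5b", "Stat6",
    "Ifnar1", "Ifnar2", "Ifngr1", "Ifngr2",
    "Tlr3", "Tlr4", "Myd88", "Ticam1", "Tirap",
    "Traf3", "Traf6", "Ikbkb", "Chuk", "Nfkb1", "Nfkb2", "Mapk14",
)

DEFAULT_CLUSTERS: tuple[str, ...] = ("i8", "i16", "i18")

#: Sex coding used in the metadata: 0 = female, 1 = male.
DEFAULT_SEXES: tuple[int, int] = (0, 1)

EPOCHS: tuple[str, ...] = ("baseline", "approach", "retrieval", "post_interaction")
BEHAVIORAL_EPOCHS: tuple[str, ...] = ("approach", "retrieval", "post_interaction")


@dataclass
class SimConfig:
    """All knobs of the synthetic-data generators.

    Rates are in Hz (or events/min where stated), times in seconds,
    spike widths in ms, lengths in µm.
    """

    seed: int = 0

    # --- spike-train generator -------------------------------------------
    n_units_per_class: int = 20
    baseline_duration_s: float = 600.0     # 10-min baseline without pups
    assay_duration_s: float = 900.0        # 15-min pup-retrieval assay
    fr_narrow: float = 6.0                 # slow-firing, putative GABAergic
    fr_wide: float = 3.0                   # slow-firing, putative dopaminergic
    fr_fast: float = 15.0                  # fast-firing (FR > 10 Hz)
    fr_cv: float = 0.0                     # lognormal unit-to-unit rate spread
    width_means: Mapping[str, float] = field(
        default_factory=lambda: {"narrow": 0.9, "wide": 1.6, "fast": 0.8})
    width_sds: Mapping[str, float] = field(
        default_factory=lambda: {"narrow": 0.05, "wide": 0.05, "fast": 0.05})
    burst_rate: float = 0.05               # injected bursts/s for wide units
    intra_burst_isi_ms: float = 20.0
    burst_spikes_min: int = 2
    burst_spikes_max: int = 5
    epoch_gain: Mapping[str, float] = field(
        default_factory=lambda: {"approach": 1.0, "retrieval": 1.0,
                                 "post_interaction": 1.0})
    waveform_dt_us: float = 25.0           # 40-kHz sampled mean waveform
    waveform_n_samples: int = 120

    # --- behavior generator ----------------------------------------------
    n_pups: int = 4
    test_duration_s: float = 300.0         # 5-min retrieval cutoff
    p_fail: float = 0.15                   # P(approach fails) per approach
    approach_interval_mean_s: float = 20.0
    rear_rate: float = 3.0                 # rearing events/min
    sniff_rate: float = 10.0               # sniff events/min

    # --- USV generator ----------------------------------------------------
    usv_n_per_category: int = 50
    usv_contour_dt_s: float = 0.001

    # --- morphology generator --------------------------------------------
    tree_depth: int = 4
    branch_len: float = 30.0
    branch_prob: float = 0.7               # P(bifurcate) per non-root node

    # --- cell table / expression generator -------------------------------
    n_animals: int = 6
    n_sections: int = 2
    n_hemispheres: int = 2
    cells_per_image: int = 100
    p_gal: float = 0.2                     # P(Gal+ | DAPI+)
    p_cfos: float = 0.4                    # P(c-Fos+ | Gal+)
    cells_per_group: int = 200             # cells per (cluster, sex)
    nb_mean: float = 2.0                   # NB mean for expressing cells
    nb_dispersion: float = 1.0             # NB size parameter
    expr_fractions: Mapping[tuple, float] | None = None
    gene_panel: tuple[str, ...] = DEFAULT_GENE_PANEL
    clusters: tuple[str, ...] = DEFAULT_CLUSTERS

    def __post_init__(self) -> None:
        for name in ("p_fail", "p_gal", "p_cfos", "branch_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name in ("fr_narrow", "fr_wide", "fr_fast", "burst_rate",
                     "rear_rate", "sniff_rate", "fr_cv"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for epoch, gain in self.epoch_gain.items():
            if gain < 0:
                raise ValueError(f"epoch_gain[{epoch!r}] must be >= 0")
        if self.tree_depth < 0:
            raise ValueError("tree_depth must be >= 0")
        if self.n_pups < 0:
            raise ValueError("n_pups must be >= 0")
        if self.burst_spikes_min < 2:
            raise ValueError("bursts need at least 2 spikes")
        if self.expr_fractions is not None:
            for key, p in self.expr_fractions.items():
                if not 0.0 <= p <= 1.0:
                    raise ValueError(f"expr_fractions[{key}] must be in [0, 1]")

    def replace(self, **kwargs) -> "SimConfig":
        return dataclasses.replace(self, **kwargs)

    def to_json(self, path) -> None:
        d = dataclasses.asdict(self)
        d["width_means"] = dict(self.width_means)
        d["width_sds"] = dict(self.width_sds)
        d["epoch_gain"] = dict(self.epoch_gain)
        if self.expr_fractions is not None:
            d["expr_fractions"] = {"|".join(map(str, k)): v
                                   for k, v in self.expr_fractions.items()}
        with open(path, "w") as fh:
            json.dump(d, fh, indent=2, default=list)

    @classmethod
    def from_json(cls, path) -> "SimConfig":
        with open(path) as fh:
            d = json.load(fh)
        if d.get("expr_fractions") is not None:
            d["expr_fractions"] = {
                tuple(k.split("|")): v for k, v in d["expr_fractions"].items()}
        for key in ("gene_panel", "clusters"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)
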