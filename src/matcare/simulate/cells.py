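"""Synthetic cell-count tables and cell x gene count matrices.

Cell tables emulate per-image marker counts (DAPI always positive, Gal+
as a Bernoulli of ``p_gal``, c-Fos+ evaluated only within Gal+ cells with
probability ``p_cfos``).  Expression matrices draw, per (gene, cluster,
sex), a Bernoulli expression flag times a shifted negative-binomial count,
plus a few filler genes so every cell has nonzero library size.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ..config import DEFAULT_SEXES, SimConfig
from ._rng import substream

FILLER_GENES = ("Actb", "Gapdh", "Tubb3", "Rpl13a")


@dataclass(frozen=True)
class CellTableTruth:
    p_gal: float
    p_cfos: float
    n_cells: int
    n_gal: int
    n_cfos: int


@dataclass(frozen=True)
class ExpressionTruth:
    expr_fractions: dict             # (gene, cluster, sex) -> probability
    nb_mean: float
    nb_dispersion: float


def gen_cell_table(cfg: SimConfig, roi: str = "mPOA",
                   rng: np.random.Generator | None = None,
                   p_gal: float | None = None,
                   p_cfos: float | None = None,
                   group: str = "",
                   ) -> tuple[pd.DataFrame, CellTableTruth]:
    """One ROI's cell table across animals, sections and hemispheres."""
    if rng is None:
        rng = substream(cfg.seed, "cells")
    p_gal = cfg.p_gal if p_gal is None else p_gal
    p_cfos = cfg.p_cfos if p_cfos is None else p_cfos
    rows = []
    cell = 0
    for a in range(cfg.n_animals):
        for s in range(cfg.n_sections):
            for h in range(cfg.n_hemispheres):
                gal = rng.random(cfg.cells_per_image) < p_gal
                cfos = gal & (rng.random(cfg.cells_per_image) < p_cfos)
                for i in range(cfg.cells_per_image):
                    rows.append((f"cell{cell:06d}", roi,
                                 f"{group}animal{a}", f"sec{s}", f"hem{h}",
                                 True, bool(gal[i]), bool(cfos[i])))
                    cell += 1
    tab = pd.DataFrame(rows, columns=["cell_id", "roi", "animal_id",
                                      "section", "hemisphere",
                                      "dapi", "gal", "cfos"])
    truth = CellTableTruth(p_gal=p_gal, p_cfos=p_cfos, n_cells=len(tab),
                           n_gal=int(tab["gal"].sum()),
                           n_cfos=int(tab["cfos"].sum()))
    return tab, truth


def default_expr_fractions(cfg: SimConfig,
                           rng: np.random.Generator) -> dict:
    """Per-(gene, cluster, sex) expression probabilities drawn once from
    U(0.05, 0.8) when the config does not pin them."""
    return {(g, c, s): float(rng.uniform(0.05, 0.8))
            for g in cfg.gene_panel for c in cfg.clusters
            for s in DEFAULT_SEXES}


def gen_expression(cfg: SimConfig,
                   rng: np.random.Generator | None = None
                   ) -> tuple[pd.DataFrame, pd.DataFrame, ExpressionTruth]:
    """Counts (cells x genes), metadata (cluster, sex) and ground truth."""
    if rng is None:
        rng = substream(cfg.seed, "expression")
    fracs = dict(cfg.expr_fractions) if cfg.expr_fractions is not None \
        else default_expr_fractions(cfg, rng)
    p_nb = cfg.nb_dispersion / (cfg.nb_dispersion + cfg.nb_mean)
    cells, meta_rows = [], []
    counts = {g: [] for g in (*cfg.gene_panel, *FILLER_GENES)}
    cell = 0
    for cluster in cfg.clusters:
        for sex in DEFAULT_SEXES:
            n = cfg.cells_per_group
            for g in cfg.gene_panel:
                p = fracs.get((g, cluster, sex), 0.0)
                expressing = rng.random(n) < p
                c = np.where(
                    expressing,
                    1 + rng.negative_binomial(cfg.nb_dispersion, p_nb, n),
                    0)
                counts[g].extend(c.tolist())
            for g in FILLER_GENES:
                counts[g].extend((1 + rng.poisson(4.0, n)).tolist())
            for _ in range(n):
                cells.append(f"cell{cell:06d}")
                meta_rows.append((cluster, sex))
                cell += 1
    counts_df = pd.DataFrame(counts, index=cells)
    meta = pd.DataFrame(meta_rows, columns=["cluster", "sex"], index=cells)
    return counts_df, meta, ExpressionTruth(
        expr_fractions=fracs, nb_mean=cfg.nb_mean,
        nb_dispersion=cfg.nb_dispersion)
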