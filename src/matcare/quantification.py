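"""Marker-fraction quantification and expression dot-plot summaries.

Histochemistry side: cell tables carry per-cell boolean flags (DAPI, Gal+,
c-Fos+) per image (one image per hemisphere, two sections per brain);
fractions aggregate image -> animal -> group with unweighted means at each
level.  Transcriptomics side: cluster- and sex-resolved fraction-expressing
and mean log-normalized expression for a gene panel, as shown in dot
plots.  Library-size log-normalization is ln(1 + scale * count / total).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class MarkerFractions:
    frac_cfos_in_gal: float          # (#Gal+ & c-Fos+) / #Gal+
    frac_gal_per_dapi: float         # #Gal+ / #DAPI+
    cfos_defined: bool               # False when no Gal+ cell in the ROI
    per_animal: pd.DataFrame


def marker_fractions(table: pd.DataFrame, roi: str) -> MarkerFractions:
    """Marker fractions for one ROI.

    Per-image fractions are averaged per animal first (unweighted over
    sections and hemispheres), then across animals; the pooled per-animal
    table is returned for group statistics.
    """
    sub = table[table["roi"] == roi]
    if sub.empty:
        raise ValueError(f"no cells for ROI {roi!r}")
    group_cols = [c for c in ("animal_id", "section", "hemisphere")
                  if c in sub.columns]
    if "animal_id" not in group_cols:
        raise ValueError("cell table needs an animal_id column")

    def _image_fracs(g: pd.DataFrame) -> pd.Series:
        n_gal = int(g["gal"].sum())
        n_dapi = int(g["dapi"].sum())
        return pd.Series({
            "frac_cfos_in_gal":
                (g["cfos"] & g["gal"]).sum() / n_gal if n_gal else np.nan,
            "frac_gal_per_dapi":
                n_gal / n_dapi if n_dapi else np.nan,
        })

    per_image = (sub.groupby(group_cols, observed=True)
                 .apply(_image_fracs, include_groups=False).reset_index())
    per_animal = (per_image.groupby("animal_id", observed=True)
                  [["frac_cfos_in_gal", "frac_gal_per_dapi"]]
                  .mean().reset_index())
    cfos_vals = per_animal["frac_cfos_in_gal"].dropna()
    return MarkerFractions(
        frac_cfos_in_gal=float(cfos_vals.mean()) if len(cfos_vals) else np.nan,
        frac_gal_per_dapi=float(per_animal["frac_gal_per_dapi"].mean()),
        cfos_defined=bool(len(cfos_vals)),
        per_animal=per_animal,
    )


def lognormalize(counts: pd.DataFrame, scale: float = 1e4) -> pd.DataFrame:
    """Per-cell library-size log-normalization: ln(1 + scale*count/total).

    Cells (rows) with zero total counts are dropped with a warning.
    """
    totals = counts.sum(axis=1)
    zero = totals == 0
    if zero.any():
        warnings.warn(f"dropping {int(zero.sum())} all-zero cells",
                      stacklevel=2)
        counts = counts.loc[~zero]
        totals = totals.loc[~zero]
    return np.log1p(counts.div(totals, axis=0) * scale)


def dotplot_summary(counts: pd.DataFrame, meta: pd.DataFrame,
                    genes, scale: float = 1e4,
                    expr_threshold: float = 0.0) -> pd.DataFrame:
    """Dot-plot summary per (gene, cluster, sex) group.

    For each group: fraction of cells with raw count > ``expr_threshold``,
    mean log-normalized expression, and a z-scaled mean across the groups
    of each gene (0 when the gene is flat across groups).  Sexes are kept
    separate throughout.  Missing genes raise rather than being silently
    dropped.
    """
    genes = list(genes)
    missing = [g for g in genes if g not in counts.columns]
    if missing:
        raise ValueError(f"genes absent from the count matrix: {missing}")
    if not meta.index.equals(counts.index):
        meta = meta.loc[counts.index]
    # normalize against the full library of each cell, then take the panel
    norm = lognormalize(counts, scale=scale)[genes]
    raw = counts.loc[norm.index, genes]
    groups = meta.loc[norm.index].groupby(["cluster", "sex"], observed=True)
    rows = []
    for (cluster, sex), idx in groups.groups.items():
        if len(idx) == 0:
            raise ValueError(f"empty group ({cluster}, {sex})")
        frac = (raw.loc[idx] > expr_threshold).mean(axis=0)
        mean = norm.loc[idx].mean(axis=0)
        for g in genes:
            rows.append({"gene": g, "cluster": cluster, "sex": sex,
                         "fraction_expressing": float(frac[g]),
                         "mean_expression": float(mean[g])})
    out = pd.DataFrame(rows)
    scaled = []
    for g, sub in out.groupby("gene", observed=True, sort=False):
        mu = sub["mean_expression"].mean()
        sd = sub["mean_expression"].std(ddof=0)
        z = (sub["mean_expression"] - mu) / sd if sd > 0 \
            else sub["mean_expression"] * 0.0
        scaled.append(z)
    out["scaled_mean"] = pd.concat(scaled)
    return out
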