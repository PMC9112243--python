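"""End-to-end synthetic experiment: two cohorts, every analysis, one report.

``run_experiment`` generates a vehicle and a treated (viral-mimic,
Poly I:C-like) cohort with configurable effect sizes, runs the behavior,
ephys, morphology, USV and quantification analyses, applies the
statistical layer, and emits tidy CSVs plus a summary table (per metric:
group mean ± SEM, test, statistic, p).  The same seed yields a
byte-identical report.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import behavior as bhv
from . import ephys, morphology, quantification, stats, usv
from .config import BEHAVIORAL_EPOCHS, SimConfig
from .simulate import (gen_behavior_log, gen_cell_table, gen_expression,
                       gen_morphology, gen_spike_dataset, gen_usv_calls)

GROUPS = ("vehicle", "polyic")

#: Default treated-group effects, sized like the group differences the
#: pipeline is meant to surface: narrow-spiking FR up ~50 %, wide-spiking
#: FR down ~30 %, more failed approaches, more rearing, shorter dendrites,
#: weaker c-Fos recruitment.
DEFAULT_EFFECTS = {
    "narrow_fr_gain": 1.5,
    "wide_fr_gain": 0.7,
    "p_fail": 0.45,
    "rear_rate_gain": 1.6,
    "branch_len_gain": 0.85,
    "p_cfos": 0.25,
}

ALL_STAGES = ("behavior", "ephys", "morphology", "usv", "quantification")


@dataclass
class ExperimentConfig:
    seed: int = 0
    n_dams_per_group: int = 16
    n_units_per_class: int = 20
    n_neurons_per_group: int = 30
    n_litters_per_group: int = 4
    effects: dict = field(default_factory=lambda: dict(DEFAULT_EFFECTS))
    base: SimConfig = field(default_factory=SimConfig)
    delta_fr_formula: str = "contrast"
    per_animal_aggregation: bool = False     # ephys tests per unit by default


@dataclass
class ExperimentReport:
    tables: dict
    summary: pd.DataFrame
    log: dict


def _group_cfg(cfg: ExperimentConfig, group: str) -> SimConfig:
    """Per-group SimConfig; assay constants are shared, effects apply to
    the treated group only."""
    gi = GROUPS.index(group)
    sim = cfg.base.replace(seed=(cfg.seed * 10 + gi) % 2 ** 31,
                           n_units_per_class=cfg.n_units_per_class)
    if group == "polyic":
        e = cfg.effects
        sim = sim.replace(
            fr_narrow=sim.fr_narrow * e.get("narrow_fr_gain", 1.0),
            fr_wide=sim.fr_wide * e.get("wide_fr_gain", 1.0),
            p_fail=e.get("p_fail", sim.p_fail),
            rear_rate=sim.rear_rate * e.get("rear_rate_gain", 1.0),
            branch_len=sim.branch_len * e.get("branch_len_gain", 1.0),
            p_cfos=e.get("p_cfos", sim.p_cfos),
        )
    return sim


def _rng_for(cfg: ExperimentConfig, group: str, stage: str, item: int):
    key = {"behavior": 10, "morphology": 11, "usv": 12, "cells": 13,
           "expression": 14}[stage]
    ss = np.random.SeedSequence(entropy=int(cfg.seed),
                                spawn_key=(key, GROUPS.index(group), item))
    return np.random.default_rng(ss)


def _summ_row(panel, metric, a, b, res: stats.TestResult) -> dict:
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    return {
        "panel": panel, "metric": metric,
        "vehicle_mean": a.mean(), "vehicle_sem": sps_sem(a),
        "polyic_mean": b.mean(), "polyic_sem": sps_sem(b),
        "n_vehicle": a.size, "n_polyic": b.size,
        "test": res.test, "statistic": res.statistic, "p": res.p,
    }


def sps_sem(x: np.ndarray) -> float:
    x = np.asarray(x, float)
    return float(x.std(ddof=1) / np.sqrt(x.size)) if x.size > 1 else np.nan


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def _stage_behavior(cfg: ExperimentConfig):
    frames = []
    for g in GROUPS:
        sim = _group_cfg(cfg, g)
        logs = {}
        for d in range(cfg.n_dams_per_group):
            log, _ = gen_behavior_log(sim, rng=_rng_for(cfg, g, "behavior", d))
            logs[f"{g}_dam{d:02d}"] = log
        tab = bhv.metrics_table(logs)
        tab.insert(1, "group", g)
        frames.append(tab)
    metrics = pd.concat(frames, ignore_index=True)
    v = metrics[metrics["group"] == "vehicle"]
    p = metrics[metrics["group"] == "polyic"]
    rows = []
    for metric, test in (
            ("latency_all_s", "t"),
            ("relative_failure_index", "t"),
            ("rearing_first_min", "t"),
            ("sniffs_first_30s", "mw"),
            ("pct_retrieved_60s", "mw")):
        a, b = v[metric].to_numpy(float), p[metric].to_numpy(float)
        res = stats.t_test(a, b) if test == "t" else stats.mann_whitney_u(a, b)
        rows.append(_summ_row("retrieval_assay", metric, a, b, res))
    return {"behavior_metrics": metrics}, rows


def _stage_ephys(cfg: ExperimentConfig):
    unit_rows, epoch_frames = [], []
    for g in GROUPS:
        sim = _group_cfg(cfg, g)
        trains, truth = gen_spike_dataset(sim)
        windows = truth.windows
        base_iv = windows["baseline"][0]
        for tr in trains:
            tr.group = g
            fr = ephys.firing_rate(tr.spike_times, base_iv)
            width = ephys.spike_width(tr.waveform, tr.dt_us)
            uc = ephys.classify_unit(fr, width, tr.waveform, tr.dt_us)
            row = {"unit_id": f"{g}_{tr.unit_id}", "group": g,
                   "label": uc.label, "fr_baseline_hz": fr,
                   "width_ms": width, "bursting_pct": np.nan,
                   "spikes_per_burst": np.nan}
            if uc.label == "wide_spiking":
                bursts = ephys.detect_bursts(tr.spike_times)
                bs = ephys.burst_stats(bursts, tr.n_spikes)
                row["bursting_pct"] = bs.bursting_percent
                row["spikes_per_burst"] = bs.mean_spikes_per_burst
            unit_rows.append(row)
            if uc.label in ("narrow_spiking", "wide_spiking"):
                et = ephys.epoch_firing_table(tr, windows,
                                              formula=cfg.delta_fr_formula)
                et["unit_id"] = f"{g}_{tr.unit_id}"
                et["label"] = uc.label
                epoch_frames.append(et)
    units = pd.DataFrame(unit_rows)
    epochs = pd.concat(epoch_frames, ignore_index=True)
    rows = []
    for label, metric in (("narrow_spiking", "fr_baseline_hz"),
                          ("wide_spiking", "fr_baseline_hz"),
                          ("wide_spiking", "bursting_pct"),
                          ("wide_spiking", "spikes_per_burst")):
        sub = units[units["label"] == label]
        a = sub.loc[sub["group"] == "vehicle", metric].to_numpy(float)
        b = sub.loc[sub["group"] == "polyic", metric].to_numpy(float)
        res = stats.mann_whitney_u(a, b)
        rows.append(_summ_row(f"vta_{label}", metric, a, b, res))
    # ΔFR across behavioral epochs: split-plot with group between, epoch within
    for label in ("narrow_spiking", "wide_spiking"):
        sub = epochs[(epochs["label"] == label)
                     & (epochs["epoch"].isin(BEHAVIORAL_EPOCHS))
                     & epochs["delta_fr"].notna()]
        complete = sub.groupby("unit_id")["epoch"].nunique()
        sub = sub[sub["unit_id"].isin(
            complete[complete == len(BEHAVIORAL_EPOCHS)].index)]
        try:
            ma = stats.mixed_anova(sub, "delta_fr", between="group",
                                   within="epoch", subject="unit_id")
        except ValueError:
            continue
        a = sub.loc[sub["group"] == "vehicle", "delta_fr"]
        b = sub.loc[sub["group"] == "polyic", "delta_fr"]
        for eff in ("between", "interaction"):
            r = _summ_row(f"vta_{label}", f"delta_fr_{eff}", a, b, ma[eff])
            rows.append(r)
    return {"ephys_units": units, "ephys_epochs": epochs}, rows


def _stage_morphology(cfg: ExperimentConfig, radii_max_um: float = 160.0):
    met_rows, sholl_rows = [], []
    for g in GROUPS:
        sim = _group_cfg(cfg, g)
        for i in range(cfg.n_neurons_per_group):
            m, _ = gen_morphology(sim, rng=_rng_for(cfg, g, "morphology", i))
            dm = morphology.dendrite_metrics(m)
            nid = f"{g}_n{i:03d}"
            met_rows.append({"neuron_id": nid, "group": g,
                             "cumulative_length_um": dm.cumulative_length_um,
                             "n_branch_points": dm.n_branch_points,
                             "soma_area_um2": dm.soma_area_um2})
            prof = morphology.sholl(m)
            by_r = dict(zip(prof.radii_um, prof.intersections))
            for r in np.arange(20.0, radii_max_um + 1e-9, 20.0):
                sholl_rows.append({"neuron_id": nid, "group": g,
                                   "radius_um": r,
                                   "intersections": int(by_r.get(r, 0))})
    metrics = pd.DataFrame(met_rows)
    sholl_long = pd.DataFrame(sholl_rows)
    v = metrics[metrics["group"] == "vehicle"]
    p = metrics[metrics["group"] == "polyic"]
    rows = []
    for metric in ("cumulative_length_um", "n_branch_points",
                   "soma_area_um2"):
        a, b = v[metric].to_numpy(float), p[metric].to_numpy(float)
        rows.append(_summ_row("morphometry", metric, a, b,
                              stats.t_test(a, b)))
    ma = stats.mixed_anova(sholl_long, "intersections", between="group",
                           within="radius_um", subject="neuron_id",
                           log_transform=True)
    a = sholl_long.loc[sholl_long["group"] == "vehicle", "intersections"]
    b = sholl_long.loc[sholl_long["group"] == "polyic", "intersections"]
    rows.append(_summ_row("morphometry", "sholl_treatment_effect", a, b,
                          ma["between"]))
    return {"morpho_metrics": metrics, "sholl_long": sholl_long}, rows


def _stage_usv(cfg: ExperimentConfig):
    frames, litter_frames = [], []
    for g in GROUPS:
        sim = _group_cfg(cfg, g)
        calls, _ = gen_usv_calls(sim, rng=_rng_for(cfg, g, "usv", 0),
                                 n_litters=cfg.n_litters_per_group)
        for c in calls:
            c.litter_id = f"{g}_{c.litter_id}"
        tab = usv.call_table(calls)
        tab.insert(1, "group", g)
        frames.append(tab)
        ls = usv.litter_summary(calls)
        ls.insert(1, "group", g)
        litter_frames.append(ls)
    calls_tab = pd.concat(frames, ignore_index=True)
    litter = pd.concat(litter_frames, ignore_index=True)
    rows = []
    v = litter[litter["group"] == "vehicle"]
    p = litter[litter["group"] == "polyic"]
    a = v.groupby("litter_id")["n_calls"].sum().to_numpy(float)
    b = p.groupby("litter_id")["n_calls"].sum().to_numpy(float)
    rows.append(_summ_row("usv", "calls_per_litter", a, b,
                          stats.mann_whitney_u(a, b)))
    for cat in ("flat", "chevron"):
        a = v.loc[v["category"] == cat, "mean_duration_s"].dropna()
        b = p.loc[p["category"] == cat, "mean_duration_s"].dropna()
        if len(a) > 1 and len(b) > 1:
            rows.append(_summ_row("usv", f"{cat}_duration_s", a, b,
                                  stats.mann_whitney_u(a, b)))
    return {"usv_calls": calls_tab, "usv_litter": litter}, rows


def _stage_quantification(cfg: ExperimentConfig):
    per_animal_frames = []
    for g in GROUPS:
        sim = _group_cfg(cfg, g)
        for roi, effect_on in (("mPOA", True), ("vBNST", False)):
            p_cfos = sim.p_cfos if effect_on else cfg.base.p_cfos
            tab, _ = gen_cell_table(
                sim, roi=roi, rng=_rng_for(cfg, g, "cells",
                                           0 if effect_on else 1),
                p_cfos=p_cfos, group=f"{g}_")
            mf = quantification.marker_fractions(tab, roi)
            pa = mf.per_animal.copy()
            pa.insert(1, "group", g)
            pa.insert(2, "roi", roi)
            per_animal_frames.append(pa)
    per_animal = pd.concat(per_animal_frames, ignore_index=True)
    rows = []
    for roi in ("mPOA", "vBNST"):
        sub = per_animal[per_animal["roi"] == roi]
        for metric in ("frac_cfos_in_gal", "frac_gal_per_dapi"):
            a = sub.loc[sub["group"] == "vehicle", metric].to_numpy(float)
            b = sub.loc[sub["group"] == "polyic", metric].to_numpy(float)
            rows.append(_summ_row(f"cfos_{roi}", metric, a, b,
                                  stats.t_test(a, b)))
    counts, meta, _ = gen_expression(
        cfg.base.replace(seed=cfg.seed % 2 ** 31))
    dot = quantification.dotplot_summary(counts, meta, cfg.base.gene_panel)
    return {"quant_cfos": per_animal, "dotplot": dot}, rows


# ---------------------------------------------------------------------------

def run_experiment(cfg: ExperimentConfig, out_dir=None,
                   stages=ALL_STAGES) -> ExperimentReport:
    """Run the selected stages and assemble the report.

    Each stage writes its tidy tables under ``out_dir`` (if given); the
    summary table mirrors the figure-panel comparisons (group mean ± SEM,
    test, statistic, p).  A log file records the seed and every resolved
    decision parameter.
    """
    stage_funcs = {"behavior": _stage_behavior, "ephys": _stage_ephys,
                   "morphology": _stage_morphology, "usv": _stage_usv,
                   "quantification": _stage_quantification}
    tables: dict = {}
    summary_rows: list = []
    for name in stages:
        try:
            t, rows = stage_funcs[name](cfg)
        except Exception as e:
            raise RuntimeError(f"pipeline stage {name!r} failed: {e}") from e
        tables.update(t)
        summary_rows.extend(rows)
    summary = pd.DataFrame(summary_rows)
    log = {
        "seed": cfg.seed,
        "groups": list(GROUPS),
        "effects": cfg.effects,
        "n_dams_per_group": cfg.n_dams_per_group,
        "n_units_per_class": cfg.n_units_per_class,
        "assay": {"test_duration_s": cfg.base.test_duration_s,
                  "n_pups": cfg.base.n_pups,
                  "baseline_s": cfg.base.baseline_duration_s,
                  "assay_s": cfg.base.assay_duration_s},
        "decision_parameters": {
            "fast_fr_hz": ephys.FAST_FIRING_FR_HZ,
            "narrow_width_ms": ephys.NARROW_WIDTH_MS,
            "wide_width_ms": ephys.WIDE_WIDTH_MS,
            "burst_isi_max_s": ephys.BURST_ISI_MAX_S,
            "burst_span_max_s": ephys.BURST_SPAN_MAX_S,
            "delta_fr_formula": cfg.delta_fr_formula,
            "usv_thresholds": dataclasses.asdict(usv.USVThresholds()),
            "spine_thresholds": dataclasses.asdict(
                morphology.SpineThresholds()),
            "sholl_step_um": 20.0,
            "failure_index_mode": "relative",
        },
    }
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name, df in tables.items():
            df.to_csv(out / f"{name}.csv", index=False)
        summary.to_csv(out / "summary.csv", index=False)
        with open(out / "log.json", "w") as fh:
            json.dump(log, fh, indent=2, default=str)
    return ExperimentReport(tables=tables, summary=summary, log=log)
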