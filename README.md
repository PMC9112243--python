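# matcare

Analysis toolkit for the quantitative chain of a maternal-care study in a
gestational immune-activation (viral-mimic, Poly I:C) mouse model: scoring
of the pup-retrieval assay, pup ultrasonic-vocalization (USV) call
classification, dendritic morphometry of preoptic and midbrain neurons,
single-unit analysis of ventral tegmental area (VTA) recordings,
marker-fraction quantification of c-Fos histochemistry, cluster-level
expression dot plots, and the matching statistical layer — all exercised
end to end on synthetic data with known ground truth.

## Who this is for

Behavioral and systems neuroscientists who need the scoring and
classification rules of this assay family as tested, reusable code rather
than spreadsheet conventions: what counts as a failed approach, how a
"full AP width" is measured on a mean waveform, what the burst rule is,
how Sholl intersections are counted, and which test is applied where.
Every analysis step has an independent oracle or a generator whose ground
truth it must recover exactly.

## The rules at the core

* **Retrieval scoring.** A 300-s test with 4 pups. Latency to retrieve
  all pups (censored at 300 s), cumulative percent retrieved as a
  right-continuous step function, and the *relative failure index*
  (failures + drops) / (failures + drops + retrieves) ∈ [0, 1]. Rearing
  is counted in [0, 60 s), sniffing in [0, 30 s).
* **Unit classification.** Baseline firing rate FR over a 10-min
  baseline; FR > 10 Hz → fast-firing. Slow units split on full AP width
  (time between the outermost crossings of 10 % of the peak amplitude on
  the mean waveform): < 1.2 ms narrow-spiking (putative GABAergic),
  > 1.4 ms wide-spiking (putative dopaminergic). Widths in the
  1.2–1.4 ms dead zone go wide only when the waveform carries a deep
  (> 20 % of peak), long (≥ 0.3 ms) undershoot; otherwise the unit is
  excluded.
* **Bursts.** A burst is ≥ 2 spikes with consecutive inter-spike
  intervals < 80 ms and total span ≤ 160 ms, detected by a greedy
  left-to-right scan; bursting % is the percent of a unit's spikes inside
  bursts.
* **Epoch firing.** ΔFR = (FR_epoch − FR_baseline) / (FR_epoch +
  FR_baseline), a symmetric contrast bounded in [−1, 1], pooled per unit
  over each behavioral epoch (approach, retrieval, post-interaction).
* **USV categories.** Each call's frequency contour is assigned exactly
  one of short / flat / chevron / complex / upward / downward through a
  decision tree on duration, total modulation, smoothed-contour direction
  reversals and net frequency change (defaults: 5 ms, 3 kHz, 6 kHz,
  3-point median smoothing with 1-kHz hysteresis; all configurable).
* **Morphometry.** Sholl intersections as edge straddles of concentric
  20-µm shells centred on the soma; cumulative dendritic length;
  branch-point count; soma area; five-class spine typing (stubby /
  mushroom / thin / long thin / filopodia) via an ordered threshold tree.
* **Quantification.** c-Fos⁺/Gal⁺ and Gal⁺/DAPI fractions aggregated
  image → animal → group; dot-plot summaries (fraction expressing, mean
  ln(1 + 10⁴·count/total) expression, z-scaled across groups) per gene ×
  cluster (i8/i16/i18) × sex, sexes analyzed separately.
* **Statistics.** Mann–Whitney U (exact by enumeration for
  n₁+n₂ ≤ 12), Welch/Student t, Spearman (exact permutation p for
  n ≤ 8), two-way ANOVA (Type-II SS), mixed split-plot ANOVA (optionally
  on log10(x+1), with Greenhouse–Geisser-corrected p), and Grubbs outlier
  screening at α = 0.05.

## Worked example

`analysis/` holds the numbered end-to-end drivers; each regenerates its
cohorts from a seed and writes tidy tables under `results/`. Scoring the
retrieval assay for 16 dams per group (treated group: failure probability
0.45 vs 0.15, more rearing):

```
$ python analysis/02_score_behavior.py
          panel                 metric  vehicle_mean  ...  polyic_mean  ...        test  statistic        p
retrieval_assay          latency_all_s     98.846337  ...   150.503129  ...      t_test  -2.086971 0.048440
retrieval_assay relative_failure_index      0.126786  ...     0.326281  ...      t_test  -2.685058 0.012599
retrieval_assay      rearing_first_min      3.250000  ...     5.500000  ...      t_test  -3.000000 0.006350
retrieval_assay       sniffs_first_30s      5.187500  ...     5.625000  ...  mann_whitney_u 118.5    0.729525
...
significant at p<0.05: ['latency_all_s', 'relative_failure_index', 'rearing_first_min']
```

Treated dams take ~50 s longer to collect all pups, fail a 2.6× larger
fraction of approaches, and rear more — while sniffing (pup detection) is
unchanged. `analysis/03_classify_units.py` does the same for the
electrophysiology: narrow-spiking baseline FR 6.01 → 9.05 Hz (U = 0,
p < 10⁻⁷) and wide-spiking FR 3.14 → 2.26 Hz under the configured
+50 % / −30 % rate effects, with spikes/burst unchanged.
`analysis/07_full_experiment.py` runs all five stages and writes the full
report bundle (per-stage tables, `summary.csv`, `log.json` with every
resolved decision parameter) under `results/experiment/`.

The same machinery is scriptable via the CLI: `matcare run --seed 1 --out
DIR`, plus per-module subcommands (`matcare ephys classify`, `matcare
behavior`, `matcare usv`, `matcare morpho sholl`, `matcare quant cfos`,
`matcare stats`).

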