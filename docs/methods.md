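# Methods

This note documents the models and procedural decisions behind each
module: what is computed, which parameters matter, what the synthetic
data emulate and what they do not, and where the design was genuinely
open.

## Behavioral scoring

A retrieval assay is a time-sorted event log over a 300-s test with 4
pups. All windows are half-open `[start, end)`; an event exactly at a
window boundary belongs to the later window. The *relative failure
index* is normalized by all pup-directed outcomes, failures / (failures +
retrieves): this bounds it in [0, 1], is invariant to rearing/sniffing
events and to event reordering at equal timestamps, and preserves the
ordering "more failed approaches → higher index". A raw failure count is
available via `mode="raw"` for sensitivity analyses. Latencies censored
at the 300-s cutoff enter group tests at 300 s with the censoring flag
retained; this matches the common treatment of the 5-min cutoff and
avoids discarding the slowest dams. Drops count once per drop event even
if the pup is later retrieved.

## Spike-train analysis

**Firing rate** is a count over a half-open interval divided by its
length; per-epoch rates pool all of an epoch's intervals (total spikes /
total duration) rather than averaging per-event rates, so short events do
not receive outsized weight.

**Full AP width** is not a standardized quantity; here it is the time
between the first and last crossing of 10 % of the peak absolute
amplitude of the mean waveform, linearly interpolated between samples.
This definition is amplitude-invariant, monotone in template width,
robust to modest noise, and deliberately spans the whole AP complex —
including the slow after-hyperpolarization lobe that makes putative
dopaminergic waveforms wide. The threshold fraction is configurable.

**Classification** applies the rate rule first (FR > 10 Hz fast-firing;
exactly 10 Hz is treated as slow), then the width cutoffs 1.2 / 1.4 ms.
The dead zone between the cutoffs is resolved by a waveform signature:
assign wide when a post-peak excursion opposite in sign to the main peak
exceeds 20 % of the peak amplitude for at least 0.3 ms (the "large
negative undershoot" of dopaminergic units); otherwise exclude the unit.
Both parameters are exposed. Dead-zone units are never assigned narrow.

**Burst detection** is a greedy left-to-right scan: a burst opens at the
first unused spike whose next ISI is < 80 ms and extends while the next
ISI stays < 80 ms *and* the total span stays ≤ 160 ms; scanning resumes
after the burst's last spike, so bursts are disjoint. A spike that would
stretch the span past 160 ms starts a fresh candidate pair only after the
current burst closes. This greedy rule is exactly equivalent to taking
maximal valid runs left-to-right (verified against exhaustive enumeration
in the tests). Bursting % is the percent of a unit's spikes inside
bursts — a per-unit scalar, not the fraction of units that burst.

**ΔFR** uses the symmetric contrast (a − b)/(a + b): bounded in
[−1, 1], zero iff no change, antisymmetric under swapping epoch and
baseline. The alternatives a/b and (a − b)/b are selectable by
configuration. When both rates are zero the index is undefined and the
record is flagged and excluded.

## USV classification

Calls are processed at the contour level (peak frequency per time bin
plus linear amplitude); detection/segmentation from audio is upstream and
out of scope. The six-way decision tree runs in a fixed order — short
(duration < 5 ms), flat (total modulation < 3 kHz), complex (≥ 2
direction reversals), chevron (exactly 1 reversal through an interior
maximum), upward / downward (net change beyond ±6 kHz), flat fallback —
so every call receives exactly one label. Reversals are counted on a
3-point moving-median smoothed contour with a 1-kHz hysteresis band;
without smoothing and hysteresis, bin-to-bin jitter inflates the complex
category. The frequency at maximum peak takes the earliest time on
amplitude ties. Classification is invariant to uniform time shifts and
amplitude rescaling. All thresholds are configurable; the defaults
follow common rodent-call classification conventions and recover ≥ 95 %
of archetype-generated calls per category.

## Morphometry

Trees use SWC semantics (single soma root, parent precedes child, 3-D
coordinates in µm). Sholl intersections are counted as *edge straddles*:
an edge contributes one intersection at radius r when its endpoints'
distances from the soma centroid lie on opposite sides of r; an endpoint
exactly on a shell counts as crossing (a deterministic boundary rule). A
curved path that dips across a shell inside a single straight edge is
therefore counted once per straddling edge — the resolution of the
reconstruction defines the resolution of the profile. Shells run 20,
40, 60 … µm out to the farthest node. Distances are 3-D even though
camera-lucida material is quasi-2-D (z may be zero-filled). Branch
points are non-soma nodes with ≥ 2 children; stems leaving the soma do
not count. Soma area uses the shoelace formula on the soma outline
polygon when one is present, else π r² of the root radius. Sholl group
statistics use log10(count + 1), which is defined at the zero counts
that occur at large radii. Spine typing is an ordered threshold tree
(length > 2 µm filopodia; head width > 0.6 µm mushroom; length below the
largest width stubby; length > 1 µm long thin; else thin) that
partitions the (L, HW, NW) space at any threshold setting.

## Quantification

Marker fractions aggregate unweighted at each level of the hierarchy
image → animal → group (one image per hemisphere, two sections per
brain), so animals with unequal cell counts are weighted equally; with
balanced sections this equals pooled counting. "Expressing" in the
dot-plot summary means raw count > 0 (configurable threshold); the mean
expression is ln(1 + 10⁴·count/cell-total) computed against each cell's
*full* library, and the display scaling is a per-gene z-score across the
cluster × sex groups (0 for a flat gene). Sexes are never pooled.
Missing panel genes raise an error rather than being dropped silently.

## Statistics

* Mann–Whitney U reports U = min(Uₓ, U_y). For n₁+n₂ ≤ 12 the two-sided
  p is exact by enumerating all C(n₁+n₂, n₁) group labelings of the
  pooled mid-ranks (ties handled naturally); larger samples use the
  normal approximation with tie and continuity correction. The two
  branches agree to well under 0.02 in p at the crossover size.
* The t test is Welch by default (fractional df), matching the
  fractional degrees of freedom this assay family reports.
* Spearman rho is the Pearson correlation of mid-ranks; p is exact by
  full permutation for n ≤ 8, t-approximate beyond.
* Two-way ANOVA uses Type-II sums of squares, appropriate for the
  unequal group sizes (4–6 animals) typical of these cohorts.
* The mixed (split-plot) ANOVA tests the between factor over the
  subject-within-group error and the within/interaction terms over the
  subject × within error; it requires complete profiles (no imputation)
  and reports a Greenhouse–Geisser-corrected p alongside the uncorrected
  one, since sphericity is rarely credible for Sholl radii.
* Grubbs screening compares G = max|xᵢ − x̄|/s with the closed-form
  critical value ((n−1)/√n)·√(t²/(n−2+t²)), t = t₁₋α/(2n),n₋₂, at
  α = 0.05; only the single most extreme point is tested per round, with
  optional iterative re-testing.
* All p values are two-sided; no multiple-testing correction is applied
  anywhere (none is part of the emulated design), and each result's
  metadata records this.

## Synthetic data: what it emulates, and what it does not

The generators reproduce the study's assay constants: a 600-s baseline
followed by a 900-s retrieval assay with 4 pups; a 300-s scored
retrieval test; unit classes with width modes 0.9 ± 0.05 ms and
1.6 ± 0.05 ms around the 1.2/1.4-ms cutoffs; rate classes 6 / 3 / 15 Hz
(narrow / wide / fast). One global seed fans out into fixed named
substreams, so adding or re-running one generator never perturbs
another's draws, and identical seeds give bit-identical output.

Within a class all units share the class rate (an optional lognormal
spread is available behind `fr_cv`). Narrow and fast units are
homogeneous Poisson within each epoch segment, with behavioral epochs
rescaling the rate multiplicatively. Wide units' tonic process carries
an 80-ms dead time (rate-compensated so the mean FR still matches the
configured rate): with pure Poisson tonic firing, chance sub-80-ms ISIs
would create bursts the ground truth does not know about, and
burst-recovery could never be exact. Injected bursts (2–5 spikes at
20-ms spacing) are cleared of tonic spikes and of each other by more
than the ISI threshold, making every injected burst exactly one detected
burst. A consequence worth noting: rate effects on wide units change
bursting % through its denominator (total spikes) even when the burst
process is untouched.

Waveform templates are closed-form (Gaussian lobes) with the 10 %-width
placed analytically, so the width measurement can be validated against
the requested width without fitting; wide templates carry a −0.4-peak,
0.25-ms-σ undershoot that also satisfies the dead-zone signature. USV
archetypes are parametric contours with 200-Hz jitter. Dendritic trees
are random binary trees with jittered segment lengths and directions (or
deterministic radial binary trees for closed-form checks). Cell tables
and count matrices draw Bernoulli marker flags and negative-binomial
counts per (gene, cluster, sex), with filler housekeeping genes
guaranteeing nonzero library sizes.

None of this emulates the hard parts of real data: spike-sorting errors
and drift, electrode loss, waveform non-stationarity, observer scoring
noise, reconstruction artifacts, segmentation errors, doublets or
ambient RNA. Passing tests therefore demonstrate that the *analysis
rules* are implemented exactly and are well calibrated — not that the
pipeline is robust to upstream measurement error.

## Pipeline and validation sizes

The end-to-end experiment compares a vehicle and a treated cohort
sharing all assay constants, with treated-group effects applied as
multiplicative gains (defaults: narrow FR ×1.5, wide FR ×0.7, failure
probability 0.15 → 0.45, rearing ×1.6, branch length ×0.85, c-Fos
probability 0.40 → 0.25). Ephys group tests are per unit (N = neurons
per group), the design this assay family tests at; per-animal
aggregation is available by configuration. Summaries report mean ± SEM.
The report bundle is byte-identical for identical seeds, and its values
equal those obtained by invoking each module independently on the same
intermediates (no hidden state).

Validation sizes: burst-oracle agreement on 1,000 random trains of up to
50 spikes; Sholl-oracle agreement on 200 random trees; behavior
ground-truth agreement on 500 random logs; 500 calls per USV category;
type-I calibration over 2,000 null simulations per test (acceptance
script: 1,000); end-to-end power over 200 replicates (script: 100) at
n = 20 units and 16 dams per group. These sizes make the full validation
run in a few minutes on one CPU while keeping every binomial check's
3-SE band tight enough to be informative.
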