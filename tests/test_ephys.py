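"""Unit tests for spike-train analysis: rates, widths, classes, bursts."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst

from matcare import ephys
from matcare.ephys import (Burst, EpochWindows, SpikeTrain, burst_stats,
                           classify_unit, delta_fr, detect_bursts,
                           epoch_firing_table, firing_rate, spike_width)
from matcare.simulate import make_waveform

from oracles import bursts_by_enumeration


# ---------------------------------------------------------------------------
# firing rate
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("times, interval, expected", [
    (np.linspace(0, 1.8, 10), (0.0, 2.0), 5.0),     # 10 spikes in 2 s
    ([], (0.0, 2.0), 0.0),
    ([2.0], (0.0, 2.0), 0.0),                       # end boundary excluded
    ([0.0, 1.0], (0.0, 2.0), 1.0),                  # start boundary included
])
def test_firing_rate_half_open(times, interval, expected):
    assert firing_rate(np.asarray(times, float), interval) == expected


def test_firing_rate_rejects_empty_interval():
    with pytest.raises(ValueError):
        firing_rate(np.array([0.1]), (1.0, 1.0))


# ---------------------------------------------------------------------------
# spike width
# ---------------------------------------------------------------------------

def test_spike_width_triangle_closed_form():
    """A symmetric triangular pulse of base 1.0 ms has 10 %-crossing width
    0.9 ms by similar triangles."""
    dt_us = 10.0
    n_half = 50                                      # 0.5 ms rise and fall
    tri = np.r_[np.zeros(20), np.linspace(0, 1, n_half + 1),
                np.linspace(1, 0, n_half + 1)[1:], np.zeros(20)]
    w = spike_width(tri, dt_us)
    assert w == pytest.approx(0.9, abs=1e-9)


def test_spike_width_amplitude_invariance():
    wf = make_waveform(1.1, "narrow")
    w0 = spike_width(wf, 25.0)
    for s in (0.3, 7.0, 1234.5):
        assert spike_width(s * wf, 25.0) == pytest.approx(w0, abs=1e-12)


@pytest.mark.parametrize("klass, width", [
    ("narrow", 0.8), ("narrow", 0.95), ("narrow", 1.3),
    ("wide", 1.45), ("wide", 1.6), ("wide", 1.75), ("fast", 0.8),
])
def test_spike_width_matches_template_request(klass, width):
    """Measured width agrees with the requested template width to within
    one sample interval."""
    dt_us = 25.0
    wf = make_waveform(width, klass, dt_us=dt_us)
    assert spike_width(wf, dt_us) == pytest.approx(width, abs=dt_us / 1000.0)


def test_spike_width_flat_waveform_errors():
    with pytest.raises(ValueError):
        spike_width(np.ones(32), 25.0)


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------

def test_classify_fr_rule_takes_precedence():
    assert classify_unit(12.0, 0.8).label == "fast_firing"


@pytest.mark.parametrize("fr, width, expected", [
    (6.0, 0.8, "narrow_spiking"),
    (6.0, 1.19, "narrow_spiking"),
    (6.0, 1.6, "wide_spiking"),
    (6.0, 1.41, "wide_spiking"),
])
def test_classify_width_rule(fr, width, expected):
    assert classify_unit(fr, width).label == expected


def test_dead_zone_resolution_by_undershoot():
    """1.2-1.4 ms units go wide only with a deep, long undershoot;
    otherwise they are excluded, never assigned narrow."""
    wf_plain = make_waveform(1.3, "narrow")          # no undershoot
    wf_under = make_waveform(1.3, "wide")            # -0.4 peak undershoot
    assert classify_unit(6.0, 1.3, wf_plain, 25.0).label \
        == "ambiguous_excluded"
    assert classify_unit(6.0, 1.3, wf_under, 25.0).label == "wide_spiking"
    assert classify_unit(6.0, 1.3).label == "ambiguous_excluded"


def test_classification_scale_invariant_and_deterministic():
    wf = make_waveform(1.3, "wide")
    labels = {classify_unit(6.0, 1.3, s * wf, 25.0).label
              for s in (0.1, 1.0, 42.0)}
    assert labels == {"wide_spiking"}


# ---------------------------------------------------------------------------
# bursts
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("times_ms, expected_bursts", [
    ([0, 50, 120, 500], [(0, 1, 2)]),
    ([0, 90, 200], []),
    ([0, 70, 140, 210], [(0, 1, 2)]),     # 210 would stretch span past 160
    ([0, 79.9], [(0, 1)]),
    ([0, 80], []),                        # ISI exactly 80 ms: not a burst
])
def test_detect_bursts_rule(times_ms, expected_bursts):
    t = np.asarray(times_ms, float) / 1000.0
    got = [b.spike_indices for b in detect_bursts(t)]
    assert got == expected_bursts


def test_burst_duration_and_disjointness_invariants(rng):
    t = np.sort(rng.uniform(0, 3.0, 60))
    t = t[np.r_[True, np.diff(t) > 0]]
    bursts = detect_bursts(t)
    used = set()
    for b in bursts:
        assert len(b.spike_indices) >= 2
        assert b.duration_ms <= 160.0 + 1e-9
        isis = np.diff(t[list(b.spike_indices)])
        assert np.all(isis < 0.080)
        assert used.isdisjoint(b.spike_indices)
        used.update(b.spike_indices)


def test_detect_bursts_matches_enumeration_oracle(rng):
    """Greedy detector equals the exhaustive maximal-run oracle on random
    trains mixing bursty and tonic ISI regimes."""
    for _ in range(300):
        n = rng.integers(2, 50)
        isis = np.where(rng.random(n) < 0.4,
                        rng.exponential(0.03, n),
                        rng.exponential(0.25, n))
        t = np.cumsum(isis)
        got = [b.spike_indices for b in detect_bursts(t)]
        assert got == bursts_by_enumeration(t)


def test_detect_bursts_rejects_unsorted():
    with pytest.raises(ValueError):
        detect_bursts(np.array([0.2, 0.1]))


def test_burst_stats_examples():
    bursts = detect_bursts(np.array([0.0, 0.05, 0.12, 0.5]))
    bs = burst_stats(bursts, 4)
    assert bs.bursting_percent == pytest.approx(75.0)
    assert bs.mean_spikes_per_burst == pytest.approx(3.0)
    empty = burst_stats([], 10)
    assert empty.bursting_percent == 0.0
    assert empty.mean_spikes_per_burst == 0.0
    assert not empty.has_bursts


# ---------------------------------------------------------------------------
# delta FR
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("a, b, expected", [
    (6.0, 4.0, 0.2), (4.0, 4.0, 0.0), (0.0, 5.0, -1.0), (5.0, 0.0, 1.0),
])
def test_delta_fr_contrast_values(a, b, expected):
    assert delta_fr(a, b) == pytest.approx(expected)


def test_delta_fr_both_zero_is_nan():
    assert np.isnan(delta_fr(0.0, 0.0))


@settings(deadline=None, max_examples=200)
@given(a=hst.floats(0, 1e3), b=hst.floats(0, 1e3))
def test_delta_fr_bounded_and_antisymmetric(a, b):
    if a == 0 and b == 0:
        return
    d = delta_fr(a, b)
    assert -1.0 <= d <= 1.0
    assert d == pytest.approx(-delta_fr(b, a), abs=1e-12)
    if a == b:
        assert d == 0.0


# ---------------------------------------------------------------------------
# epoch firing tables
# ---------------------------------------------------------------------------

def _toy_train():
    t = np.sort(np.unique(np.random.default_rng(0).uniform(0, 100, 400)))
    wf = make_waveform(0.9, "narrow")
    return SpikeTrain(unit_id="u0", spike_times=t, waveform=wf, dt_us=25.0)


def test_epoch_table_single_interval_equals_firing_rate():
    tr = _toy_train()
    w = EpochWindows({"baseline": [(0.0, 50.0)], "approach": [(50.0, 80.0)]})
    tab = epoch_firing_table(tr, w).set_index("epoch")
    assert tab.loc["approach", "fr_hz"] == pytest.approx(
        firing_rate(tr.spike_times, (50.0, 80.0)))


def test_epoch_table_pooling_additivity():
    """Splitting an epoch interval in two leaves the pooled FR unchanged."""
    tr = _toy_train()
    w1 = EpochWindows({"baseline": [(0.0, 50.0)], "retrieval": [(50.0, 90.0)]})
    w2 = EpochWindows({"baseline": [(0.0, 50.0)],
                       "retrieval": [(50.0, 64.0), (64.0, 90.0)]})
    t1 = epoch_firing_table(tr, w1).set_index("epoch")
    t2 = epoch_firing_table(tr, w2).set_index("epoch")
    assert t1.loc["retrieval", "fr_hz"] == pytest.approx(
        t2.loc["retrieval", "fr_hz"])


def test_epoch_table_spike_conservation():
    tr = _toy_train()
    w = EpochWindows({"baseline": [(0.0, 50.0)], "approach": [(50.0, 70.0)],
                      "retrieval": [(70.0, 90.0)],
                      "post_interaction": [(90.0, 100.0)]})
    tab = epoch_firing_table(tr, w)
    assert tab["n_spikes"].sum() == tr.n_spikes


def test_epoch_windows_validation():
    with pytest.raises(ValueError):
        EpochWindows({"baseline": [(0.0, 10.0), (5.0, 20.0)]})
    with pytest.raises(ValueError):
        EpochWindows({"baseline": [(100.0, 200.0)],
                      "approach": [(50.0, 60.0)]})


def test_spike_train_validation():
    wf = make_waveform(0.9, "narrow")
    with pytest.raises(ValueError):
        SpikeTrain("u", np.array([0.2, 0.1]), wf, 25.0)
    with pytest.raises(ValueError):
        SpikeTrain("u", np.array([0.1, 0.2]), np.ones(4), 25.0)
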