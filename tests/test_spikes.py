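import numpy as np
import pandas as pd
import pytest

from axinit.spikes import (
    LatencyProfile,
    SpikeEvent,
    detect_spikes,
    initiation_site,
    latency_profile,
    latency_shift_regression,
    propagation_fidelity,
    spiking_threshold,
    trace_latency_profile,
    waveform_change_vs_distance,
)


def _spike_waveform(t, center, amp=100.0, width=0.4, base=-75.0):
    """A smooth spike-like bump; its dV/dt maximum sits at center − width/√…"""
    return base + amp * np.exp(-((t - center) ** 2) / (2.0 * width**2))


# ---------------------------------------------------------------------------
# detection
# ---------------------------------------------------------------------------


def test_flat_trace_yields_no_events():
    t = np.arange(0.0, 100.0, 0.05)
    assert detect_spikes(t, np.full_like(t, -75.0)) == []


def test_constructed_spike_onset_recovered_within_one_sample():
    """For a Gaussian spike the dV/dt maximum is exactly one width below the
    center; the detector must recover it to sub-sample accuracy."""
    dt = 0.05
    t = np.arange(0.0, 50.0, dt)
    center, width = 25.0, 0.4
    v = _spike_waveform(t, center, width=width)
    events = detect_spikes(t, v)
    assert len(events) == 1
    expected_onset = center - width  # inflection of a Gaussian
    assert events[0].onset_time == pytest.approx(expected_onset, abs=dt)
    assert events[0].peak_time == pytest.approx(center, abs=dt)
    assert events[0].peak_amplitude == pytest.approx(100.0, rel=0.01)


def test_two_spikes_separated_by_refractory():
    dt = 0.05
    t = np.arange(0.0, 100.0, dt)
    v = _spike_waveform(t, 30.0) + _spike_waveform(t, 60.0) + 75.0
    events = detect_spikes(t, v)
    assert len(events) == 2
    assert [e.index for e in events] == [0, 1]


def test_nonuniform_sampling_rejected():
    t = np.array([0.0, 0.1, 0.3, 0.35, 0.6])
    with pytest.raises(ValueError, match="uniform"):
        detect_spikes(t, np.zeros_like(t))


# ---------------------------------------------------------------------------
# latency
# ---------------------------------------------------------------------------


def test_latency_zero_for_identical_traces():
    dt = 0.05
    t = np.arange(0.0, 50.0, dt)
    v = _spike_waveform(t, 25.0)
    prof = latency_profile(t, v, {10.0: v.copy()})
    assert len(prof) == 1
    assert prof.records.latency_us.iloc[0] == pytest.approx(0.0, abs=1.0)


def test_latency_matches_kinematic_line():
    """With a constant conduction velocity beyond the initiation site, the
    latency grows linearly with |x − x₀|/v."""
    dt = 0.02
    t = np.arange(0.0, 60.0, dt)
    x0, v_cond = 25.0, 200.0  # µm, µm/ms
    t_soma = 30.0 + x0 / v_cond
    soma = _spike_waveform(t, t_soma)
    axon = {}
    for x in (50.0, 100.0, 200.0, 400.0):
        axon[x] = _spike_waveform(t, 30.0 + abs(x - x0) / v_cond)
    prof = latency_profile(t, soma, axon)
    for x, rec in zip(sorted(axon), prof.records.latency_us):
        expected_us = 1000.0 * ((abs(x - x0) - x0) / v_cond)
        assert rec == pytest.approx(expected_us, abs=2.0)


def test_mismatched_spike_counts_drop_records(caplog):
    dt = 0.05
    t = np.arange(0.0, 120.0, dt)
    soma = _spike_waveform(t, 30.0) + _spike_waveform(t, 80.0) + 75.0
    axon = {15.0: _spike_waveform(t, 30.2)}
    prof = latency_profile(t, soma, axon, spike_indices=(0, 1))
    assert len(prof) == 1  # index 1 missing at the axonal site


def test_model_latency_minimum_at_initiation_site(step_trace):
    """The latency-curve minimum and the earliest-onset compartment are two
    views of the same thing and must agree within one compartment length."""
    prof = trace_latency_profile(step_trace, (0,))
    s = prof.summary()
    lat_min_x = float(s.distance_um[s.mean_us.idxmin()])
    site = initiation_site(step_trace, 0)
    assert abs(lat_min_x - site) <= 2.5
    assert 20.0 <= lat_min_x <= 25.0


def test_initiation_site_shifts_distally_under_depolarized_spiking(step_trace):
    """Under depolarization-driven spiking the third spike initiates strictly
    more distally than the first (initiation-zone expansion)."""
    first = initiation_site(step_trace, 0)
    third = initiation_site(step_trace, 2)
    assert first <= 25.0
    assert third > first


def test_forced_spikes_at_rest_do_not_shift_the_site(spikes_only_trace):
    sites = [initiation_site(spikes_only_trace, si) for si in range(5)]
    assert max(sites) - min(sites) <= 2.5  # within one compartment


def test_initiation_site_follows_relocated_hotspot():
    """Moving the Na⁺ hotspot to 60 µm moves the first-spike initiation site
    with it (within the hotspot's width)."""
    from axinit.cable import SolverConfig, StimulusProtocol, run
    from axinit.morphology import GranuleCellParams, build_granule_cell

    m = build_granule_cell(GranuleCellParams(na_hotspot_center=60.0,
                                             na_axon_peak=0.6))
    proto = StimulusProtocol(kind="current_step", amplitude=130.0, onset=20.0,
                             duration=120.0)
    tr = run(m, proto, SolverConfig(duration=150.0))
    site = initiation_site(tr, 0)
    assert 45.0 <= site <= 75.0


def test_missing_spike_index_raises_with_sites(step_trace):
    with pytest.raises(ValueError, match="absent"):
        initiation_site(step_trace, 50)


# ---------------------------------------------------------------------------
# threshold
# ---------------------------------------------------------------------------


def test_threshold_crossing_recovers_takeoff_voltage():
    """A linear ramp ending in a sharp spike: the dV/dt-crossing criterion
    returns the takeoff voltage within a sample."""
    dt = 0.02
    t = np.arange(0.0, 60.0, dt)
    v_star = -50.0
    v = np.full_like(t, -75.0)
    ramp = (t >= 10.0) & (t < 50.0)
    v[ramp] = -75.0 + (t[ramp] - 10.0) * ((v_star + 75.0) / 40.0)  # 0.625 mV/ms
    v += _spike_waveform(t, 50.3, amp=90.0, width=0.3, base=0.0) * (t >= 49.0)
    est = spiking_threshold(t, v, criterion="dvdt_crossing")
    assert est.threshold == pytest.approx(v_star, abs=2.0)
    est2 = spiking_threshold(t, v, criterion="second_derivative_extremum")
    assert -76.0 < est2.threshold < 45.0  # between rest and peak


def test_threshold_requires_a_spike():
    t = np.arange(0.0, 50.0, 0.05)
    with pytest.raises(ValueError):
        spiking_threshold(t, np.full_like(t, -75.0))


# ---------------------------------------------------------------------------
# latency-shift regression
# ---------------------------------------------------------------------------


def _profile(rows):
    return LatencyProfile(pd.DataFrame(rows, columns=LatencyProfile.COLUMNS))


def test_zero_latency_change_gives_zero_slope_p_one():
    rows1 = [(x, 0, 100.0, 0) for x in (10.0, 50.0, 100.0, 150.0)]
    rows3 = [(x, 2, 100.0, 0) for x in (10.0, 50.0, 100.0, 150.0)]
    slope, stderr, p = latency_shift_regression(_profile(rows1), _profile(rows3))
    assert slope == 0.0 and p == pytest.approx(1.0)


def test_exact_line_recovers_slope_with_tiny_p():
    xs = np.linspace(10.0, 190.0, 10)
    rows1 = [(x, 0, 0.0, i) for i, x in enumerate(xs)]
    rows3 = [(x, 2, -2.0 * x, i) for i, x in enumerate(xs)]
    slope, stderr, p = latency_shift_regression(_profile(rows1), _profile(rows3))
    assert slope == pytest.approx(-2.0, rel=1e-9)
    assert p < 1e-12


def test_too_few_distances_rejected():
    rows = [(10.0, 0, 0.0, 0), (20.0, 0, 0.0, 1)]
    with pytest.raises(ValueError):
        latency_shift_regression(_profile(rows), _profile(rows))


# ---------------------------------------------------------------------------
# waveform statistics
# ---------------------------------------------------------------------------


def _events(dists, amps, rises):
    out = []
    for d, a, r in zip(dists, amps, rises):
        out.append(SpikeEvent(onset_time=1.0, peak_time=1.2, peak_amplitude=a,
                              max_dvdt=300.0, rise_time=r, index=0,
                              site_distance=d))
    return out


def test_identical_waveforms_give_zero_change_and_na_fit():
    d = np.linspace(10, 300, 8)
    e1 = _events(d, np.full(8, 90.0), np.full(8, 0.3))
    table, amp_fit, rise_fit = waveform_change_vs_distance(e1, _events(
        d, np.full(8, 90.0), np.full(8, 0.3)))
    assert np.allclose(table.amp_change_pct, 0.0)
    assert not amp_fit.applicable and not rise_fit.applicable


def test_exponential_decay_length_constant_recovered():
    """Changes decaying as exp(−x/50 µm), sampled noiselessly, recover
    λ = 50 µm within 1%."""
    d = np.linspace(5, 300, 10)
    amp1 = np.full(10, 100.0)
    change = 40.0 * np.exp(-d / 50.0)  # percent
    amp3 = amp1 * (1.0 - change / 100.0)
    rise1 = np.full(10, 0.30)
    rise3 = rise1 * (1.0 + change / 100.0)
    table, amp_fit, rise_fit = waveform_change_vs_distance(
        _events(d, amp1, rise1), _events(d, amp3, rise3))
    assert amp_fit.applicable and rise_fit.applicable
    assert amp_fit.length_constant == pytest.approx(50.0, rel=0.01)
    assert rise_fit.length_constant == pytest.approx(50.0, rel=0.01)


# ---------------------------------------------------------------------------
# propagation fidelity
# ---------------------------------------------------------------------------


def test_fidelity_identical_traces_is_one():
    dt = 0.05
    t = np.arange(0.0, 200.0, dt)
    v = sum(_spike_waveform(t, c, base=0.0) for c in (30.0, 80.0, 130.0)) - 75.0
    assert propagation_fidelity(t, v, v) == 1.0


def test_fidelity_halves_when_every_second_spike_deleted():
    dt = 0.05
    t = np.arange(0.0, 300.0, dt)
    centers = (30.0, 80.0, 130.0, 180.0)
    soma = sum(_spike_waveform(t, c, base=0.0) for c in centers) - 75.0
    axon = sum(_spike_waveform(t, c, base=0.0) for c in centers[::2]) - 75.0
    assert propagation_fidelity(t, soma, axon) == pytest.approx(0.5)


def test_model_propagates_with_high_fidelity_at_max_rate(default_model):
    """At the highest spiking rate the soma can sustain, every somatic spike
    reaches the distal axon (fidelity ≥ 0.995)."""
    from axinit.cable import SolverConfig, make_synaptic_train, run

    p = make_synaptic_train(40.0, n_events=25, rate=100.0)
    tr = run(default_model, p, SolverConfig(duration=350.0))
    soma = tr.v[:, tr.soma_index()]
    distal = tr.v[:, tr.site_index(500.0)]
    assert len(detect_spikes(tr.t, soma)) >= 10
    assert propagation_fidelity(tr.t, soma, distal, window=5.0) >= 0.995
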