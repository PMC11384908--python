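"""Generator correctness: event bookkeeping, determinism, rate fidelity."""

import numpy as np
import pytest

from lymphpump.io import ProtocolSpec, Segment
from lymphpump.synthetic import (
    ConfigError,
    SimulationConfig,
    simulate_fluorescence_series,
    simulate_protocol_trace,
    simulate_vm_trace,
    standard_protocol,
)


def test_regular_pattern_event_count_and_troughs(baseline_protocol, clean_config):
    """10 cpm over 300 s gives exactly 50 events at 6 s spacing, with trace
    minima at baseline − amplitude at the event times."""
    trace, truth = simulate_protocol_trace(clean_config, baseline_protocol)
    assert truth.event_times_s.size == 50
    assert np.allclose(np.diff(truth.event_times_s), 6.0, atol=1.5 / 30)
    fs = clean_config.sample_rate_hz
    idx = np.round(truth.event_times_s * fs).astype(int)
    expected_esd = clean_config.baseline_edd_um - clean_config.amplitude_um
    assert np.allclose(trace.d[idx], expected_esd, atol=1e-9)
    assert trace.d.min() == pytest.approx(expected_esd)


def test_zero_amplitude_gives_flat_trace(baseline_protocol):
    cfg = SimulationConfig(duration_s=300, amplitude_um=0.0, freq_cpm=10,
                           noise_sd_um=0.0)
    trace, truth = simulate_protocol_trace(cfg, baseline_protocol)
    assert np.allclose(trace.d, cfg.baseline_edd_um)
    assert truth.event_times_s.size == 50
    assert np.all(truth.event_amps_um == 0.0)


def test_determinism_bit_identical(baseline_protocol, clean_config):
    t1, _ = simulate_protocol_trace(clean_config, baseline_protocol)
    t2, _ = simulate_protocol_trace(clean_config, baseline_protocol)
    assert np.array_equal(t1.d, t2.d)
    v1, _ = simulate_vm_trace(clean_config, baseline_protocol)
    v2, _ = simulate_vm_trace(clean_config, baseline_protocol)
    assert np.array_equal(v1.vm, v2.vm)
    f1 = simulate_fluorescence_series(2.0, noise_sd_au=1.0, seed=7)
    f2 = simulate_fluorescence_series(2.0, noise_sd_au=1.0, seed=7)
    assert np.array_equal(f1.roi_au, f2.roi_au)


def test_segment_frequency_multiplier_scales_rate():
    """A drug segment with multiplier 0.2 realizes 2 cpm when baseline is
    10 cpm (exact for the regular pattern)."""
    proto = ProtocolSpec([
        Segment("baseline", "baseline", 0, 600),
        Segment("drug", "drug", 600, 1200),
    ])
    cfg = SimulationConfig(duration_s=1200, freq_cpm=10, noise_sd_um=0,
                           segment_effects=(("drug", 0.2, 1.0),))
    _, truth = simulate_protocol_trace(cfg, proto)
    in_drug = [t for t in truth.event_times_s if 600 <= t < 1200]
    assert len(in_drug) == 20  # 2 cpm × 10 min


def test_conservation_bounds_noise_free(baseline_protocol, clean_config):
    trace, _ = simulate_protocol_trace(clean_config, baseline_protocol)
    assert trace.d.max() <= clean_config.baseline_edd_um + 1e-9
    assert trace.d.min() >= (
        clean_config.baseline_edd_um - clean_config.amplitude_um - 1e-9
    )


def test_poisson_rate_within_three_se(baseline_protocol):
    rates = []
    for seed in range(100):
        cfg = SimulationConfig(duration_s=300, freq_cpm=10, pattern="poisson",
                               noise_sd_um=0, seed=seed)
        _, truth = simulate_protocol_trace(cfg, baseline_protocol)
        rates.append(truth.event_times_s.size / 5.0)
    se = np.std(rates, ddof=1) / np.sqrt(len(rates))
    assert abs(np.mean(rates) - 10.0) <= 3 * se


def test_bursting_counts_members_toward_cpm(baseline_protocol):
    """Burst members all count: the realized rate approximates the request."""
    cfg = SimulationConfig(duration_s=300, freq_cpm=11, pattern="bursting",
                           noise_sd_um=0, seed=3)
    _, truth = simulate_protocol_trace(cfg, baseline_protocol)
    realized_cpm = truth.event_times_s.size / 5.0
    assert abs(realized_cpm - 11.0) <= 2.0
    gaps = np.diff(truth.event_times_s)
    # intra-burst gaps near 1.5 s and clearly longer pauses both occur
    assert (gaps < 2.0).any() and (gaps > 4.0).any()


def test_unrenderable_rate_rejected(baseline_protocol):
    cfg = SimulationConfig(duration_s=300, freq_cpm=200.0, noise_sd_um=0)
    with pytest.raises(ConfigError):
        simulate_protocol_trace(cfg, baseline_protocol)


def test_passive_segment_sits_at_dmax():
    proto = ProtocolSpec([
        Segment("baseline", "baseline", 0, 300),
        Segment("passive", "passive", 300, 420),
    ])
    cfg = SimulationConfig(duration_s=420, freq_cpm=10, noise_sd_um=0)
    trace, truth = simulate_protocol_trace(cfg, proto)
    mask = trace.t >= 300
    assert np.allclose(trace.d[mask], cfg.dmax_um)
    assert all(t < 300 for t in truth.event_times_s)


def test_vm_ap_contraction_bijection(baseline_protocol, clean_config):
    """One AP per contraction, at identical times."""
    vm_trace, vm_truth = simulate_vm_trace(clean_config, baseline_protocol)
    _, d_truth = simulate_protocol_trace(clean_config, baseline_protocol)
    assert vm_truth.ap_times_s.size == d_truth.event_times_s.size == 50
    assert np.array_equal(vm_truth.ap_times_s, d_truth.event_times_s)


def test_vm_suppressed_segment_fires_nothing_and_depolarizes():
    proto = standard_protocol(300, 300, 0)
    cfg = SimulationConfig(duration_s=600, freq_cpm=10, noise_sd_um=0,
                           vm_noise_sd_mv=0.0,
                           segment_effects=(("drug", 0.0, 1.0),))
    trace, truth = simulate_vm_trace(cfg, proto)
    assert all(t < 300 for t in truth.ap_times_s)
    drug_vm = trace.vm[trace.t >= 300]
    assert np.allclose(
        drug_vm, cfg.resting_vm_mv + cfg.suppressed_depolarization_mv
    )
    assert truth.resting_vm_by_segment["drug"] == pytest.approx(-42.0)


def test_fluorescence_linear_ramp_and_null():
    s = simulate_fluorescence_series(2.0, noise_sd_au=0.0)
    corrected = s.roi_au - s.background_au
    assert corrected[-1] - corrected[0] == pytest.approx(30.0)
    flat = simulate_fluorescence_series(0.0, noise_sd_au=1.0, seed=1)
    dF = (flat.roi_au - flat.background_au)
    assert np.all(np.abs(dF - dF[0]) < 6.0)  # noise envelope only


def test_fluorescence_slope_recovered_by_regression():
    slopes = []
    for seed in range(50):
        s = simulate_fluorescence_series(2.0, noise_sd_au=1.0, seed=seed)
        corrected = s.roi_au - s.background_au
        slope = np.polyfit(s.t_min, corrected, 1)[0]
        slopes.append(slope)
    se = np.std(slopes, ddof=1) / np.sqrt(len(slopes))
    assert abs(np.mean(slopes) - 2.0) <= 3 * se


def test_fluorescence_bad_intervals_rejected():
    with pytest.raises(ConfigError):
        simulate_fluorescence_series(2.0, duration_min=-5)
    with pytest.raises(ConfigError):
        simulate_fluorescence_series(2.0, duration_min=15, interval_min=4)


def test_config_invariants_enforced():
    with pytest.raises(ConfigError):
        SimulationConfig(duration_s=0)
    with pytest.raises(ConfigError):
        SimulationConfig(amplitude_um=100.0, baseline_edd_um=95.0)
    with pytest.raises(ConfigError):
        SimulationConfig(freq_cpm=-1)
    with pytest.raises(ConfigError):
        SimulationConfig(pattern="fractal")
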