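"""Synthetic recordings with known ground truth.

Generates the three recording types of an ex vivo lymphatic pump-function
study — inner-diameter traces, intracellular membrane-potential traces, and
ROS-reporter fluorescence time courses — with bookkeeping of every rendered
event, so detectors and metrics can be validated against exact truth.

The diameter generator emulates spontaneous twitch contractions of
pressurized popliteal collecting lymphatics at 37 °C and 3 cmH₂O: baseline
end-diastolic diameters around 95 µm, amplitudes around 40 µm (≈41 % of the
~97.5 µm maximal passive diameter), and rates of 2–16 cpm, with optional
bursting (3–8 contractions in rapid succession, then a pause) and
drug-segment effects that scale frequency and/or amplitude.  Each twitch is
an asymmetric transient: a fast half-cosine fall from EDD to ESD followed by
a slower raised-cosine recovery that returns to baseline with zero slope in
finite time.  Membrane-potential traces fire one action potential per
contraction (the pacemaker's 1:1 AP–twitch coupling); suppressed segments
fire none and depolarize slightly.  Fluorescence series accumulate linearly
over a 15 min, 1-frame-per-minute acquisition.

Resting V_m (−45 mV) and AP peak (+5 mV) defaults are conventions chosen for
plausibility, not measured values.  All randomness flows from ``seed``;
identical (config, protocol, seed) gives bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import DiameterTrace, FluorescenceSeries, ProtocolSpec, Segment, VmTrace


class ConfigError(ValueError):
    """Raised when a simulation config cannot be rendered as requested."""


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of a synthetic vessel recording.

    Defaults reproduce the typical wild-type recording: EDD 95 µm, amplitude
    40 µm (41 % of D_MAX = 97.5 µm), 11 cpm, 30 samples/s video tracking with
    ~1 µm diameter noise.  ``segment_effects`` maps protocol segment ids to
    ``(freq_multiplier, amp_multiplier)`` pairs — e.g. a drug that suppresses
    pacemaking to 22 % of control with preserved amplitude is
    ``(0.22, 1.0)``.

    The twitch shape is set by ``contraction_halfwidth_s`` (width at half
    amplitude): the fall takes one third of the half-width and the recovery
    spans ``2·halfwidth − fall``, preserving the fast-fall / slow-recovery
    asymmetry of real twitches.
    """

    duration_s: float = 300.0
    sample_rate_hz: float = 30.0
    baseline_edd_um: float = 95.0
    amplitude_um: float = 40.0
    freq_cpm: float = 11.0
    pattern: str = "regular"  # regular | poisson | bursting
    burst_size_range: tuple[int, int] = (3, 8)
    intra_burst_interval_s: float = 1.5
    contraction_halfwidth_s: float = 0.9
    noise_sd_um: float = 1.0
    drift_um_per_min: float = 0.0
    segment_effects: tuple = ()  # ((segment_id, freq_mult, amp_mult), ...)
    dmax_um: float = 97.5
    seed: int = 0
    # membrane-potential conventions (no published numeric values exist)
    vm_sample_rate_hz: float = 2000.0
    resting_vm_mv: float = -45.0
    ap_peak_mv: float = 5.0
    ap_rise_s: float = 0.015
    ap_fall_s: float = 0.060
    vm_noise_sd_mv: float = 0.3
    suppressed_depolarization_mv: float = 3.0
    electrode_offset_mv: float = 0.0

    def __post_init__(self) -> None:
        if not self.duration_s > 0:
            raise ConfigError("duration_s must be positive")
        if not self.sample_rate_hz > 0:
            raise ConfigError("sample_rate_hz must be positive")
        if not (0 <= self.amplitude_um < self.baseline_edd_um):
            raise ConfigError("require 0 <= amplitude_um < baseline_edd_um")
        if self.freq_cpm < 0:
            raise ConfigError("freq_cpm must be >= 0")
        if self.pattern not in ("regular", "poisson", "bursting"):
            raise ConfigError(f"unknown pattern {self.pattern!r}")
        lo, hi = self.burst_size_range
        if not (1 <= lo <= hi):
            raise ConfigError("burst_size_range must satisfy 1 <= lo <= hi")
        if self.noise_sd_um < 0:
            raise ConfigError("noise_sd_um must be >= 0")
        for eff in self.segment_effects:
            _, fm, am = eff
            if fm < 0 or am < 0:
                raise ConfigError("segment multipliers must be >= 0")

    @property
    def fall_s(self) -> float:
        return self.contraction_halfwidth_s / 3.0

    @property
    def recovery_s(self) -> float:
        return 2.0 * self.contraction_halfwidth_s - self.fall_s

    def effects_for(self, segment_id: str) -> tuple[float, float]:
        for sid, fm, am in self.segment_effects:
            if sid == segment_id:
                return float(fm), float(am)
        return 1.0, 1.0


@dataclass
class GroundTruth:
    """Bookkeeping of everything the generator rendered."""

    event_times_s: np.ndarray          # systolic trough times
    event_t_edd_s: np.ndarray          # fall-start (end-diastolic) times
    event_edd_um: np.ndarray           # realized EDD (below baseline in bursts)
    event_esd_um: np.ndarray
    event_amps_um: np.ndarray          # realized EDD − ESD
    event_segment_ids: list[str]
    segment_windows: dict[str, tuple[float, float]]
    true_dmax_um: float
    ap_times_s: np.ndarray | None = None
    resting_vm_by_segment: dict[str, float] = field(default_factory=dict)
    fluorescence_slope_au_per_min: float | None = None

    def __post_init__(self) -> None:
        if self.event_times_s.size > 1 and np.any(np.diff(self.event_times_s) <= 0):
            raise ValueError("ground-truth event times must be strictly increasing")


def standard_protocol(
    baseline_s: float = 600.0,
    drug_s: float = 1200.0,
    rescue_s: float = 600.0,
    passive_s: float = 0.0,
    drug: str = "drug",
    rescue_drug: str = "GLIB 1 uM",
) -> ProtocolSpec:
    """Baseline → drug → (rescue) → (passive) protocol starting at t = 0."""
    t = 0.0
    segs = [Segment("baseline", "baseline", t, t + baseline_s)]
    t += baseline_s
    if drug_s > 0:
        segs.append(Segment("drug", "drug", t, t + drug_s, drug=drug))
        t += drug_s
    if rescue_s > 0:
        segs.append(Segment("rescue", "rescue", t, t + rescue_s, drug=rescue_drug))
        t += rescue_s
    if passive_s > 0:
        segs.append(Segment("passive", "passive", t, t + passive_s,
                            drug="Ca2+-free + EGTA"))
    return ProtocolSpec(segs)


# ---------------------------------------------------------------------------
# event placement
# ---------------------------------------------------------------------------


def _min_gap(cfg: SimulationConfig) -> float:
    # next fall may not start before 2 samples after the current trough
    return cfg.fall_s + 2.0 / cfg.sample_rate_hz


def _segment_event_times(
    rng: np.random.Generator, seg_start: float, seg_end: float,
    rate_cpm: float, cfg: SimulationConfig,
) -> np.ndarray:
    if rate_cpm <= 0:
        return np.array([])
    mean_gap = 60.0 / rate_cpm
    minsep = _min_gap(cfg)
    times: list[float] = []
    if cfg.pattern == "regular":
        if mean_gap < minsep:
            raise ConfigError(
                f"regular pattern at {rate_cpm:g} cpm needs {mean_gap:g} s "
                f"spacing < renderable minimum {minsep:g} s"
            )
        t = seg_start + mean_gap / 2.0
        while t < seg_end - 1e-9:
            times.append(t)
            t += mean_gap
    elif cfg.pattern == "poisson":
        if mean_gap <= minsep:
            raise ConfigError(
                f"poisson pattern at {rate_cpm:g} cpm cannot respect the "
                f"{minsep:g} s minimum event separation"
            )
        # hard-core Poisson: shifted exponential keeps the requested mean rate
        t = seg_start
        while True:
            t += minsep + rng.exponential(mean_gap - minsep)
            if t >= seg_end:
                break
            times.append(t)
    else:  # bursting
        lo, hi = cfg.burst_size_range
        intra = cfg.intra_burst_interval_s
        if intra < minsep:
            raise ConfigError(
                f"intra-burst interval {intra:g} s below renderable minimum "
                f"{minsep:g} s"
            )
        pause_for = lambda k: k * mean_gap - (k - 1) * intra
        if pause_for(hi) <= minsep:
            raise ConfigError(
                "burst pause would be non-positive: requested cpm too high "
                "for the burst size range and intra-burst interval"
            )
        t = seg_start + mean_gap / 2.0
        while t < seg_end - 1e-9:
            k = int(rng.integers(lo, hi + 1))
            for j in range(k):
                tj = t + j * intra
                if tj < seg_end - 1e-9:
                    times.append(tj)
            # pause preserves the requested mean cpm counting every member
            t += (k - 1) * intra + pause_for(k)
    # snap to the sample grid so troughs land exactly on samples
    fs = cfg.sample_rate_hz
    snapped = np.round(np.array(times) * fs) / fs
    return snapped[(snapped >= seg_start) & (snapped < seg_end)]


def _plan_events(
    cfg: SimulationConfig, protocol: ProtocolSpec, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Return (trough times, per-event amplitude, per-event segment id)."""
    times, amps, segids = [], [], []
    for seg in protocol.segments:
        if seg.label == "passive":
            continue
        fm, am = cfg.effects_for(seg.segment_id)
        seg_times = _segment_event_times(
            rng, seg.start_s, seg.end_s, cfg.freq_cpm * fm, cfg
        )
        times.extend(seg_times)
        amps.extend([cfg.amplitude_um * am] * len(seg_times))
        segids.extend([seg.segment_id] * len(seg_times))
    order = np.argsort(times)
    times = np.array(times)[order]
    amps = np.array(amps)[order]
    segids = [segids[i] for i in order]
    if times.size > 1:
        gaps = np.diff(times)
        bad = np.nonzero(gaps < _min_gap(cfg) - 1e-9)[0]
        if bad.size:
            i = int(bad[0])
            raise ConfigError(
                f"events at {times[i]:.3f} s and {times[i + 1]:.3f} s are "
                f"{gaps[i]:.3f} s apart and cannot be rendered distinctly "
                f"(minimum {_min_gap(cfg):.3f} s at this halfwidth/rate)"
            )
    if times.size and times[0] - protocol.start_s < cfg.fall_s:
        raise ConfigError("first event falls before the recording starts")
    return times, amps, segids


# ---------------------------------------------------------------------------
# diameter rendering
# ---------------------------------------------------------------------------


def _recovery_depth(s: np.ndarray | float, fall_s: float,
                    rec_s: float) -> np.ndarray:
    """Depth fraction below baseline at time ``s`` after the trough.

    The first half fall-time mirrors the fall (so the trough is locally
    symmetric — its sample is the true minimum of any centered average),
    then a slower raised cosine returns to baseline with zero slope at
    ``rec_s``.  Depth is 1 at the trough and exactly 0 from ``rec_s`` on.
    """
    s = np.asarray(s, dtype=float)
    t_sym = fall_s / 2.0
    mirror = 0.5 * (1.0 + np.cos(np.pi * np.clip(s / fall_s, 0.0, 1.0)))
    tail = 0.25 * (
        1.0 + np.cos(np.pi * np.clip((s - t_sym) / (rec_s - t_sym), 0.0, 1.0))
    )
    return np.where(s <= t_sym, mirror, tail)


def simulate_protocol_trace(
    config: SimulationConfig, protocol: ProtocolSpec
) -> tuple[DiameterTrace, GroundTruth]:
    """Render a diameter recording over a full protocol.

    Active segments fire contractions at ``freq_cpm`` times the segment's
    frequency multiplier with amplitude scaled by its amplitude multiplier;
    passive segments sit at the maximal passive diameter with no events.
    Returns the noisy trace and the exact ground truth of every rendered
    event (in bursts the realized EDD is the partially recovered diameter at
    fall start, and is recorded as such).
    """
    if abs(protocol.end_s - protocol.start_s - config.duration_s) > 1e-6:
        raise ConfigError(
            f"protocol spans {protocol.end_s - protocol.start_s:g} s but "
            f"config.duration_s is {config.duration_s:g} s"
        )
    seeds = np.random.SeedSequence(config.seed).spawn(3)
    rng_events = np.random.default_rng(seeds[0])
    rng_noise = np.random.default_rng(seeds[1])

    times, amps, segids = _plan_events(config, protocol, rng_events)
    t, d, edd_t, edd_v, esd_v = render_events(config, protocol, times, amps)
    n = t.size

    # passive segments sit at D_MAX (no contractions ever rendered there)
    seg_windows = {}
    for seg in protocol.segments:
        seg_windows[seg.segment_id] = (seg.start_s, seg.end_s)
        if seg.label == "passive":
            d[(t >= seg.start_s) & (t < seg.end_s)] = config.dmax_um

    if config.drift_um_per_min:
        d = d + config.drift_um_per_min * (t - t[0]) / 60.0
    if config.noise_sd_um > 0:
        d = d + rng_noise.normal(0.0, config.noise_sd_um, n)

    meta = {
        "pressure_cmH2O": 3.0,
        "temperature_C": 37.0,
        "seed": config.seed,
        "pattern": config.pattern,
    }
    trace = DiameterTrace(t, d, config.sample_rate_hz, meta)
    truth = GroundTruth(
        event_times_s=times,
        event_t_edd_s=edd_t,
        event_edd_um=edd_v,
        event_esd_um=esd_v,
        event_amps_um=edd_v - esd_v,
        event_segment_ids=segids,
        segment_windows=seg_windows,
        true_dmax_um=config.dmax_um,
    )
    return trace, truth


def render_events(
    config: SimulationConfig,
    protocol: ProtocolSpec,
    times: np.ndarray,
    amps: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Render a noise-free diameter trajectory from explicit event times.

    Returns ``(t, d, t_edd, edd, esd)`` where the last three record the
    realized fall-start time and diameters of each event.  Used internally
    by :func:`simulate_protocol_trace`; exposed so a detected event list can
    be re-rendered with the same waveform model.
    """
    fs = config.sample_rate_hz
    n = int(round(config.duration_s * fs))
    t = protocol.start_s + np.arange(n) / fs
    base = config.baseline_edd_um
    d = np.full(n, base, dtype=float)
    fall, rec = config.fall_s, config.recovery_s

    times = np.asarray(times, dtype=float)
    amps = np.asarray(amps, dtype=float)
    edd_t = np.empty(times.size)
    edd_v = np.empty(times.size)
    esd_v = np.empty(times.size)
    for k in range(times.size):
        s_k = times[k]
        a_k = s_k - fall
        # pre-fall diameter: baseline, unless the previous recovery is unfinished
        d_pre = base
        if k > 0 and a_k - times[k - 1] < rec:
            d_pre = base - amps[k - 1] * float(
                _recovery_depth(a_k - times[k - 1], fall, rec)
            )
        esd = base - amps[k]
        if amps[k] > 0 and esd >= d_pre:
            raise ConfigError(
                f"event at {s_k:.3f} s: pre-fall diameter {d_pre:.2f} µm does "
                f"not exceed target ESD {esd:.2f} µm; events overlap too much"
            )
        i_tr = int(round((s_k - protocol.start_s) * fs))
        i_a = int(np.ceil((a_k - protocol.start_s) * fs - 1e-9))
        idx = np.arange(max(i_a, 0), min(i_tr + 1, n))
        u = (t[idx] - a_k) / fall
        d[idx] = esd + (d_pre - esd) * 0.5 * (1.0 + np.cos(np.pi * np.clip(u, 0, 1)))
        # recovery until the next fall start (or completion)
        r_end = s_k + rec
        if k + 1 < times.size:
            r_end = min(r_end, times[k + 1] - fall)
        j_end = int(np.floor((r_end - protocol.start_s) * fs + 1e-9))
        jdx = np.arange(min(i_tr + 1, n), min(j_end + 1, n))
        if jdx.size:
            d[jdx] = base - amps[k] * _recovery_depth(t[jdx] - s_k, fall, rec)
        edd_t[k] = a_k
        edd_v[k] = d_pre
        esd_v[k] = esd

    return t, d, edd_t, edd_v, esd_v


# ---------------------------------------------------------------------------
# membrane potential
# ---------------------------------------------------------------------------


def simulate_vm_trace(
    config: SimulationConfig, protocol: ProtocolSpec
) -> tuple[VmTrace, GroundTruth]:
    """Render the membrane-potential recording paired with the diameter trace.

    One action potential fires at each contraction time (pacemaking is 1:1
    with twitches), drawn from the same seed stream as
    :func:`simulate_protocol_trace`, so AP times equal contraction times
    exactly.  Segments whose frequency multiplier is zero fire no APs and
    sit ``suppressed_depolarization_mv`` above the resting potential — firing
    ceases even though V_m depolarizes slightly.  The emitted trace carries
    the configured electrode offset, recorded in ``offset_mv`` so that
    offset correction can undo it.
    """
    if abs(protocol.end_s - protocol.start_s - config.duration_s) > 1e-6:
        raise ConfigError("protocol span does not match config.duration_s")
    ap_width = config.ap_rise_s + config.ap_fall_s
    if config.freq_cpm > 0 and ap_width >= _min_gap(config):
        raise ConfigError(
            f"AP width {ap_width:g} s not below the minimum inter-event "
            f"interval {_min_gap(config):g} s"
        )
    fs = config.vm_sample_rate_hz
    n = int(round(config.duration_s * fs))
    t = protocol.start_s + np.arange(n) / fs

    seeds = np.random.SeedSequence(config.seed).spawn(3)
    rng_events = np.random.default_rng(seeds[0])
    rng_vm = np.random.default_rng(seeds[2])

    times, amps, segids = _plan_events(config, protocol, rng_events)

    rest = config.resting_vm_mv
    vm = np.full(n, rest, dtype=float)
    resting_by_seg: dict[str, float] = {}
    for seg in protocol.segments:
        fm, _ = config.effects_for(seg.segment_id)
        level = rest
        if seg.label != "passive" and fm == 0.0:
            level = rest + config.suppressed_depolarization_mv
        resting_by_seg[seg.segment_id] = level
        vm[(t >= seg.start_s) & (t < seg.end_s)] = level

    for s_k, sid in zip(times, segids):
        level = resting_by_seg[sid]
        amp = config.ap_peak_mv - level
        i_pk = int(round((s_k - protocol.start_s) * fs))
        i_lo = max(0, int(np.ceil((s_k - config.ap_rise_s - protocol.start_s) * fs)))
        i_hi = min(n - 1, int(np.floor((s_k + config.ap_fall_s - protocol.start_s) * fs)))
        idx = np.arange(i_lo, i_hi + 1)
        tt = t[idx] - s_k
        shape = np.where(
            tt <= 0,
            0.5 * (1.0 + np.cos(np.pi * np.clip(-tt / config.ap_rise_s, 0, 1))),
            0.5 * (1.0 + np.cos(np.pi * np.clip(tt / config.ap_fall_s, 0, 1))),
        )
        vm[idx] = level + amp * shape

    if config.vm_noise_sd_mv > 0:
        vm = vm + rng_vm.normal(0.0, config.vm_noise_sd_mv, n)
    if config.electrode_offset_mv:
        vm = vm + config.electrode_offset_mv

    trace = VmTrace(
        t, vm, fs, offset_mv=config.electrode_offset_mv,
        metadata={"seed": config.seed},
    )
    truth = GroundTruth(
        event_times_s=times,
        event_t_edd_s=times - config.fall_s,
        event_edd_um=np.full(times.size, config.baseline_edd_um),
        event_esd_um=config.baseline_edd_um - amps,
        event_amps_um=amps.copy(),
        event_segment_ids=segids,
        segment_windows={s.segment_id: (s.start_s, s.end_s) for s in protocol.segments},
        true_dmax_um=config.dmax_um,
        ap_times_s=times.copy(),
        resting_vm_by_segment=resting_by_seg,
    )
    return trace, truth


# ---------------------------------------------------------------------------
# fluorescence
# ---------------------------------------------------------------------------


def simulate_fluorescence_series(
    slope_au_per_min: float,
    duration_min: float = 15.0,
    interval_min: float = 1.0,
    noise_sd_au: float = 0.0,
    background_au: float = 50.0,
    roi_baseline_au: float = 100.0,
    seed: int = 0,
) -> FluorescenceSeries:
    """Linear ROS-reporter accumulation sampled on a minute grid.

    ROI intensity is ``roi_baseline + background + slope·t + noise``; the
    background channel is emitted separately (constant plus its own noise).
    A positive slope emulates oxidant-driven dye conversion; slope 0
    emulates a scavenger-pretreated vessel.
    """
    if duration_min <= 0 or interval_min <= 0:
        raise ConfigError("duration and interval must be positive")
    n_steps = duration_min / interval_min
    if abs(n_steps - round(n_steps)) > 1e-9:
        raise ConfigError("interval must divide duration")
    t = np.arange(int(round(n_steps)) + 1) * interval_min
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 4]))
    roi = roi_baseline_au + background_au + slope_au_per_min * t
    bg = np.full(t.size, background_au, dtype=float)
    if noise_sd_au > 0:
        roi = roi + rng.normal(0.0, noise_sd_au, t.size)
        bg = bg + rng.normal(0.0, noise_sd_au, t.size)
    roi = np.maximum(roi, 0.0)
    bg = np.maximum(bg, 0.0)
    return FluorescenceSeries(
        t, roi, bg,
        metadata={"slope_au_per_min": slope_au_per_min, "seed": seed},
    )
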