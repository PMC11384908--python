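"""Membrane-potential analysis: offset correction, AP detection, resting V_m.

Intracellular recordings from lymphatic muscle are corrected for the
electrode offset potential read at retraction, then scanned for action
potentials: a regenerative upstroke is a dV/dt excursion above threshold
(default 1 V/s, well above the slow diastolic depolarization) followed by a
peak sufficiently far above the resting potential.  Resting V_m is the
median of the samples outside an exclusion window around each spike, which
makes it insensitive to how many APs fire.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.ndimage import uniform_filter1d

from .io import VmTrace


@dataclass(frozen=True)
class APEvent:
    """One detected action potential."""

    t_peak: float
    peak_vm: float
    threshold_crossing_t: float


@dataclass(frozen=True)
class APDetectionParams:
    """AP detector thresholds.

    ``dvdt_threshold_mv_per_s`` (default 1 V/s) separates regenerative
    upstrokes from diastolic depolarization; ``min_refractory_s`` (2 ms)
    suppresses duplicate detections on one upstroke;
    ``min_peak_above_rest_mv`` rejects subthreshold fluctuations whose slope
    momentarily exceeds the dV/dt criterion.
    """

    dvdt_threshold_mv_per_s: float = 1000.0
    min_refractory_s: float = 0.002
    min_peak_above_rest_mv: float = 20.0
    peak_search_s: float = 0.2


def correct_offset(trace: VmTrace) -> VmTrace:
    """Subtract the electrode offset potential from the whole recording.

    Raises if no offset was recorded — an uncorrected trace must never be
    analyzed silently.  The applied offset is noted in the metadata and
    ``offset_mv`` is reset to 0 so the correction is idempotent.
    """
    if trace.offset_mv is None:
        raise ValueError("offset_mv missing: record the retraction offset first")
    meta = dict(trace.metadata, applied_offset_mv=trace.offset_mv)
    return VmTrace(
        trace.t.copy(), trace.vm - trace.offset_mv, trace.sample_rate_hz,
        offset_mv=0.0, metadata=meta,
    )


def detect_action_potentials(
    trace: VmTrace, params: APDetectionParams | None = None
) -> list[APEvent]:
    """Detect action potentials in an offset-corrected V_m trace.

    One event per suprathreshold upstroke: dV/dt (on a ~2 ms smoothed copy)
    must cross ``dvdt_threshold_mv_per_s`` rising, and the following peak
    must sit at least ``min_peak_above_rest_mv`` above the trace-median
    resting estimate.  Duplicate crossings within a refractory period of a
    detected peak are suppressed.

    Raises
    ------
    ValueError
        If the sampling rate is below 1 kHz (dV/dt cannot resolve the
        upstroke).
    """
    if params is None:
        params = APDetectionParams()
    fs = trace.sample_rate_hz
    if fs < 1000.0:
        raise ValueError(
            f"sample rate {fs:g} Hz too low for dV/dt-based AP detection "
            "(need >= 1 kHz)"
        )
    vm = trace.vm
    t = trace.t
    smooth = uniform_filter1d(vm, size=max(3, int(round(0.002 * fs)) | 1),
                              mode="nearest")
    dvdt = np.gradient(smooth, 1.0 / fs)
    rest = float(np.median(vm))

    thr = params.dvdt_threshold_mv_per_s
    crossings = np.nonzero((dvdt[1:] >= thr) & (dvdt[:-1] < thr))[0] + 1
    search = max(1, int(round(params.peak_search_s * fs)))

    events: list[APEvent] = []
    last_peak_t = -np.inf
    for c in crossings:
        if t[c] < last_peak_t + params.min_refractory_s:
            continue
        hi = min(c + search, vm.size)
        i_pk = c + int(np.argmax(vm[c:hi]))
        if events and t[i_pk] <= events[-1].t_peak + params.min_refractory_s:
            continue
        if vm[i_pk] < rest + params.min_peak_above_rest_mv:
            continue
        events.append(APEvent(float(t[i_pk]), float(vm[i_pk]), float(t[c])))
        last_peak_t = float(t[i_pk])
    return events


def resting_vm_and_ap_frequency(
    trace: VmTrace,
    events: list[APEvent],
    window: tuple[float, float],
    exclusion_halfwidth_s: float = 0.15,
) -> tuple[float, float]:
    """Resting V_m and AP rate over a half-open window ``[start, end)``.

    Resting V_m is the median of in-window samples at least
    ``exclusion_halfwidth_s`` away from every AP peak; the AP frequency is
    events per minute.  A window whose samples are all excluded (continuous
    firing faster than the exclusion window allows) is an error.
    """
    start, end = window
    if not end > start:
        raise ValueError("window must have positive length")
    mask = (trace.t >= start) & (trace.t < end)
    for e in events:
        mask &= np.abs(trace.t - e.t_peak) > exclusion_halfwidth_s
    if not mask.any():
        raise ValueError(
            "no samples left for resting V_m: window fully covered by AP "
            "exclusion zones"
        )
    resting = float(np.median(trace.vm[mask]))
    n = sum(1 for e in events if start <= e.t_peak < end)
    ap_freq = 60.0 * n / (end - start)
    return resting, ap_freq
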