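"""Contraction-event detection on inner-diameter traces.

Each spontaneous twitch of a pressurized collecting lymphatic is scored on a
contraction-by-contraction basis: the end-diastolic diameter (EDD) is the
local maximum immediately preceding the systolic trough, the end-systolic
diameter (ESD) is the trough itself, and per-event amplitude and ejection
fraction follow from the raw (unsmoothed) diameters at the located samples.

Localization runs on a lightly smoothed copy of the trace (centered moving
average) so that video-tracking noise does not fragment events, but reported
diameters always come from the raw trace.  When the diastolic plateau is flat
to within the noise level, the last plateau sample (the one nearest the
contraction) is taken as EDD; ties between equal minima break to the earliest
sample.  Thresholds are the analyst's to set — they are surfaced in
provenance headers, not hard-wired.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import uniform_filter1d
from scipy.signal import find_peaks

from .io import DiameterTrace


@dataclass
class ContractionEvent:
    """One detected contraction.

    ``amp`` and ``ef`` are derived at construction: amplitude is
    ``EDD − ESD`` (µm) and ejection fraction is ``1 − (ESD/EDD)²``, the
    fraction of luminal cross-sectional area expelled by the twitch.
    """

    t_edd: float
    edd: float
    t_esd: float
    esd: float
    burst_id: int | None = None
    amp: float = field(init=False)
    ef: float = field(init=False)

    def __post_init__(self) -> None:
        if not self.t_edd < self.t_esd:
            raise ValueError("EDD must precede ESD in time")
        if self.esd <= 0 or self.edd <= 0:
            raise ValueError("diameters must be positive")
        if self.esd > self.edd:
            raise ValueError("ESD cannot exceed EDD")
        self.amp = self.edd - self.esd
        self.ef = 1.0 - (self.esd / self.edd) ** 2


@dataclass(frozen=True)
class DetectionParams:
    """Tunable detector thresholds.

    smooth_window_s : centered moving-average span used for localization
        (0.2 s spans ~7 frames of 30 fps video — well below a 1–2 s twitch).
    min_amp_um : events with raw amplitude below this are discarded; 5 µm
        keeps residual micro-movements out of the contraction count.
    min_interval_s : minimum trough-to-trough spacing; must stay below the
        shortest expected inter-contraction interval (burst members can be
        ~1.5 s apart).
    prominence_um : trough prominence on the smoothed trace required to
        nominate a candidate contraction.
    edd_lookback_s : how far before a trough to search for its EDD; the
        end-diastolic peak sits immediately before the fall, so a short
        window avoids picking up unrelated diastolic drift.
    """

    smooth_window_s: float = 0.2
    min_amp_um: float = 5.0
    min_interval_s: float = 1.0
    prominence_um: float = 5.0
    edd_lookback_s: float = 2.5

    def __post_init__(self) -> None:
        for name in ("smooth_window_s", "min_amp_um", "min_interval_s",
                     "prominence_um", "edd_lookback_s"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


def _smooth(d: np.ndarray, window_samples: int) -> np.ndarray:
    if window_samples <= 1:
        return d.astype(float)
    return uniform_filter1d(d.astype(float), size=window_samples, mode="nearest")


def detect_contractions(
    trace: DiameterTrace, params: DetectionParams | None = None
) -> list[ContractionEvent]:
    """Detect every contraction in a diameter trace.

    Returns events ordered in time and non-overlapping.  Candidate systolic
    troughs are prominent minima of the smoothed trace; each EDD is the
    preceding local maximum (bounded by the previous trough and
    ``edd_lookback_s``); amplitude and EF are computed from raw diameters at
    the located sample indices, and events with amplitude below
    ``min_amp_um`` are discarded.

    Raises
    ------
    ValueError
        If the trace is shorter than twice the smoothing window.
    """
    if params is None:
        params = DetectionParams()
    fs = trace.sample_rate_hz
    d = trace.d
    if trace.duration_s < 2.0 * params.smooth_window_s:
        raise ValueError(
            f"trace ({trace.duration_s:g} s) shorter than twice the smoothing "
            f"window ({params.smooth_window_s:g} s)"
        )

    w = int(params.smooth_window_s * fs)
    w = max(1, w if w % 2 == 1 else w + 1)
    sm = _smooth(d, w)

    distance = max(1, int(round(params.min_interval_s * fs)))
    troughs, _ = find_peaks(-sm, prominence=params.prominence_um, distance=distance)
    if troughs.size == 0:
        return []

    # Plateau tolerance adapts to the noise level so a flat diastole under
    # noise is still treated as a plateau (EDD = last plateau sample).
    resid = d - sm
    sigma = 1.4826 * float(np.median(np.abs(resid - np.median(resid))))
    plateau_tol = sigma / np.sqrt(w)

    lookback = max(1, int(round(params.edd_lookback_s * fs)))
    events: list[ContractionEvent] = []
    prev_trough = -1
    for i in troughs:
        lo = max(prev_trough + 1, i - lookback, 0)
        prev_trough = int(i)
        if lo >= i:
            continue
        seg = sm[lo:i]
        m = seg.max()
        plateau = np.nonzero(seg >= m - plateau_tol)[0]
        j = lo + int(plateau[-1])  # last plateau sample: nearest the fall
        edd, esd = float(d[j]), float(d[i])
        if edd - esd < params.min_amp_um or edd <= esd or esd <= 0:
            continue
        events.append(
            ContractionEvent(
                t_edd=float(trace.t[j]), edd=edd,
                t_esd=float(trace.t[i]), esd=esd,
            )
        )
    return events


def compute_windowed_frequency(
    events: list[ContractionEvent], window: tuple[float, float]
) -> float:
    """Contraction frequency (cpm) inside a half-open window ``[start, end)``.

    Every contraction whose systolic trough falls in the window is counted,
    burst members individually — a bursting vessel genuinely contracts more
    often per minute.
    """
    start, end = window
    if not end > start:
        raise ValueError("analysis window must have positive length")
    n = sum(1 for e in events if start <= e.t_esd < end)
    return 60.0 * n / (end - start)


def label_bursts(
    events: list[ContractionEvent],
    intra_burst_max_interval_s: float,
    min_burst_size: int = 3,
) -> list[ContractionEvent]:
    """Assign burst ids to runs of closely spaced contractions.

    A burst is a maximal run of consecutive events whose trough-to-trough
    intervals are all ≤ ``intra_burst_max_interval_s``, of length at least
    ``min_burst_size`` (bursting vessels fire 3–8 contractions in rapid
    succession before a pause).  Events outside such runs keep
    ``burst_id = None``.  Events must be sorted in time.
    """
    times = [e.t_esd for e in events]
    if any(b < a for a, b in zip(times, times[1:])):
        raise ValueError("events must be sorted by t_esd")
    for e in events:
        e.burst_id = None
    next_id = 1
    run_start = 0
    n = len(events)
    for k in range(1, n + 1):
        in_run = (
            k < n and events[k].t_esd - events[k - 1].t_esd <= intra_burst_max_interval_s
        )
        if not in_run:
            if k - run_start >= min_burst_size:
                for e in events[run_start:k]:
                    e.burst_id = next_id
                next_id += 1
            run_start = k
    return events
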