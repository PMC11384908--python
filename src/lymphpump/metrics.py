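"""The five contractile-function statistics of lymphatic pump analysis.

Per contraction:

    AMP       = EDD − ESD                     (µm)
    normAMP   = (EDD − ESD) / D_MAX × 100     (% of maximal passive diameter)
    EF        = (EDD² − ESD²) / EDD²          (area ejection fraction)

Per analysis window:

    FREQ      = contractions per minute (cpm)
    FPF       = EF · FREQ                     (min⁻¹, fractional pump flow)
    normFREQ  = FREQ / FREQ_avg × 100         (% of the vessel's own baseline)

D_MAX is the maximum passive diameter measured after Ca²⁺-free superfusion at
the working pressure.  Because spontaneous frequency varies widely between
vessels, drug effects are expressed per vessel as a percentage of that
vessel's baseline average.  Window statistics are unweighted means of
per-event values (parameters are computed contraction by contraction, then
averaged).  When a window contains no contractions, frequency and pump flow
are zero but amplitude and EF are *absent*, not zero — no contraction, no
amplitude to record.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP

import numpy as np

from .detection import (
    ContractionEvent,
    DetectionParams,
    compute_windowed_frequency,
    detect_contractions,
)
from .io import DiameterTrace


@dataclass(frozen=True)
class DmaxRecord:
    """Maximum passive diameter and its provenance."""

    dmax_um: float
    pressure_cmH2O: float | None = None
    source_window: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if not self.dmax_um > 0:
            raise ValueError("D_MAX must be positive")


@dataclass
class WindowMetrics:
    """Per-analysis-window summary of contractile function.

    Amplitude/EF fields are ``None`` (absent) when the window holds no
    events; ``fpf_per_min`` is 0 when frequency is 0.
    """

    window: tuple[float, float]
    freq_cpm: float
    n_events: int
    mean_amp_um: float | None = None
    mean_norm_amp_pct: float | None = None
    mean_ef: float | None = None
    fpf_per_min: float = 0.0
    norm_freq_pct: float | None = None
    norm_amp_pct: float | None = None
    norm_fpf_pct: float | None = None


def per_contraction_metrics(
    edd: float, esd: float, dmax: float
) -> tuple[float, float, float]:
    """Amplitude, normalized amplitude, and ejection fraction of one twitch.

    Parameters
    ----------
    edd, esd : float
        End-diastolic and end-systolic inner diameters, µm, with
        ``0 < esd <= edd``.
    dmax : float
        Maximum passive diameter, µm.  An EDD slightly above ``dmax`` only
        warns — noise can push the diastolic peak past the passive estimate.

    Returns
    -------
    (amp_um, norm_amp_pct, ef)
    """
    if esd <= 0 or edd <= 0 or dmax <= 0:
        raise ValueError("diameters must be positive")
    if esd > edd:
        raise ValueError("ESD exceeds EDD: detector contract violated")
    if edd > dmax:
        warnings.warn(
            f"EDD ({edd:g} µm) exceeds D_MAX ({dmax:g} µm); computing anyway",
            stacklevel=2,
        )
    amp = edd - esd
    norm_amp = amp / dmax * 100.0
    ef = 1.0 - (esd / edd) ** 2
    return amp, norm_amp, ef


def window_summary(
    events: list[ContractionEvent],
    window: tuple[float, float],
    dmax: float,
    freq_fn=compute_windowed_frequency,
) -> WindowMetrics:
    """Summarize contractile function over a half-open window ``[start, end)``.

    Frequency comes from ``freq_fn`` (all events counted, burst members
    individually); amplitude and EF are unweighted means over the window's
    events; FPF is the window's mean EF times its frequency.
    """
    freq = freq_fn(events, window)
    start, end = window
    inside = [e for e in events if start <= e.t_esd < end]
    if not inside:
        return WindowMetrics(window=(start, end), freq_cpm=freq, n_events=0,
                             fpf_per_min=0.0)
    amps = np.array([e.amp for e in inside])
    efs = np.array([e.ef for e in inside])
    mean_ef = float(efs.mean())
    return WindowMetrics(
        window=(start, end),
        freq_cpm=freq,
        n_events=len(inside),
        mean_amp_um=float(amps.mean()),
        mean_norm_amp_pct=float(amps.mean() / dmax * 100.0),
        mean_ef=mean_ef,
        fpf_per_min=mean_ef * freq,
    )


def normalize_to_baseline(metric_value: float, baseline_avg: float) -> float:
    """Express a statistic as a percentage of its baseline (control) average.

    ``value / baseline_avg × 100``, full precision; rounding to the 1-decimal
    reporting convention happens only at output (:func:`report_value`).
    """
    if not baseline_avg > 0:
        raise ValueError("normalization undefined; baseline silent")
    return metric_value / baseline_avg * 100.0


_REPORT_DECIMALS = {"cpm": 1, "pct": 1, "um": 1, "ef": 3, "fpf": 1, "mv": 1}


def report_value(x: float | None, kind: str) -> float | None:
    """Round for reporting (half-up) at the convention for the given kind:
    1 decimal for cpm, %, µm, mV and FPF; 3 decimals for EF."""
    if x is None:
        return None
    nd = _REPORT_DECIMALS[kind]
    q = Decimal(1).scaleb(-nd)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def estimate_dmax(
    passive_trace: DiameterTrace,
    detection_params: DetectionParams | None = None,
    tail_s: float = 60.0,
) -> DmaxRecord:
    """Estimate D_MAX from a passive (Ca²⁺-free) segment recording.

    The estimate is the mean diameter over the final ``tail_s`` seconds of
    the segment, discarding the preceding equilibration.  If the detector
    still finds contractions above its amplitude threshold the vessel was
    not passive and the segment is rejected.
    """
    if detection_params is None:
        detection_params = DetectionParams()
    events = detect_contractions(passive_trace, detection_params)
    if events:
        raise ValueError(
            f"passive segment contains {len(events)} contraction(s) above "
            f"{detection_params.min_amp_um:g} µm; vessel not passive"
        )
    t_end = passive_trace.t[-1]
    t_start = max(passive_trace.t[0], t_end - tail_s)
    mask = passive_trace.t >= t_start
    dmax = float(passive_trace.d[mask].mean())
    return DmaxRecord(
        dmax_um=dmax,
        pressure_cmH2O=passive_trace.metadata.get("pressure_cmH2O"),
        source_window=(float(t_start), float(t_end)),
    )
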