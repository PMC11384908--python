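"""Typed containers and delimited-text I/O for traces, events, and protocols.

Unit conventions are fixed and never inferred: time in seconds (fluorescence
grids in minutes), inner diameter in µm, membrane potential in mV,
fluorescence in arbitrary units, contraction frequency in cpm only at
reporting boundaries.  Column headers must carry the unit suffix
(``time_s``, ``diameter_um``, ``vm_mv``, ``time_min``, ``roi_au``,
``background_au``); a file without them is rejected rather than guessed at.

TSV is the canonical on-disk format; CSV is accepted on read.  Every writer
prepends a provenance header (``#``-prefixed lines carrying the tool version
and, when supplied, a config hash and seed).  Analysis windows are half-open
``[start, end)`` on a 0-based time axis.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__ as _VERSION

VALID_SEGMENT_LABELS = ("baseline", "drug", "rescue", "passive")
VALID_WINDOW_RULES = ("last_5_min", "last_2_min", "full")

_DIAMETER_COLS = ("time_s", "diameter_um")
_VM_COLS = ("time_s", "vm_mv")
_FLUOR_COLS = ("time_min", "roi_au", "background_au")


class TraceFormatError(ValueError):
    """Raised when an on-disk trace or table violates the format contract."""


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass
class DiameterTrace:
    """Uniformly sampled inner-diameter time series.

    Parameters
    ----------
    t : array of float
        Sample times in seconds, strictly increasing, uniform to 1 ppm.
    d : array of float
        Inner diameter in µm, finite and positive.
    sample_rate_hz : float
        Acquisition rate (video diameter tracking is typically 30 fps).
    metadata : dict
        Free-form acquisition metadata (pressure_cmH2O, temperature_C,
        genotype, vessel_id, condition labels, ...).
    """

    t: np.ndarray
    d: np.ndarray
    sample_rate_hz: float
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.d = np.asarray(self.d, dtype=float)
        if self.t.size != self.d.size:
            raise ValueError("t and d must have equal length")
        if self.t.size < 2:
            raise ValueError("diameter trace needs at least 2 samples")
        dt = np.diff(self.t)
        if np.any(dt <= 0):
            i = int(np.argmax(dt <= 0))
            raise ValueError(f"time not strictly increasing at sample {i + 1}")
        mean_dt = float(dt.mean())
        if np.any(np.abs(dt - mean_dt) > 1e-6 * max(mean_dt, 1.0)):
            raise ValueError("time grid not uniform to 1 part in 1e6")
        if not np.all(np.isfinite(self.d)) or np.any(self.d <= 0):
            raise ValueError("diameters must be finite and positive")

    @property
    def duration_s(self) -> float:
        return float(self.t[-1] - self.t[0])


@dataclass
class VmTrace:
    """Membrane-potential time series from an intracellular impalement.

    ``offset_mv`` is the residual potential read at electrode retraction;
    :func:`lymphpump.ephys.correct_offset` subtracts it before analysis.
    """

    t: np.ndarray
    vm: np.ndarray
    sample_rate_hz: float
    offset_mv: float | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.vm = np.asarray(self.vm, dtype=float)
        if self.t.size != self.vm.size:
            raise ValueError("t and vm must have equal length")
        if self.t.size >= 2 and np.any(np.diff(self.t) <= 0):
            i = int(np.argmax(np.diff(self.t) <= 0))
            raise ValueError(f"time not strictly increasing at sample {i + 1}")
        if not np.all(np.isfinite(self.vm)):
            raise ValueError("vm must be finite")


@dataclass
class FluorescenceSeries:
    """ROI and background fluorescence intensities on a minute grid.

    Default acquisition emulated elsewhere is one frame per minute for
    15 min; the grid must start at 0 so ΔF-from-baseline is defined.
    """

    t_min: np.ndarray
    roi_au: np.ndarray
    background_au: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.t_min = np.asarray(self.t_min, dtype=float)
        self.roi_au = np.asarray(self.roi_au, dtype=float)
        self.background_au = np.asarray(self.background_au, dtype=float)
        if not (self.t_min.size == self.roi_au.size == self.background_au.size):
            raise ValueError("t, roi and background must have equal length")
        if self.t_min.size == 0 or self.t_min[0] != 0:
            raise ValueError("fluorescence series must start at t = 0")
        # raw intensities are non-negative; a background-subtracted series
        # may legitimately dip below zero and says so in its metadata
        if not self.metadata.get("background_subtracted") and (
            np.any(self.roi_au < 0) or np.any(self.background_au < 0)
        ):
            raise ValueError("intensities must be non-negative")


@dataclass(frozen=True)
class Segment:
    """One protocol segment, half-open ``[start_s, end_s)``."""

    segment_id: str
    label: str
    start_s: float
    end_s: float
    drug: str | None = None
    window_rule: str | tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.label not in VALID_SEGMENT_LABELS:
            raise ValueError(
                f"segment label {self.label!r} not in {VALID_SEGMENT_LABELS}"
            )
        if not self.end_s > self.start_s:
            raise ValueError(f"segment {self.segment_id!r}: end must exceed start")

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


# Default analysis-window rule per segment label; drug effects are scored over
# the last 5 min of exposure unless the protocol says otherwise.
_DEFAULT_RULES = {
    "baseline": "full",
    "drug": "last_5_min",
    "rescue": "last_5_min",
    "passive": "full",
}


@dataclass
class ProtocolSpec:
    """Ordered, gap-free segmentation of a recording with window rules."""

    segments: list[Segment]

    def __post_init__(self) -> None:
        if not self.segments:
            raise ValueError("protocol needs at least one segment")
        segs = sorted(self.segments, key=lambda s: s.start_s)
        for a, b in zip(segs, segs[1:]):
            if b.start_s < a.end_s - 1e-9:
                raise ValueError(
                    f"segments overlap: {a.segment_id!r} [{a.start_s}, {a.end_s}) "
                    f"and {b.segment_id!r} [{b.start_s}, {b.end_s})"
                )
            if b.start_s > a.end_s + 1e-9:
                raise ValueError(
                    f"gap between segments {a.segment_id!r} and {b.segment_id!r}: "
                    f"[{a.end_s}, {b.start_s})"
                )
        resolved = []
        for s in segs:
            rule = s.window_rule if s.window_rule is not None else _DEFAULT_RULES[s.label]
            resolved.append(
                Segment(s.segment_id, s.label, s.start_s, s.end_s, s.drug, rule)
            )
        self.segments = resolved

    @property
    def start_s(self) -> float:
        return self.segments[0].start_s

    @property
    def end_s(self) -> float:
        return self.segments[-1].end_s

    def segment(self, segment_id: str) -> Segment:
        for s in self.segments:
            if s.segment_id == segment_id:
                return s
        raise KeyError(segment_id)

    def analysis_window(self, segment: Segment | str) -> tuple[float, float]:
        """Resolve a segment's analysis window to ``[start, end)`` seconds."""
        if isinstance(segment, str):
            segment = self.segment(segment)
        rule = segment.window_rule
        if isinstance(rule, (tuple, list)):
            start, end = float(rule[0]), float(rule[1])
            if start < segment.start_s - 1e-9 or end > segment.end_s + 1e-9 or end <= start:
                raise ValueError(
                    f"custom window [{start}, {end}) not inside segment "
                    f"{segment.segment_id!r} [{segment.start_s}, {segment.end_s})"
                )
            return start, end
        if rule == "full":
            return segment.start_s, segment.end_s
        if rule in ("last_5_min", "last_2_min"):
            span = 300.0 if rule == "last_5_min" else 120.0
            if span > segment.duration_s + 1e-9:
                raise ValueError(
                    f"window rule {rule!r} ({span:g} s) longer than segment "
                    f"{segment.segment_id!r} ({segment.duration_s:g} s)"
                )
            return segment.end_s - span, segment.end_s
        raise ValueError(f"unknown window rule {rule!r}")


# ---------------------------------------------------------------------------
# provenance
# ---------------------------------------------------------------------------


def provenance_header(config: dict | None = None, seed: int | None = None) -> list[str]:
    """Build ``#``-prefixed provenance lines for output files."""
    lines = [f"# lymphpump {_VERSION}"]
    if config is not None:
        digest = hashlib.sha256(
            json.dumps(config, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]
        lines.append(f"# config_sha256: {digest}")
    if seed is not None:
        lines.append(f"# seed: {seed}")
    return lines


def _write_table(df: pd.DataFrame, path: Path | str,
                 config: dict | None = None, seed: int | None = None) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        for line in provenance_header(config, seed):
            fh.write(line + "\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.9g")


def _read_table(path: Path | str) -> tuple[pd.DataFrame, int]:
    """Read a TSV/CSV table, returning the frame and the 1-based header line."""
    path = Path(path)
    n_comments = 0
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                n_comments += 1
            else:
                break
    sep = "\t" if "\t" in line else ","
    try:
        df = pd.read_csv(path, sep=sep, comment="#", skip_blank_lines=True)
    except Exception as exc:  # surface the offending line if pandas knows it
        raise TraceFormatError(f"{path}: malformed table ({exc})") from exc
    return df, n_comments + 1


# ---------------------------------------------------------------------------
# traces
# ---------------------------------------------------------------------------


def read_trace(path, kind: str):
    """Read a delimited-text trace of the given kind.

    Parameters
    ----------
    path : str or Path
        TSV (canonical) or CSV file whose header names the time and value
        columns with explicit unit suffixes.
    kind : {"diameter", "vm", "fluorescence"}
        Selects the expected column set and returned container.

    Returns
    -------
    DiameterTrace, VmTrace or FluorescenceSeries

    Raises
    ------
    TraceFormatError
        On missing unit-bearing columns, non-numeric rows, or a
        non-monotonic time column (the first offending data line is named).
    """
    df, header_line = _read_table(path)
    meta = _read_sidecar(path)

    expected = {"diameter": _DIAMETER_COLS, "vm": _VM_COLS, "fluorescence": _FLUOR_COLS}
    if kind not in expected:
        raise ValueError(f"unknown trace kind {kind!r}")
    cols = expected[kind]
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise TraceFormatError(
            f"{path}: missing unit-bearing column(s) {missing}; units are "
            "declared in the header, never inferred"
        )
    for c in cols:
        vals = pd.to_numeric(df[c], errors="coerce")
        bad = np.nonzero(vals.isna().to_numpy() & df[c].notna().to_numpy())[0]
        if bad.size or vals.isna().any():
            row = int(bad[0]) if bad.size else int(np.argmax(vals.isna().to_numpy()))
            raise TraceFormatError(
                f"{path}: non-numeric or missing value in column {c!r} at line "
                f"{header_line + 1 + row}"
            )
        df[c] = vals

    tcol = cols[0]
    t = df[tcol].to_numpy(float)
    if t.size >= 2:
        dec = np.nonzero(np.diff(t) <= 0)[0]
        if dec.size:
            raise TraceFormatError(
                f"{path}: time column {tcol!r} not strictly increasing at line "
                f"{header_line + 1 + int(dec[0]) + 1}"
            )

    if kind == "diameter":
        rate = meta.get("sample_rate_hz")
        if rate is None:
            rate = 1.0 / float(np.mean(np.diff(t)))
        return DiameterTrace(t, df["diameter_um"].to_numpy(float), rate, meta)
    if kind == "vm":
        rate = meta.get("sample_rate_hz")
        if rate is None:
            rate = 1.0 / float(np.mean(np.diff(t)))
        return VmTrace(t, df["vm_mv"].to_numpy(float), rate,
                       meta.get("offset_mv"), meta)
    return FluorescenceSeries(
        t, df["roi_au"].to_numpy(float), df["background_au"].to_numpy(float), meta
    )


def _sidecar_path(path) -> Path:
    return Path(path).with_suffix(Path(path).suffix + ".json")


def _read_sidecar(path) -> dict:
    sc = _sidecar_path(path)
    if sc.exists():
        with open(sc) as fh:
            return json.load(fh)
    return {}


def write_trace(trace, path, config: dict | None = None, seed: int | None = None) -> None:
    """Write a trace as TSV with a provenance header and a JSON sidecar."""
    if isinstance(trace, DiameterTrace):
        df = pd.DataFrame({"time_s": trace.t, "diameter_um": trace.d})
        meta = dict(trace.metadata, sample_rate_hz=trace.sample_rate_hz)
    elif isinstance(trace, VmTrace):
        df = pd.DataFrame({"time_s": trace.t, "vm_mv": trace.vm})
        meta = dict(trace.metadata, sample_rate_hz=trace.sample_rate_hz)
        if trace.offset_mv is not None:
            meta["offset_mv"] = trace.offset_mv
    elif isinstance(trace, FluorescenceSeries):
        df = pd.DataFrame({
            "time_min": trace.t_min,
            "roi_au": trace.roi_au,
            "background_au": trace.background_au,
        })
        meta = dict(trace.metadata)
    else:
        raise TypeError(f"cannot write trace of type {type(trace).__name__}")
    _write_table(df, path, config, seed)
    with open(_sidecar_path(path), "w") as fh:
        json.dump(meta, fh, indent=1, default=str)


# ---------------------------------------------------------------------------
# event tables
# ---------------------------------------------------------------------------

_EVENT_COLS = ["event_index", "t_edd_s", "edd_um", "t_esd_s", "esd_um",
               "amp_um", "ef", "burst_id"]


def write_events(events: Sequence, path, config: dict | None = None,
                 seed: int | None = None) -> None:
    """Write detected contraction events as a TSV, one row per event.

    Events must already be sorted by end-diastolic time; rows carry a
    1-based ``event_index``.
    """
    times = [e.t_edd for e in events]
    if any(b < a for a, b in zip(times, times[1:])):
        raise ValueError("events must be sorted by t_edd before writing")
    df = pd.DataFrame(
        {
            "event_index": np.arange(1, len(events) + 1),
            "t_edd_s": [e.t_edd for e in events],
            "edd_um": [e.edd for e in events],
            "t_esd_s": [e.t_esd for e in events],
            "esd_um": [e.esd for e in events],
            "amp_um": [e.amp for e in events],
            "ef": [e.ef for e in events],
            "burst_id": [("" if e.burst_id is None else e.burst_id) for e in events],
        },
        columns=_EVENT_COLS,
    )
    _write_table(df, path, config, seed)


def read_events(path) -> list:
    """Read a contraction-event TSV back into ``ContractionEvent`` objects."""
    from .detection import ContractionEvent

    df, header_line = _read_table(path)
    missing = [c for c in _EVENT_COLS if c not in df.columns]
    if missing:
        raise TraceFormatError(f"{path}: missing event column(s) {missing}")
    out = []
    for _, row in df.iterrows():
        bid = row["burst_id"]
        burst_id = None if (pd.isna(bid) or bid == "") else int(bid)
        out.append(
            ContractionEvent(
                t_edd=float(row["t_edd_s"]),
                edd=float(row["edd_um"]),
                t_esd=float(row["t_esd_s"]),
                esd=float(row["esd_um"]),
                burst_id=burst_id,
            )
        )
    return out


# ---------------------------------------------------------------------------
# protocols
# ---------------------------------------------------------------------------


def read_protocol(path) -> ProtocolSpec:
    """Read a protocol description from YAML or JSON.

    The document is a mapping with a ``segments`` list; each entry carries
    ``id``, ``label``, ``start_s``, ``end_s`` and optionally ``drug`` and
    ``window`` (a rule name or ``[start, end]`` pair).  Defaults — drug and
    rescue segments scored over their last 5 min, baseline and passive over
    the full segment — are applied here and recorded on the returned object.
    """
    path = Path(path)
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict) or "segments" not in doc:
        raise TraceFormatError(f"{path}: protocol document must map 'segments'")
    segments = []
    for i, entry in enumerate(doc["segments"]):
        try:
            window = entry.get("window")
            if isinstance(window, list):
                window = (float(window[0]), float(window[1]))
            segments.append(
                Segment(
                    segment_id=str(entry.get("id", f"seg{i}")),
                    label=entry["label"],
                    start_s=float(entry["start_s"]),
                    end_s=float(entry["end_s"]),
                    drug=entry.get("drug"),
                    window_rule=window,
                )
            )
        except KeyError as exc:
            raise TraceFormatError(
                f"{path}: segment {i} missing required key {exc}"
            ) from exc
    return ProtocolSpec(segments)


def write_protocol(protocol: ProtocolSpec, path) -> None:
    doc = {
        "segments": [
            {
                "id": s.segment_id,
                "label": s.label,
                "start_s": s.start_s,
                "end_s": s.end_s,
                "drug": s.drug,
                "window": list(s.window_rule)
                if isinstance(s.window_rule, tuple)
                else s.window_rule,
            }
            for s in protocol.segments
        ]
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)
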