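"""Protocol segmentation, drug-response tables, and group comparisons.

A drug-response experiment records one vessel through ordered protocol
segments (baseline → drug → rescue → passive).  Because baseline contraction
frequency varies widely between vessels, every statistic is expressed per
vessel as a percentage of that vessel's own baseline average before groups
are compared.  Group inference follows the conventions of the field:
means ± SD, paired t-tests or one-way ANOVA with Tukey or Dunnett post hoc
comparisons at α = 0.05, and no inference at all for groups smaller than
five vessels (reported descriptively with a flag instead).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .detection import ContractionEvent, compute_windowed_frequency
from .io import ProtocolSpec
from .metrics import WindowMetrics, normalize_to_baseline, window_summary

ALPHA = 0.05
MIN_GROUP_SIZE = 5


@dataclass
class DrugResponseRecord:
    """Per-vessel drug response across protocol segments.

    ``windows`` maps segment id to its :class:`WindowMetrics`, with the
    ``norm_*`` fields filled as percent of the vessel's baseline averages.
    When the baseline is silent (FREQ average 0) normalized values are left
    ``None`` and flagged undefined rather than set to 0.
    """

    vessel_id: str
    condition: str | None
    windows: dict[str, WindowMetrics]
    baseline_segment_id: str
    baseline_freq_avg_cpm: float
    baseline_amp_avg_um: float | None
    baseline_fpf_avg_per_min: float
    normalization_undefined: bool = False
    flags: list[str] = field(default_factory=list)


def segment_windows(protocol: ProtocolSpec) -> dict[str, tuple[float, float]]:
    """Resolve every segment's analysis window, in protocol order.

    Baseline segments default to their full span; drug and rescue segments
    to their last 5 min (a protocol may override with ``last_2_min`` or a
    custom window).
    """
    return {
        s.segment_id: protocol.analysis_window(s) for s in protocol.segments
    }


def _baseline_freq_avg(
    events: list[ContractionEvent], window: tuple[float, float]
) -> float:
    """Baseline FREQ average: mean of per-minute frequencies over the whole
    baseline window (falls back to the overall rate when the window is
    shorter than a minute)."""
    start, end = window
    n_min = int((end - start) // 60)
    if n_min < 1:
        return compute_windowed_frequency(events, window)
    per_min = [
        compute_windowed_frequency(events, (start + 60.0 * k, start + 60.0 * (k + 1)))
        for k in range(n_min)
    ]
    return float(np.mean(per_min))


def build_drug_response(
    events: list[ContractionEvent],
    protocol: ProtocolSpec,
    dmax: float,
    vessel_id: str = "vessel",
    condition: str | None = None,
    amp_norm_mode: str = "raw",
) -> DrugResponseRecord:
    """Build one vessel's normalized drug-response record.

    Each segment's analysis window is summarized, then FREQ, AMP, and FPF
    are normalized to the baseline-window averages of the same vessel.
    ``amp_norm_mode`` selects whether the amplitude normalization divides
    raw mean AMP by baseline mean AMP (``"raw"``) or the D_MAX-normalized
    amplitudes by their baseline counterpart (``"dmax"``); applied
    consistently the two give identical percentages, so the flag exists to
    make the choice explicit, not to change the numbers.
    """
    if amp_norm_mode not in ("raw", "dmax"):
        raise ValueError("amp_norm_mode must be 'raw' or 'dmax'")
    baselines = [s for s in protocol.segments if s.label == "baseline"]
    if not baselines:
        raise ValueError("protocol has no baseline segment")
    base_seg = baselines[0]
    windows = segment_windows(protocol)

    wm: dict[str, WindowMetrics] = {}
    for seg in protocol.segments:
        if seg.label == "passive":
            continue
        wm[seg.segment_id] = window_summary(events, windows[seg.segment_id], dmax)

    base = wm[base_seg.segment_id]
    base_freq = _baseline_freq_avg(
        [e for e in events], windows[base_seg.segment_id]
    )
    base_amp = base.mean_amp_um
    base_norm_amp = base.mean_norm_amp_pct
    base_fpf = base.fpf_per_min

    flags: list[str] = []
    undefined = base_freq <= 0
    if undefined:
        flags.append("baseline silent: normalized values undefined")

    for sid, m in wm.items():
        if undefined:
            continue
        m.norm_freq_pct = normalize_to_baseline(m.freq_cpm, base_freq)
        if m.mean_amp_um is not None and base_amp:
            if amp_norm_mode == "raw":
                m.norm_amp_pct = normalize_to_baseline(m.mean_amp_um, base_amp)
            else:
                m.norm_amp_pct = normalize_to_baseline(
                    m.mean_norm_amp_pct, base_norm_amp
                )
        if base_fpf > 0:
            m.norm_fpf_pct = normalize_to_baseline(m.fpf_per_min, base_fpf)

    return DrugResponseRecord(
        vessel_id=vessel_id,
        condition=condition,
        windows=wm,
        baseline_segment_id=base_seg.segment_id,
        baseline_freq_avg_cpm=base_freq,
        baseline_amp_avg_um=base_amp,
        baseline_fpf_avg_per_min=base_fpf,
        normalization_undefined=undefined,
        flags=flags,
    )


# ---------------------------------------------------------------------------
# group comparisons
# ---------------------------------------------------------------------------


def _descriptives(values: np.ndarray) -> tuple[float, float, int]:
    return (
        float(np.mean(values)),
        float(np.std(values, ddof=1)) if values.size > 1 else 0.0,
        int(values.size),
    )


def group_compare(
    groups: dict[str, Sequence[float]],
    design: dict | None = None,
) -> pd.DataFrame:
    """Compare per-vessel statistics across groups or conditions.

    Parameters
    ----------
    groups : dict
        Group (or condition) name → per-vessel values.  For a
        ``within-vessel`` design all groups must hold the same vessels in
        the same order.
    design : dict
        ``repeated`` ∈ {"within-vessel", "between-genotype"} (default
        between), ``posthoc`` ∈ {"tukey", "dunnett"} for ≥3 groups, and
        ``control`` naming the reference group (required for Dunnett).

    Returns
    -------
    pandas.DataFrame
        One row per pairwise comparison: group descriptives (mean ± SD, n),
        test name, statistic, p-value, a significance flag at α = 0.05, and
        a ``flag`` column.  Any group with fewer than five vessels is
        excluded from inference and reported descriptively with a
        ``"not tested (n < 5)"`` flag.
    """
    design = dict(design or {})
    repeated = design.get("repeated", "between-genotype")
    posthoc = design.get("posthoc", "tukey")
    control = design.get("control")
    if posthoc == "dunnett" and control is None:
        raise ValueError("Dunnett post hoc requires a declared control group")
    if posthoc == "dunnett" and control not in groups:
        raise ValueError(f"control group {control!r} not among groups")

    arrays = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    small = {k for k, v in arrays.items() if v.size < MIN_GROUP_SIZE}
    tested = {k: v for k, v in arrays.items() if k not in small}

    rows: list[dict] = []

    def add_row(a, b, test, stat, p, flag=""):
        ma, sa, na = _descriptives(arrays[a])
        mb, sb, nb = _descriptives(arrays[b]) if b is not None else (np.nan, np.nan, 0)
        rows.append(
            {
                "group_a": a, "group_b": b,
                "mean_a": ma, "sd_a": sa, "n_a": na,
                "mean_b": mb, "sd_b": sb, "n_b": nb,
                "test": test, "statistic": stat, "p_value": p,
                "significant": bool(p < ALPHA) if np.isfinite(p) else False,
                "flag": flag,
            }
        )

    for k in small:
        other = None
        add_row(k, other, "descriptive", np.nan, np.nan, "not tested (n < 5)")

    names = list(tested)
    if len(names) == 2:
        a, b = names
        x, y = tested[a], tested[b]
        if repeated == "within-vessel":
            if x.size != y.size:
                raise ValueError("within-vessel design needs paired values")
            diff = x - y
            if np.allclose(diff, 0.0):
                add_row(a, b, "paired t", 0.0, 1.0)
            else:
                stat, p = sps.ttest_rel(x, y)
                add_row(a, b, "paired t", float(stat), float(p))
        else:
            stat, p = sps.ttest_ind(x, y)
            add_row(a, b, "t", float(stat), float(p))
    elif len(names) > 2:
        samples = [tested[k] for k in names]
        fstat, fp = sps.f_oneway(*samples)
        add_row(names[0], names[-1], "one-way ANOVA", float(fstat), float(fp),
                flag="omnibus")
        if posthoc == "tukey":
            from statsmodels.stats.multicomp import pairwise_tukeyhsd

            values = np.concatenate(samples)
            labels = np.concatenate([[k] * tested[k].size for k in names])
            res = pairwise_tukeyhsd(values, labels, alpha=ALPHA)
            for (g1, g2, _md, p, *_rest) in res.summary().data[1:]:
                add_row(str(g1), str(g2), "Tukey HSD", np.nan, float(p))
        else:
            if control in small:
                raise ValueError("control group too small for inference")
            others = [k for k in names if k != control]
            res = sps.dunnett(
                *[tested[k] for k in others], control=tested[control]
            )
            for k, p in zip(others, np.atleast_1d(res.pvalue)):
                add_row(k, control, "Dunnett", np.nan, float(p))

    return pd.DataFrame(rows)
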