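"""Action-potential biomarkers from voltage traces.

Extracts APD50, APD80 and beat rate from simulated or optical-style voltage
recordings. Optical traces carry arbitrary units and polarity, so every
operation here is invariant to affine transforms of the voltage channel
(and to polarity inversion when requested at the detection step).

Definitions
-----------
* An *upstroke* is the time of maximal positive finite-difference slope
  within each excursion above 50 % of the per-trace amplitude, with a
  200 ms refractory guard between detections.
* *APD at fraction f* is the time between the rising and the falling
  crossing of the level ``peak - f*(peak - baseline)``, where the baseline
  is the minimum between consecutive upstrokes and the peak the maximum
  after the upstroke; crossings are located by linear interpolation.
* *Beat rate* is ``60000 / mean inter-upstroke interval`` in beats/minute.

Per-recording summaries use the median across beats, which is robust to a
clipped first or last beat.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .cell_model import Trace
from .errors import InvalidParameterError

__all__ = [
    "BiomarkerSet",
    "BeatMeasure",
    "detect_beats",
    "apd",
    "beat_rate",
    "compute_biomarkers",
    "biomarker_table",
]


@dataclass
class BeatMeasure:
    """Per-beat detail: upstroke time, extrema, and the two APDs (ms)."""

    upstroke_ms: float
    peak: float
    baseline: float
    apd50_ms: float | None = None
    apd80_ms: float | None = None


@dataclass
class BiomarkerSet:
    """Per-recording biomarker summary with per-beat detail.

    ``apd50_ms``/``apd80_ms`` are medians across measurable beats;
    ``beat_rate_bpm`` is None (missing) when fewer than two upstrokes were
    detected. Quality flags: ``quiescent``, ``beats_dropped``,
    ``single_beat``.
    """

    apd50_ms: float | None
    apd80_ms: float | None
    beat_rate_bpm: float | None
    n_beats: int
    per_beat: list[BeatMeasure] = field(default_factory=list)
    flags: set[str] = field(default_factory=set)


def _moving_average(x: np.ndarray, window: int) -> np.ndarray:
    if window <= 1:
        return x
    kernel = np.ones(window) / window
    # reflect-pad so the smoothed trace keeps its length and edges
    pad = window // 2
    xp = np.pad(x, pad, mode="reflect")
    return np.convolve(xp, kernel, mode="same")[pad : pad + x.size]


def _normalize_polarity(v: np.ndarray) -> np.ndarray:
    """Flip an inverted optical trace.

    Action potentials depolarise much faster than they repolarise, so on an
    upright trace the steepest upward slope exceeds the steepest downward
    one; an inverted trace reverses the asymmetry. A lightly smoothed
    difference keeps single noise spikes from deciding the polarity.
    """
    if v.size < 4:
        return v
    d = np.diff(_moving_average(v, 3))
    if d.size and -float(np.min(d)) > float(np.max(d)):
        return -v
    return v


def _noise_sd(v: np.ndarray) -> float:
    """Robust noise estimate from first differences (MAD-based)."""
    d = np.diff(v)
    if d.size == 0:
        return 0.0
    return 1.4826 * float(np.median(np.abs(d - np.median(d)))) / math.sqrt(2.0)


def detect_beats(
    trace: Trace,
    smoothing_window: int = 0,
    *,
    refractory_ms: float = 200.0,
    min_amplitude: float | None = None,
    min_snr: float = 8.0,
) -> tuple[np.ndarray, set[str]]:
    """Detect upstroke times in a voltage trace.

    Excursions above 50 % of the (optionally smoothed) per-trace amplitude
    are located, and within each the time of maximal positive
    finite-difference slope is returned. Consecutive detections closer than
    ``refractory_ms`` are suppressed.

    A trace whose amplitude falls below the noise floor — ``min_amplitude``
    if given, otherwise ``min_snr`` times a robust noise estimate — yields
    an empty list and the ``quiescent`` flag.

    Returns
    -------
    (upstroke_times_ms, flags)
    """
    if len(trace) < 10:
        raise InvalidParameterError("trace must have at least 10 samples")
    t = trace.time_ms
    v_raw = _normalize_polarity(trace.voltage.astype(float))
    v = _moving_average(v_raw, smoothing_window)
    vmin, vmax = float(np.min(v)), float(np.max(v))
    amplitude = vmax - vmin
    floor = min_amplitude if min_amplitude is not None else min_snr * _noise_sd(v)
    if amplitude <= floor or amplitude == 0.0:
        return np.empty(0), {"quiescent"}

    thr = vmin + 0.5 * amplitude
    above = v >= thr
    edges_up = np.flatnonzero(~above[:-1] & above[1:]) + 1
    edges_dn = np.flatnonzero(above[:-1] & ~above[1:]) + 1
    # slopes on the raw trace: smoothing flattens the upstroke and would
    # quantise the max-slope location
    slopes = np.diff(v_raw) / np.diff(t)

    times: list[float] = []
    last = -math.inf
    for i_up in edges_up:
        i_dn_candidates = edges_dn[edges_dn > i_up]
        i_end = int(i_dn_candidates[0]) if i_dn_candidates.size else v.size
        # max positive slope just before/within the suprathreshold excursion
        lo = max(i_up - 2, 0)
        seg = slopes[lo : max(i_end - 1, lo + 1)]
        if seg.size == 0:
            continue
        k = lo + int(np.argmax(seg))
        t_up = 0.5 * (t[k] + t[k + 1])
        if t_up - last >= refractory_ms:
            times.append(float(t_up))
            last = t_up
    flags: set[str] = set()
    if not times:
        flags.add("quiescent")
    return np.asarray(times), flags


def _interp_crossing(
    t: np.ndarray, v: np.ndarray, level: float, i0: int, i1: int, rising: bool
) -> float | None:
    """Linear-interpolated crossing of ``level`` in samples [i0, i1)."""
    for i in range(i0, min(i1, v.size - 1)):
        a, b = v[i], v[i + 1]
        if rising and a < level <= b or (not rising) and a >= level > b:
            if b == a:
                return float(t[i])
            return float(t[i] + (level - a) * (t[i + 1] - t[i]) / (b - a))
    return None


def apd(
    trace: Trace,
    upstrokes: Sequence[float] | np.ndarray,
    fraction: float,
    *,
    smoothing_window: int = 0,
) -> tuple[list[float | None], set[str]]:
    """Per-beat action potential duration at repolarization ``fraction``.

    For each beat, the baseline is the minimum between consecutive
    upstrokes (the last beat uses the trailing window), the peak the
    maximum after the upstroke, and the APD the time between the rising and
    falling crossings of ``peak - fraction*(peak - baseline)``. Beats whose
    falling crossing lies beyond the trace are dropped (None) and flagged.
    """
    if not 0.0 < fraction < 1.0:
        raise InvalidParameterError("fraction must lie in (0, 1)")
    ups = np.asarray(upstrokes, dtype=float)
    if ups.size < 1:
        raise InvalidParameterError("at least one upstroke is required")
    t = trace.time_ms
    v_raw = _normalize_polarity(trace.voltage.astype(float))
    v = _moving_average(v_raw, smoothing_window)

    durations: list[float | None] = []
    flags: set[str] = set()
    boundaries = np.append(ups, t[-1] + 1.0)
    # a trailing beat whose window is much shorter than a typical cycle is
    # truncated mid-AP: its extrema and crossings would be meaningless
    min_window = 0.5 * float(np.median(np.diff(ups))) if ups.size >= 2 else 0.0
    for b in range(ups.size):
        t_up, t_next = boundaries[b], boundaries[b + 1]
        i_up = int(np.searchsorted(t, t_up))
        i_next = int(np.searchsorted(t, t_next))
        if i_next - i_up < 3 or (t_next - t_up) < min_window:
            durations.append(None)
            flags.add("beats_dropped")
            continue
        seg_v = v[i_up:i_next]
        i_peak = i_up + int(np.argmax(seg_v))
        peak = float(v[i_peak])
        tail = v[i_peak:i_next] if i_next > i_peak + 1 else seg_v
        # low percentile instead of the minimum: the min of many noisy
        # samples sits ~2 sigma below the true diastolic level, which would
        # bias the repolarization threshold
        baseline = float(np.percentile(tail, 10)) if tail.size >= 10 else float(tail.min())
        level = peak - fraction * (peak - baseline)
        # rising crossing: on the raw trace (the upstroke is steep, and
        # smoothing would smear it across a frame); search a short lead
        # window before the max-slope time since sub-midpoint levels are
        # crossed just before it
        i_lead = int(np.searchsorted(t, t_up - 100.0))
        if b > 0:
            i_lead = max(i_lead, int(np.searchsorted(t, boundaries[b - 1])))
        t_rise = _interp_crossing(t, v_raw, level, i_lead, i_peak + 1, rising=True)
        t_fall = _interp_crossing(t, v, level, i_peak, i_next, rising=False)
        if t_rise is None or t_fall is None:
            durations.append(None)
            flags.add("beats_dropped")
            continue
        durations.append(t_fall - t_rise)
    return durations, flags


def beat_rate(upstrokes: Sequence[float] | np.ndarray) -> float | None:
    """Beat rate in bpm from upstroke times; None if fewer than two."""
    ups = np.asarray(upstrokes, dtype=float)
    if ups.size < 2:
        return None
    return 60_000.0 / float(np.mean(np.diff(ups)))


def compute_biomarkers(
    trace: Trace,
    *,
    fps_mode: str = "model",
    smoothing_window: int | None = None,
    min_amplitude: float | None = None,
) -> BiomarkerSet:
    """Full biomarker extraction for one trace.

    ``fps_mode`` selects the default smoothing: none for dense model traces,
    a 5-sample moving average for 50 fps optical-style recordings.
    """
    if fps_mode not in ("model", "optical"):
        raise InvalidParameterError("fps_mode must be 'model' or 'optical'")
    if smoothing_window is None:
        smoothing_window = 3 if fps_mode == "optical" else 0

    ups, flags = detect_beats(
        trace, smoothing_window, min_amplitude=min_amplitude
    )
    if ups.size == 0:
        return BiomarkerSet(None, None, None, 0, [], flags)

    a50, f50 = apd(trace, ups, 0.5, smoothing_window=smoothing_window)
    a80, f80 = apd(trace, ups, 0.8, smoothing_window=smoothing_window)
    flags |= f50 | f80
    rate = beat_rate(ups)
    if rate is None:
        flags.add("single_beat")

    per_beat: list[BeatMeasure] = []
    t = trace.time_ms
    v = _normalize_polarity(_moving_average(trace.voltage.astype(float), smoothing_window))
    boundaries = np.append(ups, t[-1] + 1.0)
    for b in range(ups.size):
        i0 = int(np.searchsorted(t, boundaries[b]))
        i1 = int(np.searchsorted(t, boundaries[b + 1]))
        seg = v[i0:i1] if i1 > i0 else v[i0 : i0 + 1]
        per_beat.append(
            BeatMeasure(
                upstroke_ms=float(ups[b]),
                peak=float(seg.max()),
                baseline=float(seg.min()),
                apd50_ms=a50[b],
                apd80_ms=a80[b],
            )
        )

    def _median(vals: list[float | None]) -> float | None:
        good = [x for x in vals if x is not None]
        return float(np.median(good)) if good else None

    return BiomarkerSet(
        apd50_ms=_median(a50),
        apd80_ms=_median(a80),
        beat_rate_bpm=rate,
        n_beats=int(ups.size),
        per_beat=per_beat,
        flags=flags,
    )


def biomarker_table(
    traces: Mapping[str, Trace],
    *,
    fps_mode: str = "model",
    smoothing_window: int | None = None,
) -> pd.DataFrame:
    """One biomarker row per trace, ordered by label.

    Per-trace failures never abort the table: problem rows carry missing
    values and their quality flags.
    """
    rows = []
    for label in sorted(traces):
        try:
            bm = compute_biomarkers(
                traces[label], fps_mode=fps_mode, smoothing_window=smoothing_window
            )
            rows.append(
                {
                    "label": label,
                    "apd50_ms": bm.apd50_ms,
                    "apd80_ms": bm.apd80_ms,
                    "beat_rate_bpm": bm.beat_rate_bpm,
                    "n_beats": bm.n_beats,
                    "flags": ";".join(sorted(bm.flags)),
                }
            )
        except InvalidParameterError as exc:
            rows.append(
                {
                    "label": label,
                    "apd50_ms": None,
                    "apd80_ms": None,
                    "beat_rate_bpm": None,
                    "n_beats": 0,
                    "flags": f"error:{exc}",
                }
            )
    return pd.DataFrame(rows)
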