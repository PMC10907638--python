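"""Synthetic optical-style voltage recordings and drug-study datasets.

Emulates plate-based optical voltage measurements of beating cardiomyocyte
microtissues: 8 s recordings at 50 frames/s per well, for a control arm and
two nifedipine arms (0.1 uM, 1 uM) sampled at baseline and 2, 4, 6, 8, 13
and 16 h post-dose, with well-level variability, additive Gaussian noise
and linear baseline drift.

The single-beat waveform is a piecewise half-cosine template — sigmoidal
upstroke of configurable rise time, flat plateau, smooth half-cosine
repolarization — whose threshold crossings are analytically invertible, so
the generating APD50/APD80 are exact by construction and serve as ground
truth for validating the biomarker pipeline:

* rising crossing of level ``L`` (amplitude fraction from baseline):
  ``t = (t_rise/pi) * arccos(1 - 2 L)``
* falling crossing: ``t = t_rise + t_plateau + (t_fall/pi) * arccos(2 L - 1)``
* hence ``APD(f) = t_plateau + w(f) * (t_rise + t_fall)`` with
  ``w(f) = arccos(1 - 2 f)/pi`` evaluated at level ``L = 1 - f``.

Optical units are arbitrary; the generator can flip polarity to exercise
the amplitude normalisation of the biomarker module.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Callable

import numpy as np
import pandas as pd

from .biomarkers import BeatMeasure, BiomarkerSet
from .cell_model import Trace
from .errors import InvalidParameterError

__all__ = [
    "SynthTraceSpec",
    "SynthStudySpec",
    "ArmEffect",
    "synth_optical_trace",
    "synth_study",
    "STUDY_TIMEPOINTS_H",
]

#: Recording schedule of the emulated drug study (hours post-dose; 0 = baseline).
STUDY_TIMEPOINTS_H = (0.0, 2.0, 4.0, 6.0, 8.0, 13.0, 16.0)


@dataclass(frozen=True)
class SynthTraceSpec:
    """Specification of one synthetic optical recording."""

    beat_rate_bpm: float = 60.0
    apd50_ms: float = 300.0
    apd80_ms: float = 360.0
    duration_s: float = 8.0
    fps: float = 50.0
    noise_sd: float = 0.0  # fraction of amplitude
    drift_per_s: float = 0.0  # baseline slope, fraction of amplitude per s
    amplitude: float = 1.0  # arbitrary optical units
    rise_ms: float = 20.0
    invert: bool = False
    phase_ms: float = 40.0  # delay of the first upstroke
    seed: int = 0

    def __post_init__(self) -> None:
        if self.beat_rate_bpm <= 0 or self.fps <= 0 or self.duration_s <= 0:
            raise InvalidParameterError("rate, fps and duration must be positive")
        if not self.apd80_ms > self.apd50_ms:
            raise InvalidParameterError("apd80 must exceed apd50")
        if self.fps * self.duration_s < 50:
            raise InvalidParameterError("need at least 50 samples (fps*duration)")
        if self.apd80_ms >= self.period_ms:
            raise InvalidParameterError("apd80 must be shorter than the beat period")

    @property
    def period_ms(self) -> float:
        return 60_000.0 / self.beat_rate_bpm


def _crossing_weight(fraction: float) -> float:
    """w(f) = arccos(1 - 2 f)/pi, the rise/fall share of APD(f)."""
    return math.acos(1.0 - 2.0 * fraction) / math.pi


def _template_segments(spec: SynthTraceSpec) -> tuple[float, float, float]:
    """Solve (t_rise, t_plateau, t_fall) from the requested APD50/APD80.

    APD(f) = t_plateau + w(f)*(t_rise + t_fall), so the pair of target APDs
    fixes t_plateau and t_rise + t_fall; t_rise itself is the configured
    upstroke rise time.
    """
    w50, w80 = _crossing_weight(0.5), _crossing_weight(0.8)
    rise_plus_fall = (spec.apd80_ms - spec.apd50_ms) / (w80 - w50)
    t_fall = rise_plus_fall - spec.rise_ms
    t_plateau = spec.apd50_ms - w50 * rise_plus_fall
    if t_fall <= 0:
        raise InvalidParameterError(
            "apd80 - apd50 too small for the configured rise time"
        )
    if t_plateau <= 0:
        raise InvalidParameterError("apd50 too short for the implied repolarization")
    if spec.rise_ms + t_plateau + t_fall >= spec.period_ms:
        raise InvalidParameterError("waveform does not fit in the beat period")
    return spec.rise_ms, t_plateau, t_fall


def _waveform(t_in_beat: np.ndarray, t_r: float, t_p: float, t_f: float) -> np.ndarray:
    """Normalised single-beat waveform on [0, period), range [0, 1]."""
    w = np.zeros_like(t_in_beat)
    rise = t_in_beat < t_r
    w[rise] = 0.5 * (1.0 - np.cos(np.pi * t_in_beat[rise] / t_r))
    plateau = (t_in_beat >= t_r) & (t_in_beat < t_r + t_p)
    w[plateau] = 1.0
    fall = (t_in_beat >= t_r + t_p) & (t_in_beat < t_r + t_p + t_f)
    w[fall] = 0.5 * (1.0 + np.cos(np.pi * (t_in_beat[fall] - t_r - t_p) / t_f))
    return w


def synth_optical_trace(spec: SynthTraceSpec) -> tuple[Trace, BiomarkerSet]:
    """Generate one synthetic optical trace plus its ground-truth biomarkers.

    The returned BiomarkerSet carries the analytically exact APD50/APD80 and
    beat rate of the generating template (upstroke times at the point of
    maximal slope, i.e. mid-rise).
    """
    t_r, t_p, t_f = _template_segments(spec)
    rng = np.random.default_rng(spec.seed)

    n_samples = int(round(spec.fps * spec.duration_s))
    dt_ms = 1000.0 / spec.fps
    t = np.arange(n_samples) * dt_ms
    t_in_beat = np.mod(t - spec.phase_ms, spec.period_ms)
    v = spec.amplitude * _waveform(t_in_beat, t_r, t_p, t_f)
    v = v + spec.drift_per_s * spec.amplitude * (t / 1000.0)
    if spec.noise_sd > 0:
        v = v + rng.normal(0.0, spec.noise_sd * spec.amplitude, size=v.shape)
    if spec.invert:
        v = -v

    # ground truth: mid-rise upstroke times of beats inside the record
    first = spec.phase_ms + 0.5 * t_r
    ups = np.arange(first, t[-1], spec.period_ms)
    per_beat = [
        BeatMeasure(
            upstroke_ms=float(u),
            peak=spec.amplitude,
            baseline=0.0,
            apd50_ms=spec.apd50_ms,
            apd80_ms=spec.apd80_ms,
        )
        for u in ups
    ]
    truth = BiomarkerSet(
        apd50_ms=spec.apd50_ms,
        apd80_ms=spec.apd80_ms,
        beat_rate_bpm=spec.beat_rate_bpm,
        n_beats=len(ups),
        per_beat=per_beat,
        flags=set(),
    )
    trace = Trace(
        time_ms=t,
        voltage=v,
        calcium=None,
        metadata={
            "sampling": "uniform",
            "fps": spec.fps,
            "units": {"time": "ms", "voltage": "arbitrary"},
            "provenance": "synthetic optical template",
            "seed": spec.seed,
        },
    )
    return trace, truth


@dataclass(frozen=True)
class ArmEffect:
    """Parametric biomarker trajectory of one study arm.

    Fractional changes relative to the control baseline follow an
    exponential recovery from an initial effect toward a residual effect:
    ``effect(t) = residual + (initial - residual) * exp(-t / tau_h)`` for
    t > 0 (baseline recordings are unaffected). APD fractions shrink the
    APDs; the rate fraction acts on the beat rate with opposite sign
    conventions left to the caller.
    """

    apd_initial: float = 0.0  # fractional APD suppression at t -> 0+
    apd_residual: float = 0.0  # fractional suppression remaining as t -> inf
    rate_initial: float = 0.0  # fractional beat-rate increase at t -> 0+
    rate_residual: float = 0.0
    tau_h: float = 5.0

    def apd_factor(self, t_h: float) -> float:
        if t_h <= 0:
            return 1.0
        e = self.apd_residual + (self.apd_initial - self.apd_residual) * math.exp(
            -t_h / self.tau_h
        )
        return 1.0 - e

    def rate_factor(self, t_h: float) -> float:
        if t_h <= 0:
            return 1.0
        e = self.rate_residual + (self.rate_initial - self.rate_residual) * math.exp(
            -t_h / self.tau_h
        )
        return 1.0 + e


#: Default arm effects: the low dose suppresses APD ~25 % initially and
#: recovers nearly fully; the high dose suppresses ~45 % with a lasting
#: residual, matching the qualitative time course of a partially
#: compensated block. Beat rate moves opposite to APD.
DEFAULT_ARM_EFFECTS: dict[str, ArmEffect] = {
    "control": ArmEffect(),
    "0.1uM": ArmEffect(apd_initial=0.25, apd_residual=0.02, rate_initial=0.15, rate_residual=0.01, tau_h=5.0),
    "1uM": ArmEffect(apd_initial=0.45, apd_residual=0.25, rate_initial=0.25, rate_residual=0.12, tau_h=5.0),
}


@dataclass(frozen=True)
class SynthStudySpec:
    """Specification of a full synthetic drug study."""

    wells_per_arm: int = 4
    arms: tuple[str, ...] = ("control", "0.1uM", "1uM")
    timepoints_h: tuple[float, ...] = STUDY_TIMEPOINTS_H
    baseline_rate_bpm: float = 60.0
    baseline_apd50_ms: float = 300.0
    baseline_apd80_ms: float = 360.0
    well_sd: float = 0.05  # well-level multiplicative variability
    recording_sd: float = 0.01  # per-recording jitter on biomarkers
    noise_sd: float = 0.02  # optical noise, fraction of amplitude
    drift_per_s: float = 0.01
    duration_s: float = 8.0
    fps: float = 50.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.wells_per_arm < 1:
            raise InvalidParameterError("wells_per_arm must be >= 1")
        if not self.arms:
            raise InvalidParameterError("at least one arm required")


def synth_study(
    spec: SynthStudySpec,
    out_dir: str | Path | None = None,
    *,
    arm_effects: dict[str, ArmEffect] | None = None,
    effect_curves: dict[str, Callable[[float], tuple[float, float]]] | None = None,
) -> tuple[dict[tuple[str, str, float], tuple[Trace, BiomarkerSet]], pd.DataFrame, pd.DataFrame]:
    """Generate a complete synthetic drug study.

    One trace per well x timepoint follows its arm's effect curve plus
    well-level random effects. ``effect_curves`` optionally maps an arm
    label to a callable ``t_h -> (apd_factor, rate_factor)`` — e.g. built
    from a coupled-simulation biomarker table — overriding the parametric
    :class:`ArmEffect` defaults for that arm.

    Returns
    -------
    (recordings, design, truth):
        recordings maps ``(arm, well, timepoint_h)`` to (Trace, ground
        truth); design and truth are DataFrames. When ``out_dir`` is given,
        traces are written as ``<arm>/<well>_<timepoint>.csv`` along with
        ``design.csv`` and ``truth.csv``.
    """
    effects = dict(DEFAULT_ARM_EFFECTS)
    if arm_effects:
        effects.update(arm_effects)
    rng = np.random.default_rng(spec.seed)

    recordings: dict[tuple[str, str, float], tuple[Trace, BiomarkerSet]] = {}
    design_rows, truth_rows = [], []
    for arm in spec.arms:
        if arm not in effects and (effect_curves is None or arm not in effect_curves):
            raise InvalidParameterError(f"no effect curve for arm {arm!r}")
        for w in range(spec.wells_per_arm):
            well = f"{arm}_w{w:02d}"
            well_apd = 1.0 + spec.well_sd * rng.standard_normal()
            well_rate = 1.0 + spec.well_sd * rng.standard_normal()
            for t_h in spec.timepoints_h:
                if effect_curves is not None and arm in effect_curves:
                    f_apd, f_rate = effect_curves[arm](t_h)
                else:
                    eff = effects[arm]
                    f_apd, f_rate = eff.apd_factor(t_h), eff.rate_factor(t_h)
                jit_a = 1.0 + spec.recording_sd * rng.standard_normal()
                jit_r = 1.0 + spec.recording_sd * rng.standard_normal()
                tspec = SynthTraceSpec(
                    beat_rate_bpm=spec.baseline_rate_bpm * well_rate * f_rate * jit_r,
                    apd50_ms=spec.baseline_apd50_ms * well_apd * f_apd * jit_a,
                    apd80_ms=spec.baseline_apd80_ms * well_apd * f_apd * jit_a,
                    duration_s=spec.duration_s,
                    fps=spec.fps,
                    noise_sd=spec.noise_sd,
                    drift_per_s=spec.drift_per_s,
                    phase_ms=float(rng.uniform(0.0, 500.0)),
                    seed=int(rng.integers(0, 2**31 - 1)),
                )
                trace, truth = synth_optical_trace(tspec)
                recordings[(arm, well, t_h)] = (trace, truth)
                fname = f"{arm}/{well}_{t_h:g}h.csv"
                design_rows.append(
                    {"well": well, "arm": arm, "timepoint_h": t_h, "file": fname}
                )
                truth_rows.append(
                    {
                        "well": well,
                        "arm": arm,
                        "timepoint_h": t_h,
                        "apd50_ms": tspec.apd50_ms,
                        "apd80_ms": tspec.apd80_ms,
                        "beat_rate_bpm": tspec.beat_rate_bpm,
                    }
                )
    design = pd.DataFrame(design_rows)
    truth = pd.DataFrame(truth_rows)

    if out_dir is not None:
        from .traceio import write_trace

        out = Path(out_dir)
        for (arm, well, t_h), (trace, _) in recordings.items():
            path = out / arm / f"{well}_{t_h:g}h.csv"
            path.parent.mkdir(parents=True, exist_ok=True)
            write_trace(trace, path)
        design.to_csv(out / "design.csv", index=False)
        truth.to_csv(out / "truth.csv", index=False)
        (out / "study_meta.json").write_text(json.dumps(asdict(spec), indent=2))
    return recordings, design, truth
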