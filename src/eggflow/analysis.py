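"""Offline EGG analysis: the rest-recording pipeline and session summaries.

The offline path mirrors standard cutaneous-EGG practice: decimate the
1000 Hz acquisition stream to 10 Hz, linearly detrend, bandpass to the
gastric range (0.016-0.16 Hz, i.e. 1-10 cpm) with a zero-phase
Butterworth filter, Hann-window, zero-pad to a power of 2, FFT, and
express per-band power as a percentage of the total 1-10 cpm power.

A session pairs three such recordings — a fasted baseline, the training
period after 250 ml of water, and a post-training rest after drinking to
fullness — and reports the per-timepoint band percentages plus their
successive differences, the structure used for within-session
comparisons.  Group-level inference (mixed models, post-hocs) is out of
scope; the tidy CSV export feeds external statistics packages.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core import (
    CANONICAL_BANDS,
    FilterSpec,
    RawRecording,
    band_powers,
    bandpass,
    detrend,
    downsample,
    spectrum,
)

__all__ = [
    "SessionPlan",
    "ArtifactFlag",
    "SessionResult",
    "analyze_recording",
    "artifact_flag",
    "winsorize_by_group",
    "summarize_session",
    "session_to_frame",
]

TIMEPOINTS = ("pre", "during", "post")

#: Minimum analyzable duration: two full bradygastric (1 cpm) cycles.
MIN_DURATION_S = 120.0

ANALYSIS_FS = 10.0


def analyze_recording(
    rec: RawRecording,
    *,
    filter_spec: FilterSpec | None = None,
    detrend_first: bool = True,
):
    """Run the offline band-power pipeline on one rest recording.

    Stages: downsample to 10 Hz -> detrend -> zero-phase Butterworth
    bandpass -> Hann window + zero-pad -> FFT -> percent band power.
    ``detrend_first=False`` swaps the detrend and bandpass stages (the
    streaming chain filters first); the two orders differ only through
    the filter's finite DC rejection and give near-identical percentages.

    Returns a :class:`~eggflow.core.BandPowerSummary`.  Deterministic:
    repeated calls on the same input are bit-identical.

    Raises
    ------
    ValueError
        If the recording is shorter than 120 s (the minimum needed to
        resolve the bradygastric band).
    """
    if rec.duration < MIN_DURATION_S:
        raise ValueError(
            f"recording of {rec.duration:.1f} s is shorter than the "
            f"{MIN_DURATION_S:.0f} s minimum for band-power analysis"
        )
    spec = filter_spec or FilterSpec(zero_phase=True)
    low = rec if abs(rec.fs - ANALYSIS_FS) < 1e-9 else downsample(rec, ANALYSIS_FS)
    if detrend_first:
        x = bandpass(detrend(low.samples), ANALYSIS_FS, spec)
    else:
        x = detrend(bandpass(low.samples, ANALYSIS_FS, spec))
    return band_powers(spectrum(x, ANALYSIS_FS), CANONICAL_BANDS)


@dataclass(frozen=True)
class ArtifactFlag:
    """One automated data-quality warning over a time interval."""

    kind: str  # "clipping" or "jump"
    t_start: float
    t_end: float
    detail: str

    def as_dict(self) -> dict:
        return {
            "kind": self.kind,
            "t_start": self.t_start,
            "t_end": self.t_end,
            "detail": self.detail,
        }


def artifact_flag(
    rec: RawRecording,
    clip_fraction: float = 0.01,
    *,
    window_s: float = 5.0,
    jump_sds: float = 6.0,
) -> list[ArtifactFlag]:
    """Flag saturated segments and implausible sample jumps.

    A crude automated stand-in for visual quality inspection.  Two
    checks, neither of which modifies the data:

    * **Clipping** — within each ``window_s`` window, the fraction of
      samples pinned at the recording's extreme values; above
      ``clip_fraction`` the window is flagged (amplifier saturation).
    * **Jumps** — successive-sample differences beyond ``jump_sds``
      robust standard deviations (1.4826 x MAD) of all differences
      (electrode pops, movement artifacts).
    """
    x = rec.samples
    flags: list[ArtifactFlag] = []
    lo, hi = float(x.min()), float(x.max())
    span = hi - lo
    if span > 0:
        eps = 1e-9 * span
        at_edge = (x <= lo + eps) | (x >= hi - eps)
        n_win = max(1, int(round(window_s * rec.fs)))
        for start in range(0, x.size, n_win):
            seg = at_edge[start : start + n_win]
            frac = float(seg.mean())
            if frac > clip_fraction:
                flags.append(
                    ArtifactFlag(
                        "clipping",
                        start / rec.fs,
                        min(x.size, start + n_win) / rec.fs,
                        f"{100 * frac:.1f}% of samples at range extremes",
                    )
                )
    if x.size >= 3:
        d = np.diff(x)
        mad = float(np.median(np.abs(d - np.median(d))))
        robust_sd = 1.4826 * mad
        if robust_sd > 0:
            bad = np.flatnonzero(np.abs(d) > jump_sds * robust_sd)
            for i in bad:
                flags.append(
                    ArtifactFlag(
                        "jump",
                        i / rec.fs,
                        (i + 1) / rec.fs,
                        f"step of {abs(d[i]) / robust_sd:.1f} robust SDs",
                    )
                )
    return sorted(flags, key=lambda f: (f.t_start, f.kind))


def winsorize_by_group(values: Sequence[float], k: float = 3.0) -> np.ndarray:
    """Clamp outliers to ``k`` standard deviations from the group mean.

    Mean and sample SD (ddof=1) are computed once from the input — not
    re-estimated after clamping — and values beyond ``mean +/- k*SD`` are
    set to the boundary.  The output therefore never contains a value
    outside the original list's ``[mean - k*SD, mean + k*SD]``.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("winsorization needs at least 2 values")
    mean = float(x.mean())
    sd = float(x.std(ddof=1))
    return np.clip(x, mean - k * sd, mean + k * sd)


@dataclass(frozen=True)
class SessionPlan:
    """Planned timepoint durations and mode of one training session."""

    baseline_s: float = 900.0
    training_s: float = 600.0
    post_s: float = 900.0
    mode: str = "vr"
    markers: tuple[str, ...] = ("water_intake", "wlt_start")

    def __post_init__(self) -> None:
        for name in ("baseline_s", "training_s", "post_s"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")
        if self.mode not in {"vr", "2d", "control"}:
            raise ValueError(f"mode must be one of vr/2d/control, got {self.mode!r}")

    def duration_for(self, timepoint: str) -> float:
        return {
            "pre": self.baseline_s,
            "during": self.training_s,
            "post": self.post_s,
        }[timepoint]


@dataclass(frozen=True)
class SessionResult:
    """Per-timepoint band-power summaries for one training session."""

    summaries: dict  # timepoint -> BandPowerSummary or None
    differences: dict  # e.g. "during-pre" -> {band: delta_pct} or None
    mode: str
    session_index: int
    flags: tuple[str, ...] = ()

    @property
    def complete(self) -> bool:
        return all(self.summaries.get(tp) is not None for tp in TIMEPOINTS)

    def as_dict(self) -> dict:
        return {
            "mode": self.mode,
            "session_index": self.session_index,
            "complete": self.complete,
            "summaries": {
                tp: (s.as_dict() if s is not None else None)
                for tp, s in self.summaries.items()
            },
            "differences": self.differences,
            "flags": list(self.flags),
        }


def summarize_session(
    recordings: Mapping[str, RawRecording | None],
    plan: SessionPlan | None = None,
    *,
    session_index: int = 1,
    duration_tolerance: float = 0.05,
) -> SessionResult:
    """Analyze the pre/during/post recordings of one session.

    Each present recording is run through :func:`analyze_recording`;
    successive differences (during - pre, post - during) are reported per
    band where both endpoints exist.  A missing timepoint or a recording
    whose duration deviates from the plan by more than
    ``duration_tolerance`` yields a flag rather than an error, so partial
    sessions still produce a (marked) result.
    """
    plan = plan or SessionPlan()
    if not 1 <= session_index <= 4:
        raise ValueError("session_index must be in 1..4")
    flags: list[str] = []
    summaries: dict = {}
    for tp in TIMEPOINTS:
        rec = recordings.get(tp)
        if rec is None:
            summaries[tp] = None
            flags.append(f"missing timepoint: {tp}")
            continue
        planned = plan.duration_for(tp)
        if abs(rec.duration - planned) > duration_tolerance * planned:
            flags.append(
                f"{tp} duration {rec.duration:.0f} s deviates from plan "
                f"{planned:.0f} s by more than {100 * duration_tolerance:.0f}%"
            )
        for af in artifact_flag(rec):
            flags.append(f"{tp}: {af.kind} at {af.t_start:.2f}-{af.t_end:.2f} s")
        summaries[tp] = analyze_recording(rec)

    def diff(a: str, b: str):
        sa, sb = summaries.get(a), summaries.get(b)
        if sa is None or sb is None:
            return None
        return {
            "pct_brady": sa.pct_brady - sb.pct_brady,
            "pct_normo": sa.pct_normo - sb.pct_normo,
            "pct_tachy": sa.pct_tachy - sb.pct_tachy,
        }

    differences = {"during-pre": diff("during", "pre"), "post-during": diff("post", "during")}
    return SessionResult(
        summaries=summaries,
        differences=differences,
        mode=plan.mode,
        session_index=session_index,
        flags=tuple(flags),
    )


def session_to_frame(
    result: SessionResult, participant: str | int = "P01"
) -> pd.DataFrame:
    """Tidy long-format table: one row per timepoint x band.

    Columns: participant, session, mode, timepoint, band, pct, total_power
    — the layout external statistics packages expect for repeated-measures
    models.
    """
    band_attr = {
        "bradygastria": "pct_brady",
        "normogastria": "pct_normo",
        "tachygastria": "pct_tachy",
    }
    rows = []
    for tp in TIMEPOINTS:
        summary = result.summaries.get(tp)
        if summary is None:
            continue
        for band, attr in band_attr.items():
            rows.append(
                {
                    "participant": participant,
                    "session": result.session_index,
                    "mode": result.mode,
                    "timepoint": tp,
                    "band": band,
                    "pct": getattr(summary, attr),
                    "total_power": summary.total_power,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "participant",
            "session",
            "mode",
            "timepoint",
            "band",
            "pct",
            "total_power",
        ],
    )
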