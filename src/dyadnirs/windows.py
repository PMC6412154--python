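"""Case segmentation: phase windows, minute segments, pre-rating windows.

Scenario phases vary widely in duration across sessions, so analyses
compare fixed one-minute segments — the first minute, a middle minute
centred on the phase midpoint, and the last minute of each phase — plus
the one-minute window immediately before each observer workload rating.
All windows are half-open ``[start, end)`` on the session clock.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

from dyadnirs.session import HbTimeSeries, SessionEvents

SEGMENT_LABELS = ("first_minute", "middle_minute", "last_minute")


@dataclass(frozen=True)
class AnalysisWindow:
    """A labelled half-open time window inside (or equal to) a phase.

    ``degenerate`` flags windows that could not be placed as defined —
    minute segments that overlap because the phase is shorter than
    180 s, or pre-rating windows truncated at the phase start.  They are
    emitted rather than dropped so the statistical stage decides
    inclusion.
    """

    label: str
    phase_name: str
    start: float
    end: float
    degenerate: bool = False

    def __post_init__(self) -> None:
        if not self.end > self.start:
            raise ValueError("window must have positive length")

    @property
    def span(self) -> tuple[float, float]:
        return (self.start, self.end)

    @property
    def duration(self) -> float:
        return self.end - self.start


def baseline_window(events: SessionEvents) -> AnalysisWindow:
    b0, b1 = events.baseline
    return AnalysisWindow("baseline", "baseline", b0, b1)


def segment_phases(events: SessionEvents) -> list[AnalysisWindow]:
    """Full-phase windows plus first/middle/last minute segments.

    For each phase ``[s, e)``: the full window, the first minute
    ``[s, s+60)``, a middle minute centred on the phase midpoint, and the
    last minute ``[e-60, e)``.  Phases shorter than 180 s yield
    overlapping segments (flagged degenerate); phases shorter than 60 s
    yield a single degenerate window carrying all three segment labels.
    """
    out: list[AnalysisWindow] = []
    for name, start, end in events.phases:
        dur = end - start
        out.append(AnalysisWindow("phase_full", name, start, end))
        if dur < 60:
            for label in SEGMENT_LABELS:
                out.append(AnalysisWindow(label, name, start, end, degenerate=True))
            continue
        degenerate = dur < 180
        mid = (start + end) / 2
        out.append(AnalysisWindow("first_minute", name, start, start + 60, degenerate))
        out.append(AnalysisWindow("middle_minute", name, mid - 30, mid + 30, degenerate))
        out.append(AnalysisWindow("last_minute", name, end - 60, end, degenerate))
    return out


def pre_rating_windows(events: SessionEvents) -> list[AnalysisWindow]:
    """One ``[t-60, t)`` window per observer rating time ``t``.

    A window reaching before its phase start is truncated there and
    flagged degenerate.
    """
    out = []
    for t in events.rating_times:
        phase = events.phase_at(t)
        if phase is None:  # events validation normally prevents this
            raise ValueError(f"rating time {t} outside all phases")
        p0, _ = events.phase_span(phase)
        start = t - 60
        truncated = start < p0
        out.append(
            AnalysisWindow("pre_rating", phase, max(start, p0), t, degenerate=truncated)
        )
    return out


def window_mean(x: HbTimeSeries, w: AnalysisWindow) -> tuple[float, bool]:
    """Mean of the series over the window; flags sparse coverage.

    Returns ``(mean, missing)``.  ``missing`` is true (and the mean is
    NaN) when fewer than half of the expected ``duration * sample_rate``
    samples fall inside the window.
    """
    t = x.times()
    mask = (t >= w.start) & (t < w.end)
    expected = w.duration * x.sample_rate
    if mask.sum() < expected / 2:
        return (float("nan"), True)
    return (float(x.values[mask].mean()), False)


def write_windows_bed(windows: list[AnalysisWindow], path: str | Path) -> None:
    """Export windows as 3+ column interval text for audit."""
    with open(path, "w") as fh:
        fh.write("label\tstart\tend\tphase\tdegenerate\n")
        for w in windows:
            fh.write(
                f"{w.label}\t{w.start!r}\t{w.end!r}\t{w.phase_name}\t"
                f"{int(w.degenerate)}\n"
            )
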