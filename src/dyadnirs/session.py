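"""Session data model and text-file readers/writers.

A *session* is one two-person simulation scenario: a five-minute seated
baseline, then a single-provider phase, a team phase, and a debriefing,
with a single prefrontal fNIRS channel recorded continuously for each
participant.  All timestamps are seconds on a shared session clock,
0-based at recording start; every analysis window is half-open
``[start, end)`` so a sample falling exactly on ``end`` is excluded.

File formats are deliberately plain: delimited text with a small
``# key<TAB>value`` header block, so sessions round-trip through
version control and diff cleanly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

ROLES = ("initial_provider", "responder")
PHASE_NAMES = ("single_provider", "team", "debriefing")
DIFFICULTY_LEVELS = ("low", "medium", "high")
EXPERIENCE_LEVELS = ("Y1", "Y2", "Y3", "attending")

#: processing steps in the only order the pipeline may apply them
PIPELINE_STEPS = (
    "converted",
    "artifact_removed",
    "filtered",
    "normalized",
    "baseline_subtracted",
    "resampled",
)


class SessionFormatError(ValueError):
    """Raised when an input file violates the session data model."""


@dataclass
class ODRecording:
    """Two-wavelength optical-density change series for one participant.

    ``od`` has shape (n_samples, 2), one column per wavelength; values are
    dimensionless log-attenuation changes.  ``wavelengths`` is optional
    metadata (the emitting wavelengths in nm) and may be ``None`` when the
    instrument does not report them.
    """

    participant_id: str
    role: str
    od: np.ndarray
    sample_rate: float = 100.0
    t0: float = 0.0
    wavelengths: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        self.od = np.asarray(self.od, dtype=float)
        if self.role not in ROLES:
            raise ValueError(f"role must be one of {ROLES}, got {self.role!r}")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        if self.od.ndim != 2 or self.od.shape[1] != 2:
            raise ValueError("od must have exactly 2 columns (one per wavelength)")
        if not np.all(np.isfinite(self.od)):
            raise ValueError("od contains non-finite samples; gaps must be explicit")

    @property
    def n_samples(self) -> int:
        return self.od.shape[0]

    @property
    def duration(self) -> float:
        return self.n_samples / self.sample_rate

    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.n_samples) / self.sample_rate


@dataclass
class HbTimeSeries:
    """A ΔHbO or ΔHbR concentration-change series (arbitrary units).

    ``state`` records which pipeline steps have been applied, in order;
    :func:`advance_state` enforces the order so stages cannot be skipped
    or repeated.
    """

    participant_id: str
    chromophore: str  # "HbO" | "HbR"
    values: np.ndarray
    sample_rate: float
    t0: float = 0.0
    state: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).ravel()
        if self.chromophore not in ("HbO", "HbR"):
            raise ValueError("chromophore must be 'HbO' or 'HbR'")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        for step in self.state:
            if step not in PIPELINE_STEPS:
                raise ValueError(f"unknown pipeline step {step!r}")

    @property
    def n_samples(self) -> int:
        return self.values.size

    @property
    def duration(self) -> float:
        return self.n_samples / self.sample_rate

    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.n_samples) / self.sample_rate

    def require_state(self, *steps: str) -> None:
        for step in steps:
            if step not in self.state:
                raise RuntimeError(
                    f"pipeline-order violation: step requires {step!r} but "
                    f"series state is {self.state}"
                )

    def advance_state(self, *new_steps: str) -> tuple[str, ...]:
        """Return ``state`` extended with ``new_steps``, enforcing order."""
        state = self.state + tuple(new_steps)
        order = [PIPELINE_STEPS.index(s) for s in state]
        if order != sorted(order) or len(set(state)) != len(state):
            raise RuntimeError(
                f"pipeline-order violation: {state} is not a prefix-ordered "
                f"subset of {PIPELINE_STEPS}"
            )
        return state


@dataclass
class SessionEvents:
    """Event annotations for one session on the shared clock.

    ``baseline`` and each phase are half-open ``[start, end)`` windows in
    seconds; ``rating_times`` are the moments the observer recorded a
    workload rating.
    """

    baseline: tuple[float, float]
    phases: list[tuple[str, float, float]]
    rating_times: list[float] = field(default_factory=list)
    scenario_id: str = ""
    difficulty_class: str | None = None
    experience_level: str | None = None

    def __post_init__(self) -> None:
        b0, b1 = self.baseline
        if not b1 > b0:
            raise SessionFormatError("baseline window must have positive length")
        prev_end = None
        for name, start, end in self.phases:
            if name not in PHASE_NAMES:
                raise SessionFormatError(f"unknown phase name {name!r}")
            if not end > start:
                raise SessionFormatError(f"phase {name!r} has non-positive length")
            if prev_end is not None and start < prev_end:
                raise SessionFormatError("overlapping phases")
            prev_end = end
        if self.phases and self.phases[0][1] < b1:
            raise SessionFormatError("baseline must precede the first phase")
        for t in self.rating_times:
            if self.phase_at(t) is None:
                raise SessionFormatError(
                    f"rating time {t} falls outside all phases"
                )
        if self.difficulty_class is not None and (
            self.difficulty_class not in DIFFICULTY_LEVELS
        ):
            raise SessionFormatError(
                f"difficulty_class must be one of {DIFFICULTY_LEVELS}"
            )
        if self.experience_level is not None and (
            self.experience_level not in EXPERIENCE_LEVELS
        ):
            raise SessionFormatError(
                f"experience_level must be one of {EXPERIENCE_LEVELS}"
            )

    def phase_at(self, t: float) -> str | None:
        """Name of the phase whose half-open window contains ``t``."""
        for name, start, end in self.phases:
            if start <= t < end:
                return name
        return None

    def phase_span(self, name: str) -> tuple[float, float]:
        for pname, start, end in self.phases:
            if pname == name:
                return (start, end)
        raise KeyError(name)

    @property
    def end(self) -> float:
        return self.phases[-1][2] if self.phases else self.baseline[1]


@dataclass
class RatingRecord:
    """One participant's instrument responses for one scenario."""

    participant_id: str
    borg: float | None = None
    tlx_dims: Sequence[float] | None = None
    panas_items: Sequence[float] | None = None
    timestamp: float | None = None  # None = end-of-scenario survey

    def __post_init__(self) -> None:
        for msg in self.violations():
            raise ValueError(msg)

    def violations(self) -> list[str]:
        out = []
        if self.borg is not None and not (6 <= self.borg <= 20):
            out.append(f"Borg outside 6-20: {self.borg}")
        if self.tlx_dims is not None:
            if len(self.tlx_dims) != 6:
                out.append("TLX requires exactly six dimensions")
            elif not all(0 <= v <= 100 for v in self.tlx_dims):
                out.append("TLX dimension outside 0-100")
        if self.panas_items is not None:
            if len(self.panas_items) != 20:
                out.append("PANAS requires exactly twenty items")
            elif not all(1 <= v <= 5 for v in self.panas_items):
                out.append("PANAS item outside 1-5")
        return out


@dataclass
class Session:
    """One complete dyadic session: events, two recordings, instruments."""

    session_id: str
    events: SessionEvents
    recordings: dict[str, ODRecording]
    instruments: list[RatingRecord] = field(default_factory=list)


def read_od_table(path: str | Path, schema: dict[str, str] | None = None) -> ODRecording:
    """Read an optical-density table from delimited text.

    The file has a ``# key<TAB>value`` header (participant, role, and
    optionally wavelengths) followed by a delimited table with a time
    column in seconds and two OD columns.  ``schema`` maps the logical
    names ``time``, ``od1``, ``od2`` to the file's column names; by
    default those names are used directly.

    The sampling rate is inferred from the median inter-sample interval.
    Non-monotone time stamps, or intervals deviating more than 1% from
    the median, are rejected.
    """
    schema = schema or {}
    time_col = schema.get("time", "time")
    od_cols = [schema.get("od1", "od1"), schema.get("od2", "od2")]

    meta = _read_header(path)
    df = pd.read_csv(path, sep="\t", comment="#", float_precision="round_trip")
    for col in [time_col, *od_cols]:
        if col not in df.columns:
            raise SessionFormatError(f"missing column {col!r} in {path}")

    t = df[time_col].to_numpy(dtype=float)
    if t.size < 2:
        raise SessionFormatError("OD table needs at least two samples")
    dt = np.diff(t)
    if np.any(dt <= 0):
        raise SessionFormatError("non-monotone time column")
    med = float(np.median(dt))
    if np.max(np.abs(dt - med)) > 0.01 * med:
        raise SessionFormatError(
            "irregular sampling: inter-sample interval deviates >1% from median"
        )

    wavelengths = None
    if "wavelengths_nm" in meta:
        wavelengths = tuple(float(v) for v in meta["wavelengths_nm"].split(","))

    # a declared rate (written by write_od_table) round-trips exactly;
    # otherwise fall back to the median-interval estimate
    sample_rate = float(meta["sample_rate"]) if "sample_rate" in meta else 1.0 / med

    return ODRecording(
        participant_id=meta.get("participant", Path(path).stem),
        role=meta.get("role", "initial_provider"),
        od=df[od_cols].to_numpy(dtype=float),
        sample_rate=sample_rate,
        t0=float(t[0]),
        wavelengths=wavelengths,
    )


def write_od_table(rec: ODRecording, path: str | Path) -> None:
    """Write an :class:`ODRecording` in the dialect :func:`read_od_table` reads."""
    with open(path, "w") as fh:
        fh.write(f"# participant\t{rec.participant_id}\n")
        fh.write(f"# role\t{rec.role}\n")
        fh.write(f"# sample_rate\t{rec.sample_rate!r}\n")
        if rec.wavelengths is not None:
            fh.write(
                "# wavelengths_nm\t"
                + ",".join(repr(float(w)) for w in rec.wavelengths)
                + "\n"
            )
        df = pd.DataFrame(
            {"time": rec.times(), "od1": rec.od[:, 0], "od2": rec.od[:, 1]}
        )
        # %.17g round-trips IEEE doubles exactly
        df.to_csv(fh, sep="\t", index=False, float_format="%.17g")


def read_events(path: str | Path) -> SessionEvents:
    """Read a session-events table.

    Dialect: ``# key<TAB>value`` header for scenario metadata, then a
    tab-separated table with columns ``kind`` (baseline | phase |
    rating), ``name``, ``start``, ``end``.  Rating rows carry the rating
    time in both ``start`` and ``end``.
    """
    meta = _read_header(path)
    df = pd.read_csv(path, sep="\t", comment="#")
    for col in ("kind", "name", "start", "end"):
        if col not in df.columns:
            raise SessionFormatError(f"events file missing column {col!r}")

    baseline = None
    phases: list[tuple[str, float, float]] = []
    ratings: list[float] = []
    for row in df.itertuples(index=False):
        if row.kind == "baseline":
            baseline = (float(row.start), float(row.end))
        elif row.kind == "phase":
            phases.append((str(row.name), float(row.start), float(row.end)))
        elif row.kind == "rating":
            ratings.append(float(row.start))
        else:
            raise SessionFormatError(f"unknown event kind {row.kind!r}")
    if baseline is None:
        raise SessionFormatError("missing baseline event")

    return SessionEvents(
        baseline=baseline,
        phases=phases,
        rating_times=ratings,
        scenario_id=meta.get("scenario_id", ""),
        difficulty_class=meta.get("difficulty") or None,
        experience_level=meta.get("experience") or None,
    )


def write_events(events: SessionEvents, path: str | Path) -> None:
    with open(path, "w") as fh:
        if events.scenario_id:
            fh.write(f"# scenario_id\t{events.scenario_id}\n")
        if events.difficulty_class:
            fh.write(f"# difficulty\t{events.difficulty_class}\n")
        if events.experience_level:
            fh.write(f"# experience\t{events.experience_level}\n")
        fh.write("kind\tname\tstart\tend\n")
        b0, b1 = events.baseline
        fh.write(f"baseline\tbaseline\t{b0!r}\t{b1!r}\n")
        for name, start, end in events.phases:
            fh.write(f"phase\t{name}\t{start!r}\t{end!r}\n")
        for t in events.rating_times:
            fh.write(f"rating\trating\t{t!r}\t{t!r}\n")


def validate_session(session: Session) -> list[str]:
    """Check a session against the data-model invariants.

    Returns a list of human-readable violations; an empty list means the
    session is valid.  This is report-only — nothing is raised — so a
    batch runner can quarantine bad sessions without aborting.
    """
    report: list[str] = []
    roles = set(session.recordings)
    if roles != set(ROLES):
        report.append(
            f"exactly two roles required ({', '.join(ROLES)}); got {sorted(roles)}"
        )
    end = session.events.end
    for role, rec in session.recordings.items():
        if rec.t0 > session.events.baseline[0] or rec.t0 + rec.duration < end:
            report.append(
                f"recording for {role} does not cover baseline through "
                f"debriefing end ([{rec.t0}, {rec.t0 + rec.duration}) vs "
                f"required [{session.events.baseline[0]}, {end}))"
            )
    for rating in session.instruments:
        for msg in rating.violations():
            report.append(f"{rating.participant_id}: {msg}")
    return report


def _read_header(path: str | Path) -> dict[str, str]:
    meta: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            parts = line[1:].strip().split("\t", 1)
            if len(parts) == 2:
                meta[parts[0].strip()] = parts[1].strip()
    return meta
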