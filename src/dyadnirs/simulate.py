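"""Synthetic dyadic fNIRS sessions with known ground truth.

The generator emulates the structure of a two-person crisis-simulation
session: a 300 s seated baseline, a scenario of 10–20 min split into a
single-provider and a team phase, and a 10–25 min debriefing, recorded
as two-wavelength optical density at 100 Hz for each participant.

Each participant's latent ΔHbO is a sum of

* a phase- and role-dependent workload offset (step function),
* a 0.01–0.1 Hz band-limited process that mixes a *shared* dyadic
  component (weight = the per-phase coupling ``c``) with an independent
  component (weight ``sqrt(1 - c²)``), so the instantaneous inter-brain
  correlation of the band signal equals ``c²`` when both members share
  the same coupling,
* physiological rhythms (cardiac ~1.1 Hz, respiratory ~0.27 Hz, Mayer
  waves ~0.095 Hz) with per-participant random phases,
* random-walk drift.

ΔHbR is an anti-correlated copy (gain −0.3) with its own offsets and
noise.  The forward modified Beer–Lambert model turns concentrations
into optical density, and motion artifacts (spikes, baseline shifts)
are injected at the OD level.  Everything needed to score a pipeline
stage exactly — clean series, shared component, artifact positions,
true coupling and offsets — is returned as :class:`GroundTruth`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal

from dyadnirs.preprocess import FilterSpec, MbllParams, mbll_forward
from dyadnirs.session import (
    HbTimeSeries,
    ODRecording,
    RatingRecord,
    Session,
    SessionEvents,
    ROLES,
)

PHASES = ("single_provider", "team", "debriefing")


@dataclass
class GeneratorConfig:
    """Study-condition parameters for the session generator.

    Durations are seconds; amplitudes are in the arbitrary concentration
    units of the latent band-limited signal (unit SD).  ``coupling`` maps
    baseline and each phase to the shared-signal weight in [0, 1].
    """

    sample_rate: float = 100.0
    #: recording time before the baseline window and after the debriefing
    #: (sensors are worn from setup to debrief end); keeps the protocol
    #: windows away from the record edges where wavelet estimates are
    #: excluded anyway
    lead_in: float = 300.0
    lead_out: float = 300.0
    baseline_duration: float = 300.0
    scenario_range: tuple[float, float] = (600.0, 1200.0)  # 10-20 min
    single_provider_fraction: tuple[float, float] = (0.3, 0.5)
    debriefing_range: tuple[float, float] = (600.0, 1500.0)  # 10-25 min
    coupling: dict = field(
        default_factory=lambda: {
            "baseline": 0.0,
            "single_provider": 0.2,
            "team": 0.6,
            "debriefing": 0.4,
        }
    )
    #: (HbO, HbR) workload offsets per (role, phase), a.u.
    offsets: dict = field(
        default_factory=lambda: {
            ("initial_provider", "single_provider"): (0.8, -0.8),
            ("initial_provider", "team"): (0.8, -0.8),
            ("initial_provider", "debriefing"): (0.3, -0.3),
            ("responder", "single_provider"): (0.0, 0.0),
            ("responder", "team"): (0.8, -0.8),
            ("responder", "debriefing"): (0.3, -0.3),
        }
    )
    cardiac_amp: float = 0.4
    cardiac_hz: float = 1.1
    respiratory_amp: float = 0.3
    respiratory_hz: float = 0.27
    mayer_amp: float = 0.25
    mayer_hz: float = 0.095
    drift_rate: float = 0.05  # random-walk a.u. per sqrt(second)
    hbr_gain: float = -0.3
    hbr_noise_sd: float = 0.3
    spike_rate_per_min: float = 0.5
    spike_amp_sd: float = 8.0  # multiples of the OD column SD
    shift_rate_per_min: float = 0.1
    shift_amp_sd: float = 3.0
    band: tuple[float, float] = (0.01, 0.1)
    mbll: MbllParams = field(default_factory=MbllParams)

    def __post_init__(self) -> None:
        for v in self.coupling.values():
            if not 0 <= v <= 1:
                raise ValueError("coupling weights must lie in [0, 1]")
        if self.baseline_duration <= 0:
            raise ValueError("durations must be positive")

    @classmethod
    def compact(cls, **overrides) -> "GeneratorConfig":
        """A fixed-duration configuration for replicate-heavy simulations.

        Same signal model with the stochastic durations pinned to their
        mid-range values (600 s single-provider and team phases, 600 s
        debriefing); used where many independent replicates are averaged
        and duration variability only adds run time and variance.
        """
        cfg = cls(
            scenario_range=(1200.0, 1200.0),
            single_provider_fraction=(0.5, 0.5),
            debriefing_range=(600.0, 600.0),
        )
        return replace(cfg, **overrides)


@dataclass
class GroundTruth:
    """Everything the generator knows that the pipeline must recover."""

    clean_hb: dict  # (role, chromophore) -> np.ndarray, artifact-free
    shared_band: np.ndarray
    coupling: dict  # phase/baseline -> weight
    offsets: dict  # (role, phase) -> (hbo, hbr)
    artifact_times: dict  # role -> {"spikes": [...], "shifts": [...]} seconds
    events: SessionEvents


def band_limited_noise(
    n: int, sample_rate: float, band: tuple[float, float], rng: np.random.Generator
) -> np.ndarray:
    """Unit-SD Gaussian noise band-limited with the analysis band-pass.

    White noise filtered with the same zero-phase Butterworth the
    pipeline uses guarantees the energy sits in-band.
    """
    spec = FilterSpec(low_hz=band[0], high_hz=band[1])
    x = signal.sosfiltfilt(spec.sos(sample_rate), rng.standard_normal(n))
    sd = x.std()
    return x / sd if sd > 0 else x


def _session_events(cfg: GeneratorConfig, rng: np.random.Generator) -> SessionEvents:
    scen = rng.uniform(*cfg.scenario_range)
    frac = rng.uniform(*cfg.single_provider_fraction)
    sp = scen * frac
    debrief = rng.uniform(*cfg.debriefing_range)
    b0 = cfg.lead_in
    b1 = b0 + cfg.baseline_duration
    phases = [
        ("single_provider", b1, b1 + sp),
        ("team", b1 + sp, b1 + scen),
        ("debriefing", b1 + scen, b1 + scen + debrief),
    ]
    # observer ratings at 4-6 min intervals during the scenario
    ratings = []
    t = b1 + rng.uniform(240, 360)
    while t < b1 + scen:
        ratings.append(float(t))
        t += rng.uniform(240, 360)
    return SessionEvents(
        baseline=(b0, b1),
        phases=phases,
        rating_times=ratings,
        scenario_id="synthetic",
    )


def _physio_rhythm(
    t: np.ndarray,
    hz: float,
    fs: float,
    rng: np.random.Generator,
    phase_drift: float = 0.15,
) -> np.ndarray:
    """A narrowband physiological rhythm: sinusoid with random-walk phase.

    Real cardiac/respiratory/Mayer oscillations are narrowband noise,
    not phase-locked tones; the drifting phase (``phase_drift`` rad/√s)
    decorrelates the two participants' rhythms over a few minutes so
    that same-frequency physiology does not masquerade as inter-brain
    coherence.
    """
    phase = np.cumsum(rng.standard_normal(t.size)) * phase_drift / np.sqrt(fs)
    return np.sin(2 * np.pi * hz * t + rng.uniform(0, 2 * np.pi) + phase)


def _phase_weight(events: SessionEvents, t: np.ndarray, table: dict) -> np.ndarray:
    out = np.full(t.size, float(table.get("baseline", 0.0)))
    for name, start, end in events.phases:
        out[(t >= start) & (t < end)] = float(table.get(name, 0.0))
    return out


def generate_hyperscan_session(
    cfg: GeneratorConfig | None = None,
    seed: int | np.random.Generator = 0,
    session_id: str = "synthetic",
) -> tuple[Session, GroundTruth]:
    """Generate one dyadic session plus its ground truth.

    Deterministic given the seed: the same seed yields a bit-identical
    session.
    """
    cfg = cfg or GeneratorConfig()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    events = _session_events(cfg, rng)
    fs = cfg.sample_rate
    n = int(round((events.end + cfg.lead_out) * fs))
    t = np.arange(n) / fs

    shared = band_limited_noise(n, fs, cfg.band, rng)
    c = _phase_weight(events, t, cfg.coupling)

    clean_hb: dict = {}
    recordings: dict[str, ODRecording] = {}
    artifact_times: dict = {}
    for role in ROLES:
        indep = band_limited_noise(n, fs, cfg.band, rng)
        band_sig = c * shared + np.sqrt(1 - c ** 2) * indep

        hbo_off = _phase_weight(
            events, t, {ph: cfg.offsets[(role, ph)][0] for ph in PHASES}
        )
        hbr_off = _phase_weight(
            events, t, {ph: cfg.offsets[(role, ph)][1] for ph in PHASES}
        )

        physio = (
            cfg.cardiac_amp * _physio_rhythm(t, cfg.cardiac_hz, fs, rng)
            + cfg.respiratory_amp * _physio_rhythm(t, cfg.respiratory_hz, fs, rng)
            + cfg.mayer_amp * _physio_rhythm(t, cfg.mayer_hz, fs, rng)
        )
        drift = np.cumsum(rng.standard_normal(n)) * cfg.drift_rate / np.sqrt(fs)

        hbo = hbo_off + band_sig + physio + drift
        hbr = (
            hbr_off
            + cfg.hbr_gain * (band_sig + physio + drift)
            + cfg.hbr_noise_sd * band_limited_noise(n, fs, cfg.band, rng)
        )
        clean_hb[(role, "HbO")] = hbo
        clean_hb[(role, "HbR")] = hbr

        od = mbll_forward(hbo, hbr, cfg.mbll)
        od, arts = _inject_artifacts(od, fs, cfg, rng)
        artifact_times[role] = arts

        recordings[role] = ODRecording(
            participant_id=f"{session_id}-{role}",
            role=role,
            od=od,
            sample_rate=fs,
            t0=0.0,
        )

    session = Session(session_id=session_id, events=events, recordings=recordings)
    truth = GroundTruth(
        clean_hb=clean_hb,
        shared_band=shared,
        coupling=dict(cfg.coupling),
        offsets=dict(cfg.offsets),
        artifact_times=artifact_times,
        events=events,
    )
    return session, truth


def _inject_artifacts(
    od: np.ndarray, fs: float, cfg: GeneratorConfig, rng: np.random.Generator
) -> tuple[np.ndarray, dict]:
    n = od.shape[0]
    minutes = n / fs / 60
    out = od.copy()
    spikes, shifts = [], []
    col_sd = od.std(axis=0)

    n_spikes = rng.poisson(cfg.spike_rate_per_min * minutes)
    for _ in range(n_spikes):
        i = int(rng.integers(0, n))
        tau = rng.uniform(0.1, 0.4) * fs  # decay, samples
        length = int(min(6 * tau, n - i))
        profile = np.exp(-np.arange(length) / tau)
        sign = rng.choice([-1.0, 1.0])
        for col in range(2):
            out[i : i + length, col] += sign * cfg.spike_amp_sd * col_sd[col] * profile
        spikes.append(i / fs)

    n_shifts = rng.poisson(cfg.shift_rate_per_min * minutes)
    for _ in range(n_shifts):
        i = int(rng.integers(0, n))
        sign = rng.choice([-1.0, 1.0])
        for col in range(2):
            out[i:, col] += sign * cfg.shift_amp_sd * col_sd[col]
        shifts.append(i / fs)

    return out, {"spikes": spikes, "shifts": shifts}


def generate_spike_fixture(
    seed: int | np.random.Generator = 0,
    duration: float = 600.0,
    sample_rate: float = 100.0,
    noise_sd: float = 0.0,
    n_spikes: tuple[int, int] = (3, 10),
    spike_amp: tuple[float, float] = (5.0, 15.0),
) -> tuple[HbTimeSeries, HbTimeSeries]:
    """A (clean, contaminated) pair for scoring artifact removal.

    The clean signal is a sum of in-band sinusoids; the contaminated
    copy adds sharp exponential-decay spikes whose amplitude is
    ``spike_amp`` times the clean SD (plus optional white measurement
    noise, off by default).  Both series are in the "converted" state,
    ready for :func:`wavelet_artifact_removal`.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = int(duration * sample_rate)
    t = np.arange(n) / sample_rate
    clean = np.zeros(n)
    for _ in range(3):
        f = rng.uniform(0.02, 0.08)
        clean += rng.uniform(0.5, 1.0) * np.sin(2 * np.pi * f * t + rng.uniform(0, 2 * np.pi))
    sd = clean.std()

    contaminated = clean + noise_sd * sd * rng.standard_normal(n)
    for _ in range(int(rng.integers(*n_spikes))):
        i = int(rng.integers(0, n))
        tau = rng.uniform(0.05, 0.3) * sample_rate
        length = int(min(6 * tau, n - i))
        profile = np.exp(-np.arange(length) / tau)
        contaminated[i : i + length] += (
            rng.choice([-1.0, 1.0]) * rng.uniform(*spike_amp) * sd * profile
        )

    mk = lambda v: HbTimeSeries(
        participant_id="fixture",
        chromophore="HbO",
        values=v,
        sample_rate=sample_rate,
        state=("converted",),
    )
    return mk(clean), mk(contaminated)


def generate_lme_dataset(
    X: np.ndarray,
    groups: dict[str, np.ndarray],
    beta: np.ndarray,
    group_sds: dict[str, float],
    resid_sd: float,
    seed: int | np.random.Generator = 0,
) -> dict:
    """Simulate ``y = X b + sum_g Z_g u_g + e`` with Gaussian components.

    Returns a dict with ``y``, the drawn random-intercept vectors ``u``
    per grouping, and the residuals — the full ground truth for recovery
    tests.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    X = np.asarray(X, float)
    beta = np.asarray(beta, float)
    if np.any(np.asarray(list(group_sds.values())) < 0) or resid_sd < 0:
        raise ValueError("standard deviations must be non-negative")
    y = X @ beta
    u = {}
    for g, codes in groups.items():
        q = int(np.max(codes)) + 1
        ug = group_sds[g] * rng.standard_normal(q)
        u[g] = ug
        y = y + ug[codes]
    eps = resid_sd * rng.standard_normal(X.shape[0])
    return {"y": y + eps, "u": u, "resid": eps, "beta": beta}


def crossed_outcome_table(
    n_sessions: int = 25, seed: int | np.random.Generator = 0
) -> "pd.DataFrame":
    """Covariate table mimicking the study layout.

    ``n_sessions`` sessions x 2 roles x 3 phases, with teams nested in
    sessions, scenarios drawn from a pool, and difficulty/experience
    assigned per scenario/participant.
    """
    import pandas as pd

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    rows = []
    scenarios = [f"scn{k}" for k in range(max(3, n_sessions // 2))]
    difficulty_of = {
        s: ("low", "medium", "high")[k % 3] for k, s in enumerate(scenarios)
    }
    for s in range(n_sessions):
        team = f"team{s}"
        scenario = scenarios[int(rng.integers(0, len(scenarios)))]
        exp = ("Y1", "Y2", "Y3", "attending")[int(rng.integers(0, 4))]
        for role in ROLES:
            participant = f"{team}-{role}"
            for phase in PHASES:
                rows.append(
                    dict(
                        team=team,
                        scenario=scenario,
                        participant=participant,
                        role=role,
                        phase=phase,
                        difficulty=difficulty_of[scenario],
                        experience=exp,
                    )
                )
    return pd.DataFrame(rows)


def generate_ratings(
    session: Session,
    truth: GroundTruth,
    seed: int | np.random.Generator = 0,
    link_strength: float = 1.0,
    rater_sd: float = 0.3,
    error_sd: float = 0.3,
    target_sd: float = 1.0,
    n_scenarios: int = 10,
) -> tuple[list[RatingRecord], np.ndarray]:
    """Instrument responses plus instructor difficulty ratings.

    Borg observer ratings (one per rating timestamp) and end-of-scenario
    TLX/PANAS surveys are drawn from distributions optionally linked
    (``link_strength``) to the latent workload offsets; a
    (scenarios x 3 raters) instructor-rating matrix is drawn with the
    given target/rater/error SDs on the five-point difficulty scale.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    records: list[RatingRecord] = []

    # Borg: observer rates the initial provider at each rating time
    role = "initial_provider"
    for rt in session.events.rating_times:
        phase = session.events.phase_at(rt)
        workload = truth.offsets[(role, phase)][0]
        borg = 12 + 3 * link_strength * workload + 1.5 * rng.standard_normal()
        records.append(
            RatingRecord(
                participant_id=session.recordings[role].participant_id,
                borg=float(np.clip(borg, 6, 20)),
                timestamp=rt,
            )
        )

    # end-of-scenario self-reports for both participants
    for role in ROLES:
        workload = np.mean(
            [truth.offsets[(role, ph)][0] for ph in ("single_provider", "team")]
        )
        tlx = np.clip(
            50 + 20 * link_strength * workload + 15 * rng.standard_normal(6), 0, 100
        )
        panas = np.clip(np.rint(3 + 0.8 * rng.standard_normal(20)), 1, 5)
        records.append(
            RatingRecord(
                participant_id=session.recordings[role].participant_id,
                tlx_dims=tuple(float(v) for v in tlx),
                panas_items=tuple(float(v) for v in panas),
                timestamp=None,
            )
        )

    # instructor difficulty ratings: scenario x 3 raters on a 1-5 scale
    target = 3 + target_sd * rng.standard_normal(n_scenarios)
    rater = rater_sd * rng.standard_normal(3)
    noise = error_sd * rng.standard_normal((n_scenarios, 3))
    instructor = np.clip(target[:, None] + rater[None, :] + noise, 1, 5)
    return records, instructor
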