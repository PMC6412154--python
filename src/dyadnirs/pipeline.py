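"""End-to-end orchestration: preprocess → windows → synchrony → models.

``run_pipeline`` takes a :class:`RunConfig` (loadable from YAML),
processes every session — either read from disk or generated
synthetically — and writes tidy delimited outputs plus a reproducibility
manifest (config hash, derived seeds).  Re-running with the same config
reproduces every output bit-exactly; per-session failures are
quarantined and logged, never abort the batch.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from dyadnirs import bayes
from dyadnirs.preprocess import (
    ArtifactRemovalConfig,
    FilterSpec,
    MbllParams,
    preprocess_recording,
)
from dyadnirs.session import Session, read_events, read_od_table, validate_session
from dyadnirs.simulate import GeneratorConfig, generate_hyperscan_session
from dyadnirs.synchrony import WaveletParams, baseline_adjusted_wtc
from dyadnirs.windows import pre_rating_windows, segment_phases, window_mean

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """One run's complete configuration.

    Either ``input_dir`` (directory of ``<id>.events.tsv`` plus
    ``<id>.<role>.od.tsv`` files) or ``n_sessions`` (synthetic) must be
    set.  Every stochastic stage receives a seed derived
    deterministically from ``seed``.
    """

    out_dir: str = "results"
    input_dir: str | None = None
    n_sessions: int = 0
    seed: int = 0
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    mbll: MbllParams = field(default_factory=MbllParams)
    artifact: ArtifactRemovalConfig = field(default_factory=ArtifactRemovalConfig)
    filter: FilterSpec = field(default_factory=FilterSpec)
    wavelet: WaveletParams = field(default_factory=WaveletParams)
    mcmc: bayes.McmcSettings = field(default_factory=bayes.McmcSettings)
    models: tuple[int, ...] = (1, 5)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs = {}
        for f in dataclasses.fields(cls):
            if f.name not in raw:
                continue
            value = raw[f.name]
            if dataclasses.is_dataclass(f.type) if isinstance(f.type, type) else False:
                value = f.type(**value)
            elif f.name in ("generator", "mbll", "artifact", "filter", "wavelet", "mcmc"):
                value = {
                    "generator": GeneratorConfig,
                    "mbll": MbllParams,
                    "artifact": ArtifactRemovalConfig,
                    "filter": FilterSpec,
                    "wavelet": WaveletParams,
                    "mcmc": bayes.McmcSettings,
                }[f.name](**value)
            elif f.name == "models":
                value = tuple(value)
            kwargs[f.name] = value
        return cls(**kwargs)

    def config_hash(self) -> str:
        def default(o):
            if dataclasses.is_dataclass(o):
                return dataclasses.asdict(o)
            if isinstance(o, np.ndarray):
                return o.tolist()
            if isinstance(o, dict):
                return {str(k): v for k, v in o.items()}
            raise TypeError(type(o))

        blob = json.dumps(
            dataclasses.asdict(self),
            default=default,
            sort_keys=True,
            # dict keys may be tuples (offsets); stringify
            skipkeys=False,
            cls=_TupleKeyEncoder,
        )
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


class _TupleKeyEncoder(json.JSONEncoder):
    def default(self, o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        return super().default(o)

    def encode(self, o):
        return super().encode(_stringify_keys(o))


def _stringify_keys(o):
    if isinstance(o, dict):
        return {str(k): _stringify_keys(v) for k, v in o.items()}
    if isinstance(o, (list, tuple)):
        return [_stringify_keys(v) for v in o]
    return o


def _load_sessions(cfg: RunConfig) -> list[Session]:
    sessions = []
    if cfg.input_dir:
        root = Path(cfg.input_dir)
        for events_path in sorted(root.glob("*.events.tsv")):
            sid = events_path.name.removesuffix(".events.tsv")
            events = read_events(events_path)
            recordings = {}
            for od_path in sorted(root.glob(f"{sid}.*.od.tsv")):
                rec = read_od_table(od_path)
                recordings[rec.role] = rec
            sessions.append(Session(sid, events, recordings))
    else:
        root_seed = np.random.SeedSequence(cfg.seed)
        for i, child in enumerate(root_seed.spawn(cfg.n_sessions)):
            rng = np.random.default_rng(child)
            session, _ = generate_hyperscan_session(
                cfg.generator, seed=rng, session_id=f"S{i:03d}"
            )
            # vary difficulty/experience across synthetic sessions so the
            # statistical stage has a full design
            session.events.difficulty_class = ("low", "medium", "high")[i % 3]
            session.events.experience_level = ("Y1", "Y2", "Y3", "attending")[i % 4]
            session.events.scenario_id = f"scn{i % 5}"
            sessions.append(session)
    return sessions


def process_session(cfg: RunConfig, session: Session) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Window means and synchrony values for one session.

    Returns ``(hb_means, synchrony)`` tidy frames.
    """
    problems = validate_session(session)
    if problems:
        raise ValueError("; ".join(problems))

    events = session.events
    windows = segment_phases(events) + pre_rating_windows(events)

    processed = {
        role: preprocess_recording(
            rec, events, mbll=cfg.mbll, artifact=cfg.artifact, filt=cfg.filter
        )
        for role, rec in session.recordings.items()
    }

    hb_rows = []
    for role, series_map in processed.items():
        for chrom, series in series_map.items():
            for w in windows:
                value, missing = window_mean(series, w)
                hb_rows.append(
                    dict(
                        session=session.session_id,
                        role=role,
                        chromophore=chrom,
                        label=w.label,
                        phase=w.phase_name,
                        start=w.start,
                        end=w.end,
                        degenerate=w.degenerate,
                        mean=value,
                        missing=missing,
                        difficulty=events.difficulty_class,
                        experience=events.experience_level,
                        scenario=events.scenario_id,
                    )
                )

    sync_rows = []
    for chrom in ("HbO", "HbR"):
        values = baseline_adjusted_wtc(
            processed["initial_provider"][chrom],
            processed["responder"][chrom],
            events,
            windows,
            params=cfg.wavelet,
            session_id=session.session_id,
        )
        for v in values:
            sync_rows.append(
                dict(
                    session=v.session_id,
                    chromophore=v.chromophore,
                    label=v.window.label,
                    phase=v.window.phase_name,
                    raw=v.raw_mean,
                    baseline=v.baseline_mean,
                    adjusted=v.adjusted,
                    missing=v.missing,
                    degenerate=v.window.degenerate,
                    difficulty=events.difficulty_class,
                    experience=events.experience_level,
                    scenario=events.scenario_id,
                )
            )
    return pd.DataFrame(hb_rows), pd.DataFrame(sync_rows)


def fit_models(
    cfg: RunConfig, hb_means: pd.DataFrame, synchrony: pd.DataFrame
) -> pd.DataFrame:
    """Fit the configured analysis models and collect effect summaries."""
    out = []
    for model_id in cfg.models:
        if model_id in (1, 2):
            frames = {
                chrom: _individual_table(hb_means, chrom, segments=model_id == 2)
                for chrom in ("HbO", "HbR")
            }
        elif model_id in (5, 6):
            frames = {
                chrom: _team_table(synchrony, chrom, segments=model_id == 6)
                for chrom in ("HbO", "HbR")
            }
        else:
            raise ValueError(f"pipeline supports models 1, 2, 5, 6; got {model_id}")
        for chrom, df in frames.items():
            design = bayes.build_design(model_id, df, response="value")
            samples = bayes.fit_gibbs(
                df["value"].to_numpy(),
                design,
                dataclasses.replace(cfg.mcmc, seed=cfg.mcmc.seed + model_id),
            )
            summary = bayes.summarize_all(samples)
            summary.insert(0, "model", model_id)
            summary.insert(1, "chromophore", chrom)
            out.append(summary)
    return pd.concat(out, ignore_index=True)


def _individual_table(hb: pd.DataFrame, chrom: str, segments: bool) -> pd.DataFrame:
    labels = (
        ("first_minute", "middle_minute", "last_minute") if segments else ("phase_full",)
    )
    df = hb[(hb.chromophore == chrom) & hb.label.isin(labels) & ~hb.missing].copy()
    df["value"] = df["mean"]
    df["participant"] = df["session"] + "-" + df["role"]
    df["team"] = df["session"]
    if segments:
        df["segment"] = df["label"]
    return df.reset_index(drop=True)


def _team_table(sync: pd.DataFrame, chrom: str, segments: bool) -> pd.DataFrame:
    labels = (
        ("first_minute", "middle_minute", "last_minute") if segments else ("phase_full",)
    )
    df = sync[(sync.chromophore == chrom) & sync.label.isin(labels) & ~sync.missing].copy()
    df["value"] = df["adjusted"]
    df["team"] = df["session"]
    if segments:
        df["segment"] = df["label"]
    return df.reset_index(drop=True)


def run_pipeline(cfg: RunConfig) -> dict:
    """Run the full analysis; write outputs and a manifest to ``out_dir``.

    Returns a dict with the collected frames (``hb_means``,
    ``synchrony``, ``effects``) and the per-session failure log.
    """
    sessions = _load_sessions(cfg)
    if not sessions:
        raise ValueError("no sessions")

    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    hb_frames, sync_frames, failures = [], [], {}
    for session in sessions:
        try:
            hb, sync = process_session(cfg, session)
            hb_frames.append(hb)
            sync_frames.append(sync)
        except Exception as exc:  # quarantine, don't abort the batch
            log.error("session %s failed: %s", session.session_id, exc)
            failures[session.session_id] = str(exc)

    if not hb_frames:
        raise ValueError("every session failed preprocessing")
    hb_means = pd.concat(hb_frames, ignore_index=True)
    synchrony = pd.concat(sync_frames, ignore_index=True)
    effects = fit_models(cfg, hb_means, synchrony)

    hb_means.to_csv(out_dir / "hb_window_means.tsv", sep="\t", index=False)
    synchrony.to_csv(out_dir / "synchrony_values.tsv", sep="\t", index=False)
    effects.to_csv(out_dir / "effect_summaries.tsv", sep="\t", index=False)
    manifest = {
        "config_hash": cfg.config_hash(),
        "seed": cfg.seed,
        "n_sessions": len(sessions),
        "failures": failures,
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return {
        "hb_means": hb_means,
        "synchrony": synchrony,
        "effects": effects,
        "failures": failures,
        "manifest": manifest,
    }
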