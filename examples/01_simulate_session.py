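"""Generate one synthetic dyadic simulation session and inspect it.

Builds a two-person crisis-simulation session — 300 s seated baseline,
single-provider phase, team phase, debriefing — as 100 Hz two-wavelength
optical density for each participant, with known ground truth, and
writes it to disk in the package's delimited-text dialect.
"""

from pathlib import Path

from dyadnirs import (
    GeneratorConfig,
    generate_hyperscan_session,
    validate_session,
    write_events,
    write_od_table,
)

cfg = GeneratorConfig()
session, truth = generate_hyperscan_session(cfg, seed=7, session_id="demo")

print("session", session.session_id)
b0, b1 = session.events.baseline
print(f"  baseline  [{b0:7.1f}, {b1:7.1f})  ({b1 - b0:.0f} s)")
for name, start, end in session.events.phases:
    print(f"  {name:<16s}[{start:7.1f}, {end:7.1f})  ({end - start:.0f} s)")
print(f"  {len(session.events.rating_times)} observer rating times "
      f"(4-6 min apart): {[round(t) for t in session.events.rating_times]}")

for role, rec in session.recordings.items():
    print(f"  {role}: {rec.n_samples} OD samples at {rec.sample_rate:.0f} Hz "
          f"({rec.duration:.0f} s)")
    arts = truth.artifact_times[role]
    print(f"    injected artifacts: {len(arts['spikes'])} spikes, "
          f"{len(arts['shifts'])} baseline shifts")

print("validation report:", validate_session(session) or "clean")

out = Path("scratch/example_session")
out.mkdir(parents=True, exist_ok=True)
write_events(session.events, out / "demo.events.tsv")
for role, rec in session.recordings.items():
    write_od_table(rec, out / f"demo.{role}.od.tsv")
print(f"wrote session files to {out}/")

# The phase durations are drawn from the protocol ranges (10-20 min
# scenario, 10-25 min debriefing); the artifact counts follow the
# configured per-minute rates.  Ground truth (clean series, shared
# component, coupling weights) travels alongside for scoring.
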