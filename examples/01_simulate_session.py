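"""Generate a synthetic homing-task session and inspect its structure.

Builds a 30-trial session with one neuron of each field archetype, writes it
as a plain-text container, and prints the trial structure.  The printed
counts show the task skeleton: seven initial light trials then light/dark
alternation, one lever pose per trial within 75% of the arena radius.
"""

import tempfile
from pathlib import Path

import numpy as np

from homefield import BehaviorSpec, FieldSpec, generate_session, write_session

out_dir = Path(tempfile.gettempdir()) / "homefield_example_session"

fields = {
    "place": FieldSpec(kind="place", place_center=(10.0, 5.0), peak_rate=12.0),
    "leverdist": FieldSpec(kind="lever_distance", peak_rate=14.0),
    "anchored": FieldSpec(kind="lever_anchored", peak_rate=12.0, drift_slope=0.5),
}
session, truth = generate_session(BehaviorSpec(n_trials=30), fields, seed=1)
write_session(session, out_dir)

t = truth.trials
print(f"{len(t)} trials, {int(t.light.sum())} light / {int((~t.light).sum())} dark")
print(f"first 10 light flags: {t.light.head(10).tolist()}")
radii = [np.hypot(*p.center) for p in session.lever_poses]
print(f"lever radius range: {min(radii):.1f} - {max(radii):.1f} cm (max allowed 30)")
print(f"session duration {session.t_end / 60:.1f} min, "
      f"{len(session.positions)} position samples at {session.sample_rate:.0f} Hz")
for st in session.spikes:
    print(f"  neuron {st.neuron_id}: {st.spike_times.size} spikes")
print(f"wrote container to {out_dir}/ (positions.tsv, events.tsv, spikes/, ...)")
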