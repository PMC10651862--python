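"""Classify lever-box-anchored firing fields and compare reference frames.

A lever-anchored neuron passes all three criteria (distance peak near the
box above a time-shift null, 2D map peak > 7.5 Hz, split-half map
similarity > 0.4); a place cell fails.  The anchored cell's directional
tuning has a high mean vector length in the frame it was generated in
(cardinal) and is unchanged by rigid rotation only in the bridge/lever
frames.
"""

from homefield import (
    BehaviorSpec,
    FieldSpec,
    classify_lever_anchored,
    collect_lever_frame,
    directional_tuning,
    generate_session,
    segment_journeys,
    segment_trials,
)

fields = {
    "anchored": FieldSpec(kind="lever_anchored", peak_rate=13.0,
                          preferred_direction=60.0, concentration=3.0),
    "place": FieldSpec(kind="place", place_center=(8.0, -5.0), peak_rate=13.0),
}
session, _ = generate_session(BehaviorSpec(n_trials=50), fields, seed=6)
trials = segment_trials(session)
for tr in trials:
    segment_journeys(tr, session)

for st in session.spikes:
    res = classify_lever_anchored(session, trials, st.spike_times,
                                  n_shuffles=500, seed=0)
    print(f"{st.neuron_id:>9}: anchored={res.anchored}  "
          f"[distance peak {res.peak_distance_cm:.0f} cm near box: {res.peak_near_lever}, "
          f"map peak {res.map_peak_rate:.1f} Hz: {res.peak_rate_ok}, "
          f"split-half sim {res.split_half_similarity:.2f}: {res.split_half_stable}]")

spikes = session.spikes[0].spike_times  # the anchored neuron
print("directional tuning of the anchored cell (36 bins of 10 deg):")
for frame in ("cardinal", "bridge", "lever"):
    tun = directional_tuning(collect_lever_frame(session, trials, spikes, frame))
    print(f"  {frame:>8} frame: MVL {tun.mvl:.2f}, preferred "
          f"{tun.preferred_direction:6.1f} deg, peak {tun.peak_rate:.1f} Hz")
print("(MVL is highest in the cardinal frame, where the field was injected)")
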