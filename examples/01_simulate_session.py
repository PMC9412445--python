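"""Generate a labelled synthetic calibration session and save it.

A session alternates reading (external attention) and thinking (internal
attention): four trials of 50 s + 50 s give 400 s and, at the 10 Hz frame
rate, 4000 labelled band-power frames of 4 electrodes x 5 bands.
"""

import attngate as ag

plan = ag.make_session_plan(n_trials=4, reading_s=50.0, task_s=50.0, seed=1)
stream = ag.synthesize_bandpower(plan)
ag.sessionio.write_session("session.csv", stream, plan=plan, params=ag.GeneratorParams(), seed=1)

print(f"phases: {len(plan.phases)}, total duration: {plan.total_duration:.0f} s")
print(f"frames: {len(stream)} (10 per second)")
ext = int((stream.labels == 'external').sum())
print(f"labels: {ext} external / {len(stream) - ext} internal")
# The internal frames carry extra alpha power, strongest at TP10 — the
# statistical signature the attention classifier will learn.
d = stream.powers[stream.labels == 'internal', 3, 2].mean() - \
    stream.powers[stream.labels == 'external', 3, 2].mean()
print(f"TP10 alpha shift (internal - external): {d:+.3f} log10 units")
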