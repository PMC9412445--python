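"""Closed loop: classify a fresh session, vote, pause, schedule updates.

The pause decider requires >= 60% internal predictions over the last 4 s
(24 of 40) before suspending the simulated application's sticker updates
(scheduled every 0.3-3.0 s); updates due during a pause are deferred to
the pause's end.
"""

import attngate as ag

train_plan = ag.make_session_plan(4, 50.0, 50.0, seed=4)
model = ag.train(ag.synthesize_bandpower(train_plan))

live_plan = ag.make_session_plan(4, 50.0, 50.0, seed=5)
live = ag.synthesize_bandpower(live_plan)

log, timeline = ag.run_loop(live, model, decider=ag.DeciderConfig(), updater=ag.UpdaterParams(seed=5))
summary = ag.summarize_events(log)
print(f"session: {summary['duration_s']:.0f} s, updates fired: {summary['update_count']}")
print(f"paused {100 * summary['paused_fraction']:.1f}% of the time "
      f"in {summary['pause_block_count']} pause blocks")

blocks = ag.segment_blocks(timeline)
paused_blocks = [b for b in blocks if b.paused]
shares = ag.block_share({"p1": blocks}, paused=True)
cats = ("<3s", "3-10s", "10-30s", ">30s")
print("paused-block length shares:",
      ", ".join(f"{c}: {100*s:.0f}%" for c, s in zip(cats, shares)))
# Most pausing should fall inside thinking phases:
for tid, (r0, r1, t0, t1) in enumerate(live_plan.trial_intervals()):
    pr = ag.paused_percentage(timeline, (r0, r1))
    pt = ag.paused_percentage(timeline, (t0, t1))
    print(f"trial {tid}: paused {pr:5.1f}% of reading, {pt:5.1f}% of thinking")
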