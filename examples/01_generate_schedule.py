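"""Build one participant's counterbalanced trial schedule and check it.

The experiment is a 56-trial face pop-out paradigm with auditory cues:
trials come in pairs repeating the same sound at the same volume, pairs form
two 14-pair blocks whose volume assignments are exchanged, every one of the
224 images appears exactly once, and no image category keeps its screen
position across consecutive trials.
"""

from collections import Counter

from popgaze import generate_schedule, validate_schedule

schedule = generate_schedule(seed=1)
trials = schedule.trials

print(f"trials: {len(trials)}")
print("content counts:", dict(Counter(t.sound.content for t in trials)))
print("volume counts: ", dict(Counter(t.volume for t in trials)))
print("block sizes:   ", dict(Counter(t.block for t in trials)))
print("violations:    ", validate_schedule(schedule) or "none")

tr = trials[0]
print("\nfirst trial:", tr.sound.sound_id, tr.volume,
      f"isi={tr.isi_ms:.0f} ms", tr.positions)
# 24 social + 24 non-social + 8 silent trials; an empty violation list means
# every pairing/counterbalancing/position constraint holds.
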