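"""Build a counterbalanced Go/NoGo session schedule and inspect its arithmetic.

Two base six-step sequences are rotated into eight counterbalanced
variants; each participant practices one rotation pair.  A default session
is 4 training + 2 test blocks of 48 Go + 4 NoGo trials each.
"""

import dancedsp as d

seq_a = d.DanceSequence.from_string("←→↑↓→←")
seq_b = d.DanceSequence.from_string("→↑←↑→↓")

cb = d.build_counterbalance_set(seq_a, seq_b)
print("counterbalance set:", ", ".join(s.to_arrows() for s in cb))

pair = d.assign_participant_pair(cb, participant_index=2)
print("participant 2 practices:", pair[0].to_arrows(), "and", pair[1].to_arrows())

novel = (d.DanceSequence.from_string("LRDURL"), d.DanceSequence.from_string("DRULUR"))
session = d.schedule_session(pair, novel, participant_index=2, seed=0)

block = session.blocks[0]
print(
    f"block 0: {len(block.trials)} trials, {block.n_go} Go + {block.n_nogo} NoGo "
    f"({block.go_fraction() * 100:.0f}% Go)"
)
print(f"session: {len(session.blocks)} blocks, {session.total_go_steps()} Go steps total")
print("test-block order:", [b.familiarity for b in session.test_blocks])

# The Go/NoGo cue of a six-step trial lands 7 s into the trial:
events = d.trial_timeline(block.trials[0])
print("trial timeline:", events[0], "...", events[-1])
# -> 8 rotated sequences, 52-trial blocks at 92% Go, 1728 executed steps per
#    session, and the cue at 1000 + 6*750 + 1500 = 7000 ms.
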