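"""Segment center-of-mass velocity by dance step.

Each simulated step is a 0.3 m out-and-back smoothstep excursion of the
CoM along the stepped direction; the per-step windows are the same
cue/step marker segments as the EEG analysis, so the axis pattern of the
mean velocities mirrors the executed sequence.
"""

import warnings

import numpy as np

import dancedsp as d

warnings.simplefilter("ignore")

pair = (d.DanceSequence.from_string("LRUDRL"), d.DanceSequence.from_string("RULURD"))
novel = (d.DanceSequence.from_string("LRDURL"), d.DanceSequence.from_string("DRULUR"))
schedule = d.schedule_session(
    pair, novel, n_training=1, n_test=0, seed=6, n_go_per_seq=2, n_nogo=0
)
params = d.SimParams(n_channels=1, rt_noise_sd_ms=0.0, error_prob=0.0,
                     rt_asymptote_ms=800.0, rt_gain_ms=0.0, seed=22)

sim = d.simulate_session(schedule, params)
trace = d.CoMTrace.from_stream(sim.kinematics)

vel = d.com_velocity(trace)
print(f"peak |vx| = {np.abs(vel[0]).max():.3f} m/s "
      f"(smoothstep closed form 1.5*0.3/0.4 = {1.5 * 0.3 / 0.4:.3f})")

go_trials = sorted({m.trial_index for m in sim.markers if m.label == "CUE_GO"})
k = d.segment_sequence(trace, sim.markers, go_trials[0])
seq = next(
    t.sequence for b in schedule.blocks for t in b.trials if t.is_go
)
print("sequence:", seq.to_arrows())
print("per-step mean |velocity| (m/s) by axis:")
for s in range(6):
    vx, vy, vz = k.per_step_mean_abs_velocity[s]
    print(f"  step {s + 1} ({seq.steps[s].value}): x={vx:.2f}  y={vy:.2f}  z={vz:.2f}")
print(f"peak speed over the sequence: {k.peak_speed_mps:.2f} m/s")
# Left/right steps load the x-axis, up/down steps the y-axis; the small
# z component is the vertical weight-shift bump of every step.
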