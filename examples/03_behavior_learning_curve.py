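"""Simulate four training blocks and fit the exponential RT learning curve.

Step-level response times follow asymptote + gain * exp(-decay * trial).
With 192 Go trials the curve parameters are identifiable from the noisy
per-trial means, and the session mean lands near the published pilot's
~358 ms step-level RT.
"""

import numpy as np
from scipy.optimize import curve_fit

import dancedsp as d

pair = (d.DanceSequence.from_string("LRUDRL"), d.DanceSequence.from_string("RULURD"))
novel = (d.DanceSequence.from_string("LRDURL"), d.DanceSequence.from_string("DRULUR"))
schedule = d.schedule_session(pair, novel, n_training=4, n_test=0, seed=5)

params = d.SimParams(n_channels=1, seed=123)
beh = d.simulate_behavior(schedule, params)

go = [r for r in beh.all_results if r.trial.is_go and not r.too_early]
accurate = [r for r in go if all(r.per_step_correct)]
mean_rt = np.mean([rt for r in accurate for rt in r.step_rts_ms])
print(f"{len(go)} Go trials, {len(accurate)} accurate")
print(f"mean step-level RT (accurate trials): {mean_rt:.1f} ms")

rts = np.array([np.mean(r.step_rts_ms) for r in go])
t = np.arange(len(go), dtype=float)
popt, _ = curve_fit(
    lambda t, a, g, dec: a + g * np.exp(-dec * t),
    t, rts, p0=(rts.min(), float(np.ptp(rts)), 0.01),
)
print(
    f"fitted curve: asymptote {popt[0]:.0f} ms, gain {popt[1]:.0f} ms, "
    f"decay {popt[2]:.4f}/trial"
)
print(
    f"ground truth: asymptote {params.rt_asymptote_ms:.0f} ms, "
    f"gain {params.rt_gain_ms:.0f} ms, decay {params.rt_decay_per_trial}/trial"
)

for bi, block in enumerate(beh.results_by_block):
    rt, miss = d.block_summary(block)
    print(f"block {bi}: mean RT {rt:.0f} ms, mistakes {miss:.1f}%")
# Learning shows as the block means decreasing toward the asymptote.
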