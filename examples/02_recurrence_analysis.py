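"""Recurrence-plot analysis of a periodic vs a stochastic signal.

Delay-embeds both signals, thresholds at a constant 5% recurrence rate and
prints the nine recurrence measures. A pure sinusoid shows DET = 1 (every
recurrence point lies on a long diagonal: perfectly predictable), while
white noise scatters its recurrences (DET near 0, short trapping times).
"""

import numpy as np

import neurodyn as nd
from neurodyn.recurrence import recurrence_matrix, rqa_measures, select_delay

fs = 250.0
t = np.arange(2000) / fs
signals = {
    "sine 10 Hz": np.sin(2 * np.pi * 10 * t),
    "white noise": np.random.default_rng(0).standard_normal(2000),
}

for name, x in signals.items():
    tau = max(select_delay(x, "autocorr_zero"), 2)
    traj = nd.delay_embed(x, m=3, tau=tau)
    R = recurrence_matrix(traj, target_rr=0.05, theiler=tau)
    m = rqa_measures(R, lmin=2)
    print(f"\n{name}  (tau={tau}, achieved RR={m['rr']:.4f})")
    for key in ("det", "lam", "lmean", "lmax", "lentr", "tt", "vert_ent",
                "white_vert_ent"):
        print(f"  {key:15s} {m[key]:10.4f}")
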