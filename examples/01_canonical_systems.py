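"""Generate canonical test signals and check their textbook invariants.

Builds a Lorenz trajectory, the fully chaotic logistic map, and fractional
Gaussian noise, then prints the dynamical quantities the literature gives
for them: the logistic map's Lyapunov exponent ln 2 ~ 0.693 per iteration,
the Lorenz attractor's largest exponent ~0.9 / s and correlation dimension
~2.05, and the Hurst exponent of fGn recovering its generation target.
"""

import numpy as np

import neurodyn as nd

logistic = nd.generate_system(nd.SystemSpec("logistic", {"r": 4.0, "x0": 0.3},
                                            n_samples=2000)).data[0]
lam_log = nd.lyapunov_max(logistic, m=2, tau=1)
print(f"logistic map (r=4)  lyapunov = {lam_log:.4f}   (ln 2 = {np.log(2):.4f})")

lorenz = nd.generate_system(nd.SystemSpec("lorenz", n_samples=5000,
                                          dt_or_fs=0.01)).data[0]
# for chaotic flows the 1/e autocorrelation decay is the usual delay rule;
# the first zero crossing lies far out and over-folds the attractor
tau = nd.select_delay(lorenz, "autocorr_1_over_e")
lam_lor = nd.lyapunov_max(lorenz, m=3, tau=tau, fs=100.0)
d2 = nd.correlation_dimension(lorenz, m=5, tau=tau)
print(f"lorenz x            lyapunov = {lam_lor:.3f} /s (benchmark ~0.9)")
print(f"lorenz x            corr dim = {d2:.3f}      (benchmark ~2.05)")

for h in (0.2, 0.5, 0.8):
    x = nd.generate_fgn(h, 10_000, seed=1)
    print(f"fGn H={h}           R/S estimate = {nd.hurst_rs(x):.3f}, "
          f"DFA exponent = {nd.dfa(x):.3f}")
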