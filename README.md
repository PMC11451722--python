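# neurodyn

Multiscale nonlinear dynamical invariants from multichannel
neurophysiological recordings, organized as feature tensors and mapped to
behavioral targets by supervised tensor factorization.

## The problem

A multichannel EEG recording is a set of time-series measurements of one
underlying dynamical system. By the embedding theorems, a scalar series
x(t) can be lifted into delay coordinates
(x_i, x_{i+τ}, …, x_{i+(m−1)τ}) that reconstruct the geometry of the
system's phase portrait, and quantitative properties of that geometry —
*dynamical invariants* — can be estimated directly from data. `neurodyn`
computes a standard panel of such invariants per sensor and per frequency
band, and then asks which low-dimensional combinations of them track a
subject-level variable such as age.

The pipeline is:

1. **Band decomposition** — each channel is split into dyadic frequency
   bands (fs/2^(j+1), fs/2^j] by wavelet details, reconstructed to full
   time resolution; the coarse-graining operator of multiscale-entropy
   analysis (identical to Haar approximations up to 2^(k/2)) is provided
   alongside.
2. **Dynamical measures** — per (channel, band): band power; the nine
   recurrence-plot statistics RR, DET, LAM, L_entr, L_mean, L_max, TT,
   V_entr, and the recurrence-time entropy, computed from a recurrence
   matrix R_ij = Θ(ε − ‖x_i − x_j‖) thresholded at a constant recurrence
   rate (default 0.05); sample entropy; the Grassberger–Procaccia
   correlation dimension D₂; the detrended-fluctuation exponent α; the
   rescaled-range Hurst exponent H; and the largest Lyapunov exponent λ
   (Rosenstein nearest-neighbour divergence). Recurrence networks (the
   recurrence matrix read as a graph adjacency) add clustering, efficiency
   and betweenness measures.
3. **Tensor factorization** — the values form a fourth-order tensor
   T ∈ R^(N×Ns×Nf×Nm) (subjects × sensors × bands × measures), z-scored per
   measure and decomposed as T ≈ Σ_r w_r a_r∘b_r∘c_r∘d_r (canonical
   polyadic decomposition by alternating least squares). The *supervised*
   variant minimizes
   ‖T − [[w; A,B,C,D]]‖² + γ(‖y − [A,X]β‖² + ρ‖β‖²),
   coupling the subject scores A to the target y so that components align
   with the behavioral axis; γ = 0 recovers plain CP exactly.
4. **Biomarker mapping** — per cross-validation fold the factorization is
   refit on training subjects only, held-out subjects are scored by
   least-squares projection onto the fixed non-subject factors (no target
   involved), and an ensemble regressor maps scores to the target. Pooled
   out-of-fold Pearson r and MAE are reported.

A synthetic-signal module supplies ground truth for every stage: canonical
systems (Lorenz, logistic map, sinusoids, white/pink noise, Brownian
motion, fractional Gaussian noise by circulant embedding) and an
age-graded multichannel cohort generator whose band powers and oscillatory
regularity vary monotonically with age under structured age-independent
population variability.

## Worked example

```python
import numpy as np
import neurodyn as nd

x = nd.generate_system(nd.SystemSpec("logistic", {"r": 4.0, "x0": 0.3},
                                     n_samples=2000)).data[0]
print(nd.lyapunov_max(x, m=2, tau=1))   # 0.6931  (ln 2: fully chaotic map)

lorenz = nd.generate_system(nd.SystemSpec("lorenz", n_samples=5000,
                                          dt_or_fs=0.01)).data[0]
tau = nd.select_delay(lorenz, "autocorr_1_over_e")
print(nd.correlation_dimension(lorenz, m=5, tau=tau))  # 2.096 (~2.05)
print(nd.lyapunov_max(lorenz, m=3, tau=tau, fs=100.0)) # 0.978 /s (~0.9)
```

Running `python examples/04_supervised_biomarker.py` pushes a 40-subject
synthetic cohort through the full chain and prints

```
held-out factor vs age:  supervised r = 0.84, unsupervised r = 0.80
supervised pipeline, 5-fold CV age prediction: r = 0.88 (p = 7.0e-14), MAE = 9.4 months
```

i.e. the supervised factor is a cleaner age axis than the best
unsupervised factor, and the cross-validated prediction of age from three
latent factors is accurate to about ten months. The other scripts in
`examples/` demonstrate the canonical-system oracles, recurrence
quantification, tensor assembly, and the file-based staged pipeline
(`neurodyn simulate|features|tensor|factorize|predict|all` on the command
line).

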