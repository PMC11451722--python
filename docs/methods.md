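# Methods

This note documents the models, estimators and parameter choices behind
`neurodyn`, the assumptions they rest on, and what the synthetic test data
can and cannot show about real recordings.

## Phase-space reconstruction and recurrence quantification

A scalar series is embedded in delay coordinates
v_i = (x_i, x_{i+τ}, …, x_{i+(m−1)τ}). The delay τ is chosen per series
from the autocorrelation function — the first zero crossing by default
(quarter period for narrowband signals; for broadband chaotic flows the
1/e decay rule is exposed and usually better), with the nearer of the two
bracketing lags returned so that finite-length estimates that sit a hair
above the threshold do not overshoot by one. The embedding dimension can be
fixed (default m = 3 for band-limited signals) or selected by the
false-nearest-neighbour test (neighbour false when the added coordinate
stretches the pair by a factor > 15 or beyond 2 signal SDs; fraction
threshold 5%). FNN never converges for stochastic signals; the
implementation then returns the ceiling with a warning rather than a
pretend dimension.

The recurrence matrix marks pairs with ‖v_i − v_j‖ ≤ ε. The threshold is
set in constant-recurrence-rate mode: ε is the k-th order statistic of the
pairwise distances outside the Theiler band (|i−j| ≤ θ, default θ = τ),
with k = ⌊RR·M⌋ and RR = 0.05 by default, so the achieved density matches
the target to O(1/M). The threshold comparison carries a 1e-9 relative
tolerance: for exactly periodic signals the order statistic can land
inside a round-off tie cloud whose fragmentation would otherwise split
full diagonals into spurious short lines. For continuous-valued signals
the tolerance is inert.

Line-length conventions: diagonal lines are maximal 1-runs on diagonals
with offset > θ (scanned on one triangle and doubled — the matrix is
symmetric); vertical lines are maximal 1-runs per column after zeroing the
Theiler band; white-vertical (recurrence-time) runs are maximal 0-runs per
column of the raw matrix bounded by recurrences on both ends, so censored
border runs are excluded. All entropies are Shannon entropies in nats over
the distribution of lengths ≥ lmin (lmin = 2 for black structures, 1 for
recurrence times). Statistics of an empty histogram are reported as 0 and
flagged rather than NaN, keeping downstream tensors dense.

Note one structural subtlety: with τ = 1 adjacent embedded points share
samples, which inflates DET for i.i.d. noise to ≈0.57 purely by
construction; with τ ≥ 2 no samples are shared and noise shows DET ≈ 0.1.
The per-band delay selection avoids the degenerate case automatically for
band-limited signals.

## Direct complexity measures

* **Sample entropy** — −ln(A/B) over Chebyshev template matches with a
  common template count n−m for both lengths; self-matches excluded;
  r = 0.2 of the *band series* SD (bands differ in amplitude by orders of
  magnitude, so a broadband r would be meaningless), m = 2. Pair counting
  uses a k-d tree; results equal direct enumeration exactly.
* **Approximate / permutation entropy** (optional extras) — Pincus's
  construction with self-matches, and ordinal-pattern entropy with ties
  broken by order of occurrence (stable sort), normalizable by ln(order!).
* **Correlation dimension** — Grassberger–Procaccia: slope of
  log C(ε) vs log ε, radii log-spaced between the 0.1% and 50% distance
  quantiles, Theiler-excluded pairs, and the scaling region chosen as the
  contiguous window (≥ half the admissible radii) with maximal R² via a
  prefix-sum search. Long series are stride-subsampled to ≤1200 points —
  admissible because D₂ depends only on the spatial distribution of points.
* **DFA** — cumulative-sum profile, non-overlapping windows scanned from
  both ends, polynomial detrend (order 1), α from the log-log slope over
  ~16 log-spaced scales in [4, n/4]. Calibration: α = 0.5 for white noise,
  1.5 for its running sum.
* **Hurst exponent** — rescaled-range analysis over log-spaced window
  sizes with the Anis–Lloyd small-sample correction
  (H = 0.5 + slope of log R/S − log E[R/S]); the uncorrected statistic is
  biased to ≈0.55 for white noise at these lengths, the corrected
  estimator is centred at 0.5.
* **Largest Lyapunov exponent** — Rosenstein divergence curves: nearest
  neighbour outside a temporal window (mean period), mean log separation
  tracked over time, slope over the initial rise (up to 70% of the way to
  the saturation plateau; flat curves — periodic or contracting dynamics —
  are fitted whole, yielding ≈0). Distances at round-off scale are treated
  as identical points, not neighbours; exactly periodic signals would
  otherwise produce pure-noise slopes. Validated against ln 2 for the
  logistic map at r = 4 and ≈0.9/s for the standard Lorenz flow.

Per-recording extraction computes every configured measure for each
(channel, band) pair; the default panel is power + 9 recurrence measures +
sample entropy + D₂ + α + H + λ = 15 measures. O(n²) estimators run on
bounded segments (entropies and λ on leading segments of 2000 samples,
recurrence matrices on ≤1200-point stride subsamples) — estimator choices,
not recording-length limits. Failures yield a 0 placeholder plus a quality
flag; flagged cells are masked in the tensor.

## Band decomposition

Bands are dyadic wavelet detail levels reconstructed to the input length
(per-level inverse transform with all other levels zeroed), so all band
series share the time grid. Default wavelet: `sym8` with periodization
padding — orthogonal (energy conservation to <1%), near-symmetric, and
selective enough that a mid-band sinusoid keeps >90% of its energy in its
level; Haar is selectable and is the wavelet for which the coarse-grain
identity (scale-2^k window means = level-k approximation / 2^(k/2)) holds
exactly and is tested. Levels are named by maximal overlap with the
clinical bands (delta…gamma2) with generic `d<j>` fallbacks on collision.
The final approximation is kept separately and excluded from the default
band set.

## Tensor factorization

The 4-way tensor is z-scored per measure slice (measures span incompatible
scales; the transform is stored and invertible; constant slices are zeroed
and recorded). CP-ALS uses a deterministic HOSVD-style start (leading
singular vectors of each unfolding) plus seeded random restarts, keeping
the best final objective; masked cells are EM-imputed from the running
reconstruction each sweep, so they provably cannot influence the fit.
Factors are reported with unit-norm columns, weights sorted descending, and
a deterministic sign convention.

The supervised variant augments the objective with
γ(‖y − [A, X_cov]β‖² + ρ‖β‖²), alternating the coupled subject-mode update
(A(ZᵀZ + γββᵀ) = X₍₀₎Z + γrβᵀ) with a ridge refit of β. Three choices make
the coupling effective in practice, all validated on planted-component
ground truth (three strong separable nuisance components plus one weaker
target component, where supervised recovery reaches r ≈ 0.99 held-out while
unsupervised recovery is nil):

* the coupled component is warm-started from the target profile and from
  the dominant rank-1 structure of the target-covariance tensor Σ_i y_i X_i,
  so the supervision shapes the non-subject loadings from the first sweep;
* γ defaults to 10× the observed cells per subject — large enough that the
  prediction term reshapes loadings rather than being absorbed;
* β is strongly shrunk (ρ = 10 on the standardized target), which prevents
  the coupling from being satisfied by inflating β on noise directions.

γ = 0 reduces bit-exactly to the unsupervised path. Out-of-sample subjects
are scored by least-squares projection of their (masked) feature slices
onto the weighted Khatri–Rao basis of the non-subject factors; training
subjects are *re-scored by the same projection* before any downstream
regression, so the regressor sees identically-distributed features on both
sides and the held-out side never touches a target.

## Biomarker mapping

`cv_regress` evaluates fixed scores by shuffled k-fold CV (disjoint,
exhaustive, seeded) with random-forest / gradient-boosting / linear
regressors (200 trees or estimators, fixed seeds). The full protocol
(`crossval_factor_regression`) refits the factorization inside each
training fold. Two summaries are exposed: the pooled out-of-fold
prediction r with MAE in target units (with per-fold correlations also
reported), and `crossval_factor_correlation`, the pooled held-out
correlation of the single most target-aligned factor (selected and
sign-fixed on training data only) — the direct "is one latent component a
target axis" question. At N ≈ 40 a single 5-fold split carries ≈0.04
sampling noise in r, so comparative experiments should average over
repeated splits.

## The synthetic cohort

Each subject's channel is a sum over six dyadic bands of a coherent
oscillation plus an incoherent (phase-diffusing) oscillation at the same
centre frequency, plus broadband sensor noise:

    s(t) = g · Σ_b w_b(age, ch) [ sin(ω_b t + φ) + c(age) · incoh_b(t) ] + η(t)

Age effects (defaults chosen to make the cohort a *positive control* with a
recoverable effect):

* band amplitudes w_b scale linearly with normalized age — fast bands up
  (slopes 1.6 … 0.4), slow bands down (−0.6, −1.0) — the classic
  developmental redistribution of band power;
* the incoherent-to-coherent ratio c rises with age (slope 2.0), raising
  in-band complexity;
* the phase-diffusion rate of the incoherent component *falls* with age
  (slope 1.2 on the log), i.e. rhythms become more regular with
  maturation — this is the dial the entropy/determinism measures are most
  sensitive to;
* both effects are spatially graded across the montage in opposite
  directions (gradient strength 0.7), so no single spatial pattern carries
  the whole effect.

Age-independent population variability, all scaled by `noise_sd`
(default 0.2): a log-normal per-subject gain; per-band amplitude jitter; a
spectral-curvature latent (alpha-prominence-like band pattern, loadings
±3); a noise-mixture latent; a regularity latent; and a sensor-noise-level
latent. These structured latents are what an unsupervised factorization
locks onto. With `noise_sd = 0` every band statistic is a deterministic
monotone function of age (tested). Randomness flows from one seed through
a named stream per subject, so any subject's recording is invariant under
cohort resizing. Latent draws are recorded in recording metadata, which is
how the variance budget of the design was measured and set.

What the generator does *not* emulate: volume conduction and realistic
spatial covariance, eyeblink/EMG artifacts, line noise, non-stationary
state changes, or any preprocessing chain. Passing recovery tests on this
cohort shows the *pipeline* is sound — features carry the constructed
effects and supervised factorization finds them without leakage — not that
any particular clinical effect is detectable in real EEG.

## Study sizes used by the test suite

The end-to-end recovery experiment uses 10 cohorts (seeds 0–9) of N = 40
subjects, 6 channels, 64 s at 64 Hz; features with recurrence matrices
capped at 400 points; rank 3; per seed, three repeated 5-fold splits are
averaged for both the supervised and unsupervised arms. Reference-quantity
computations use the canonical settings stated in their docstrings (8 s
sinusoid at 250 Hz; twenty 10⁴-sample noise series; 2000 Lorenz samples).

## Known limitations

* Estimator variance of the nonlinear measures on minute-scale recordings
  is substantial; at N = 40 it bounds how well any predictor — latent
  factors included — can recover the cohort's age signal, and the
  factorization pipeline operates close to that bound.
* The supervised advantage over unsupervised factorization is large when
  population nuisance dominates the variance spectrum and modest when the
  target effect is itself the dominant variance direction; both regimes
  occur across cohort draws.
* ε-motif densities are not implemented (hook only); weighted/directed
  recurrence networks and multivariate joint recurrence plots are out of
  scope.
* The fixed-RR quantile is exact (full off-diagonal distance sort), capped
  by the recurrence-point subsampling rather than block processing.
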