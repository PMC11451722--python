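"""Synthetic dynamical systems, stochastic processes, and an age-modulated
multichannel cohort generator.

Two kinds of test signal are produced here. Canonical dynamical systems
(Lorenz, logistic map, sine) and stochastic processes (white/pink noise,
Brownian motion, fractional Gaussian noise) give ground-truth inputs whose
dynamical invariants are known analytically or from the literature. The
cohort generator builds a set of EEG-like multichannel recordings whose
band-wise oscillation power and noise mixture vary monotonically with a
latent subject variable (age in months), so the full
features -> tensor -> factorization -> regression chain can be exercised and
validated end to end without access to any clinical data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import MONTAGE_10_20, Recording

_DETERMINISTIC = {"lorenz", "logistic", "sine"}
_STOCHASTIC = {"white_noise", "pink_noise", "brownian", "fgn"}


@dataclass
class SystemSpec:
    """Specification of a single generator run.

    ``dt_or_fs`` is the integration step for continuous systems (Lorenz) and
    the sampling rate for sampled signals (sine, noises); for maps it is the
    per-iteration rate, conventionally 1.0.
    """

    name: str
    params: dict = field(default_factory=dict)
    n_samples: int = 1000
    dt_or_fs: float = 1.0
    initial_state: np.ndarray | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.name not in _DETERMINISTIC | _STOCHASTIC:
            raise ValueError(f"unknown system name: {self.name!r}")
        if self.n_samples < 2:
            raise ValueError("n_samples must be >= 2")
        if not np.isfinite(self.dt_or_fs) or self.dt_or_fs <= 0:
            raise ValueError("dt_or_fs must be positive and finite")
        for k, v in self.params.items():
            if not np.all(np.isfinite(v)):
                raise ValueError(f"parameter {k!r} is not finite")
        if self.name in _STOCHASTIC and self.seed is None:
            raise ValueError(f"stochastic system {self.name!r} requires a seed")


def generate_system(spec: SystemSpec) -> Recording:
    """Generate the series described by ``spec`` as a :class:`Recording`."""
    gen = {
        "lorenz": _gen_lorenz,
        "logistic": _gen_logistic,
        "sine": _gen_sine,
        "white_noise": _gen_white,
        "pink_noise": _gen_pink,
        "brownian": _gen_brownian,
        "fgn": _gen_fgn_rec,
    }[spec.name]
    return gen(spec)


def _gen_lorenz(spec: SystemSpec) -> Recording:
    p = spec.params
    sigma = p.get("sigma", 10.0)
    rho = p.get("rho", 28.0)
    beta = p.get("beta", 8.0 / 3.0)
    dt = spec.dt_or_fs
    transient = int(p.get("transient", 1000))
    state = (np.asarray(spec.initial_state, dtype=float)
             if spec.initial_state is not None else np.array([1.0, 1.0, 1.0]))
    if state.shape != (3,):
        raise ValueError("lorenz initial_state must have 3 components")

    def deriv(s):
        x, y, z = s
        return np.array([sigma * (y - x), x * (rho - z) - y, x * y - beta * z])

    out = np.empty((spec.n_samples, 3))
    for i in range(transient + spec.n_samples):
        # fixed-step RK4
        k1 = deriv(state)
        k2 = deriv(state + 0.5 * dt * k1)
        k3 = deriv(state + 0.5 * dt * k2)
        k4 = deriv(state + dt * k3)
        state = state + (dt / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
        if i >= transient:
            out[i - transient] = state
    meta = {"system": "lorenz", "integrator": "rk4", "dt": dt,
            "transient_steps": transient,
            "params": {"sigma": sigma, "rho": rho, "beta": beta}}
    return Recording(out.T, fs=1.0 / dt, ch_names=["x", "y", "z"], meta=meta)


def _gen_logistic(spec: SystemSpec) -> Recording:
    r = spec.params.get("r", 4.0)
    if spec.initial_state is not None:
        x = float(np.asarray(spec.initial_state).ravel()[0])
    else:
        x = spec.params.get("x0", 0.3)
    out = np.empty(spec.n_samples)
    out[0] = x
    for i in range(1, spec.n_samples):
        x = r * x * (1.0 - x)
        out[i] = x
    return Recording(out[None, :], fs=spec.dt_or_fs, ch_names=["x"],
                     meta={"system": "logistic", "r": r})


def _gen_sine(spec: SystemSpec) -> Recording:
    f = spec.params.get("frequency", 10.0)
    amp = spec.params.get("amplitude", 1.0)
    phase = spec.params.get("phase", 0.0)
    fs = spec.dt_or_fs
    t = np.arange(spec.n_samples) / fs
    out = amp * np.sin(2 * np.pi * f * t + phase)
    return Recording(out[None, :], fs=fs, ch_names=["x"],
                     meta={"system": "sine", "frequency": f})


def _gen_white(spec: SystemSpec) -> Recording:
    sd = spec.params.get("sd", 1.0)
    rng = np.random.default_rng(spec.seed)
    out = rng.normal(0.0, sd, spec.n_samples)
    return Recording(out[None, :], fs=spec.dt_or_fs, ch_names=["x"],
                     meta={"system": "white_noise", "sd": sd})


def pink_noise(n: int, seed: int | np.random.Generator) -> np.ndarray:
    """1/f-amplitude Gaussian noise via spectral shaping, unit variance."""
    rng = np.random.default_rng(seed)
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n)
    scale = np.ones_like(freqs)
    scale[1:] = 1.0 / np.sqrt(freqs[1:])
    spec *= scale
    spec[0] = 0.0
    out = np.fft.irfft(spec, n)
    return out / out.std()


def _gen_pink(spec: SystemSpec) -> Recording:
    out = pink_noise(spec.n_samples, spec.seed)
    return Recording(out[None, :], fs=spec.dt_or_fs, ch_names=["x"],
                     meta={"system": "pink_noise", "method": "spectral_shaping"})


def _gen_brownian(spec: SystemSpec) -> Recording:
    rng = np.random.default_rng(spec.seed)
    out = np.cumsum(rng.standard_normal(spec.n_samples))
    return Recording(out[None, :], fs=spec.dt_or_fs, ch_names=["x"],
                     meta={"system": "brownian"})


def generate_fgn(hurst: float, n: int, seed: int) -> np.ndarray:
    """Fractional Gaussian noise by Davies-Harte circulant embedding.

    Returns a zero-mean, unit-variance Gaussian series whose autocovariance
    is gamma(k) = (|k+1|^2H - 2|k|^2H + |k-1|^2H)/2, the increment process of
    fractional Brownian motion with Hurst exponent ``hurst``. Exact in
    distribution when the circulant embedding is non-negative definite (the
    case for all H in (0,1) at practical lengths); tiny negative eigenvalues
    from round-off are clipped.
    """
    if not 0.0 < hurst < 1.0:
        raise ValueError("hurst must lie strictly between 0 and 1")
    k = np.arange(n)
    gamma = 0.5 * (np.abs(k + 1) ** (2 * hurst)
                   - 2 * np.abs(k) ** (2 * hurst)
                   + np.abs(k - 1) ** (2 * hurst))
    # first row of the 2n-size circulant embedding
    row = np.concatenate([gamma, [0.0], gamma[1:][::-1]])
    eig = np.fft.fft(row).real
    eig = np.clip(eig, 0.0, None)
    rng = np.random.default_rng(seed)
    z = rng.standard_normal(2 * n) + 1j * rng.standard_normal(2 * n)
    w = np.fft.fft(np.sqrt(eig / (4 * n)) * z)
    out = w[:n].real * np.sqrt(2.0)
    return out


def _gen_fgn_rec(spec: SystemSpec) -> Recording:
    hurst = spec.params.get("hurst", 0.5)
    out = generate_fgn(hurst, spec.n_samples, spec.seed)
    return Recording(out[None, :], fs=spec.dt_or_fs, ch_names=["x"],
                     meta={"system": "fgn", "hurst": hurst,
                           "method": "davies_harte_circulant_embedding"})


# ---------------------------------------------------------------------------
# Synthetic cohort
# ---------------------------------------------------------------------------

#: Default per-band age-effect slopes on oscillation amplitude, ordered from
#: the highest-frequency band (d1) down. Positive slopes for fast rhythms and
#: negative for slow ones mirror the developmental shift of EEG power from
#: delta/theta toward alpha/beta/gamma with maturation.
DEFAULT_EFFECT_MODEL = {
    "d1": {"power": 1.6},
    "d2": {"power": 1.2},
    "d3": {"power": 0.8},
    "d4": {"power": 0.4},
    "d5": {"power": -0.6},
    "d6": {"power": -1.0},
    "noise": {"complexity": 2.0, "regularity": 1.2},
}

#: Baseline oscillation amplitudes per band (1/f-like: slow bands larger).
_BASE_AMPLITUDE = [0.35, 0.45, 0.6, 0.8, 1.05, 1.4]

#: Loadings of the age-independent spectral-tilt nuisance factor (fast bands
#: up when slow bands down) and gain of the complexity nuisance factor, both
#: multiplied by noise_sd. At the default noise_sd these latents carry more
#: between-subject variance than the age effect.
_TILT_PATTERN = np.array([3.0, 0.0, -3.0, -3.0, 0.0, 3.0])
_MIX_SCALE = 1.5

#: Per-band amplitude jitter, as a fraction of noise_sd.
_BAND_JITTER_FRAC = 0.4

#: Strength of the anterior-posterior grading of the age effects.
_AGE_SPATIAL_GRADE = 0.7

#: Phase-diffusion rate of the incoherent band component, relative to the
#: band's angular frequency, and the log-scale gain of the regularity
#: nuisance latent on it.
_PHASE_DIFFUSION = 0.3
_REG_SCALE = 1.0

#: Baseline white sensor-noise amplitude and the log-scale gain of its
#: per-subject nuisance latent.
_SENSOR_NOISE_BASE = 0.5
_SENSOR_NOISE_SCALE = 2.0


@dataclass
class SyntheticCohortSpec:
    """Study conditions for the synthetic cohort.

    Defaults describe a realistic desk-scale stand-in for a developmental
    EEG study: 40 subjects, the 19-channel 10-20 montage at 250 Hz, 30 s of
    signal, ages spanning 5-84 months on a uniform grid, moderate
    between-subject nuisance variability (``noise_sd`` = 0.2).
    """

    n_subjects: int = 40
    n_channels: int = 19
    fs: float = 250.0
    duration: float = 30.0
    age_range: tuple[float, float] = (5.0, 84.0)
    effect_model: dict = field(default_factory=lambda: dict(DEFAULT_EFFECT_MODEL))
    noise_sd: float = 0.2
    seed: int = 0
    ch_names: list[str] | None = None

    def __post_init__(self) -> None:
        if self.n_subjects < 1 or self.n_channels < 1:
            raise ValueError("n_subjects and n_channels must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.ch_names is None:
            if self.n_channels > len(MONTAGE_10_20):
                raise ValueError(
                    f"n_channels={self.n_channels} exceeds the "
                    f"{len(MONTAGE_10_20)}-label 10-20 montage; pass ch_names"
                )
            self.ch_names = MONTAGE_10_20[: self.n_channels]
        elif len(self.ch_names) != self.n_channels:
            raise ValueError("ch_names length must equal n_channels")


def _band_centers(fs: float, n_bands: int) -> np.ndarray:
    """Center frequency of each dyadic band (fs/2^(j+1), fs/2^j], j=1..Nf."""
    j = np.arange(1, n_bands + 1)
    return 0.75 * fs / 2.0 ** j


def generate_cohort(spec: SyntheticCohortSpec) -> tuple[list[Recording], pd.DataFrame]:
    """Generate the synthetic cohort.

    Each channel is a mixture of one band-limited oscillation per dyadic
    band and 1/f (pink) noise:

        s(t) = g_i * [ sum_b w_b(age) * sin(2*pi*f_b*t + phi) + c(age) * pink(t) ]

    where w_b(age) = base_b * (1 + k_b * a) with a the age scaled to [0, 1]
    and k_b the band's effect slope, and c(age) = (1 + k_c * a) scales the
    noise mixture (complexity rises with age). ``noise_sd`` controls
    age-independent nuisance, emulating a population whose dynamical
    variability is large independently of the target: a log-normal
    per-subject gain g_i, additive per-subject band-amplitude jitter, and —
    dominating the between-subject variance at the default setting — two
    structured latent factors shared across channels, a spectral-tilt
    factor z1 that shifts amplitude between slow and fast bands and a
    complexity factor z2 that scales the noise-to-oscillation mixture.
    These structured factors are what an unsupervised factorization locks
    onto, so recovering the age component requires supervision. With
    ``noise_sd = 0`` every band statistic is a deterministic monotone
    function of age.

    Randomness flows from ``spec.seed`` through one named stream per subject
    (``SeedSequence(seed).spawn``), so subject k's recording is identical
    regardless of cohort size.
    """
    n_bands = 6
    centers = _band_centers(spec.fs, n_bands)
    slopes = np.array([
        spec.effect_model.get(f"d{j + 1}", {}).get("power", 0.0)
        for j in range(n_bands)
    ])
    k_c = spec.effect_model.get("noise", {}).get("complexity", 0.0)
    k_reg = spec.effect_model.get("noise", {}).get("regularity", 0.0)
    n = int(round(spec.fs * spec.duration))
    t = np.arange(n) / spec.fs
    ages = np.linspace(spec.age_range[0], spec.age_range[1], spec.n_subjects)
    a_norm = (ages - spec.age_range[0]) / max(
        spec.age_range[1] - spec.age_range[0], 1e-12)

    streams = np.random.SeedSequence(spec.seed).spawn(spec.n_subjects)
    # fixed spawn key: the shared realization is independent of cohort size
    shared_realization = np.random.SeedSequence(spec.seed,
                                                spawn_key=(2 ** 20,))
    recs: list[Recording] = []
    sexes = []
    for i in range(spec.n_subjects):
        rng = np.random.default_rng(streams[i])
        # population randomness (latents, jitter) is per subject; the signal
        # realization (phases, drifts, sensor noise) is also per subject
        # unless noise_sd = 0, where all subjects share one realization and
        # the cohort becomes a pure age sweep (strictly monotone statistics)
        rng_sig = (np.random.default_rng(shared_realization)
                   if spec.noise_sd == 0 else rng)
        a = a_norm[i]
        gain = float(np.exp(rng.normal(0.0, spec.noise_sd)))
        band_jitter = rng.normal(0.0, _BAND_JITTER_FRAC * spec.noise_sd,
                                 n_bands)
        z_tilt = float(rng.normal(0.0, spec.noise_sd))
        z_mix = float(rng.normal(0.0, spec.noise_sd))
        z_reg = float(rng.normal(0.0, spec.noise_sd))
        z_sens = float(rng.normal(0.0, spec.noise_sd))
        sens_amp = _SENSOR_NOISE_BASE * np.exp(_SENSOR_NOISE_SCALE * z_sens)
        w = np.array(_BASE_AMPLITUDE[:n_bands]) * (
            1.0 + slopes * a + band_jitter + z_tilt * _TILT_PATTERN[:n_bands])
        w = np.clip(w, 0.0, None)
        c_mix = max(1.0 + k_c * a + _MIX_SCALE * z_mix, 0.1)
        # oscillation regularity: phase-diffusion rate of the incoherent
        # (noise) component relative to each band's centre frequency;
        # rhythms grow more regular (slower diffusion) with age
        reg_fac = np.exp(_REG_SCALE * z_reg - k_reg * a)
        data = np.empty((spec.n_channels, n))
        grad = (np.linspace(-1.0, 1.0, spec.n_channels)
                if spec.n_channels > 1 else np.zeros(1))
        for ch in range(spec.n_channels):
            # age effects are spatially graded: power maturation is stronger
            # toward one end of the montage, rhythm regularisation toward the
            # other, so no single spatial pattern carries the whole effect
            w_ch = np.clip(np.array(_BASE_AMPLITUDE[:n_bands]) * (
                1.0 + slopes * a * (1.0 + _AGE_SPATIAL_GRADE * grad[ch])
                + band_jitter + z_tilt * _TILT_PATTERN[:n_bands]), 0.0, None)
            reg_ch = reg_fac * np.exp(
                k_reg * a * _AGE_SPATIAL_GRADE * grad[ch])
            sig = np.zeros(n)
            for b in range(n_bands):
                phase = rng_sig.uniform(0.0, 2 * np.pi)
                fjit = centers[b] * (1.0 + 0.02 * rng_sig.standard_normal())
                omega = 2 * np.pi * fjit / spec.fs
                coherent = np.sin(omega * np.arange(n) + phase)
                # band-limited incoherent oscillation: same centre frequency,
                # diffusing phase -> the in-band noise floor. Its relative
                # weight c_mix is band-independent, so complexity measures
                # respond with a band-uniform (separable) signature.
                drift = np.cumsum(rng_sig.normal(
                    0.0, _PHASE_DIFFUSION * reg_ch * omega, n))
                incoherent = np.sin(omega * np.arange(n)
                                    + rng_sig.uniform(0.0, 2 * np.pi) + drift)
                sig += w_ch[b] * (coherent + c_mix * incoherent)
            sig += sens_amp * rng_sig.standard_normal(n)
            data[ch] = gain * sig
        sex = int(rng.integers(0, 2))
        sexes.append(sex)
        recs.append(Recording(
            data, fs=spec.fs, ch_names=list(spec.ch_names),
            meta={"subject_id": f"sub-{i:03d}", "age_months": float(ages[i]),
                  "sex": sex, "cohort_seed": spec.seed,
                  "latents": {"gain": gain, "tilt": z_tilt, "mix": z_mix,
                              "regularity": z_reg, "sensor": z_sens,
                              "band_jitter": band_jitter.tolist()}}))
    cohort = pd.DataFrame({
        "subject_id": [r.meta["subject_id"] for r in recs],
        "age_months": ages,
        "sex": sexes,
    })
    return recs, cohort
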