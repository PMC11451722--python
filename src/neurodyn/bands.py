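"""Multiscale frequency decomposition by wavelet details and coarse-graining.

A discrete wavelet transform splits a signal sampled at ``fs`` into dyadic
detail levels: level j nominally spans (fs/2^(j+1), fs/2^j]. Each detail is
reconstructed back to the full-length time grid so downstream dynamical
measures operate on equal-length series. The multiscale-entropy
coarse-graining operator (non-overlapping window means) is provided too: at
dyadic scales it coincides with the Haar approximation coefficients up to
the 2^(k/2) orthonormal scaling, which ties "scales" to frequency bands.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pywt

#: Clinical EEG band ranges in Hz used to name dyadic levels by overlap.
CLINICAL_BANDS = {
    "delta": (0.5, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 13.0),
    "beta": (13.0, 30.0),
    "gamma1": (30.0, 60.0),
    "gamma2": (60.0, 150.0),
}

_MIN_BAND_FLOOR_HZ = 0.5


@dataclass
class BandSignals:
    """Per-band full-length series for one channel.

    ``bands`` maps band name -> (series, (f_lo, f_hi)) ordered from the
    highest-frequency band downward. ``approximation`` is the residual
    low-pass component below the last detail level.
    """

    source_channel: str
    fs: float
    bands: dict = field(default_factory=dict)
    approximation: np.ndarray | None = None
    method: str = "wavelet_details"
    wavelet: str = "sym8"

    @property
    def names(self) -> list[str]:
        return list(self.bands)

    def series(self, name: str) -> np.ndarray:
        return self.bands[name][0]

    def freq_range(self, name: str) -> tuple[float, float]:
        return self.bands[name][1]


def coarse_grain(series: np.ndarray, scale: int) -> np.ndarray:
    """Non-overlapping window means at the given scale.

    Output element j is the mean of samples [j*scale, (j+1)*scale); a
    trailing remainder shorter than ``scale`` is dropped, so the output has
    floor(n/scale) elements.
    """
    x = np.asarray(series, dtype=float)
    if scale < 1 or int(scale) != scale:
        raise ValueError("scale must be a positive integer")
    if x.size == 0:
        raise ValueError("empty series")
    if x.size < scale:
        raise ValueError(f"series of length {x.size} shorter than scale {scale}")
    scale = int(scale)
    n_win = x.size // scale
    return x[: n_win * scale].reshape(n_win, scale).mean(axis=1)


def dwt_decompose(series: np.ndarray, wavelet: str = "haar",
                  levels: int = 6) -> tuple[np.ndarray, list[np.ndarray]]:
    """Multilevel DWT returning (approximation, [detail_1 ... detail_L]).

    Detail level j nominally spans the band (fs/2^(j+1), fs/2^j]. Uses
    periodization padding so orthogonal wavelets conserve energy exactly on
    dyadic lengths. Perfect reconstruction holds: ``waverec`` of the parts
    reproduces the input to round-off.
    """
    x = np.asarray(series, dtype=float)
    if levels < 1:
        raise ValueError("levels must be >= 1")
    if x.size < 2 ** levels:
        raise ValueError(
            f"series of length {x.size} too short for {levels} levels")
    coeffs = pywt.wavedec(x, wavelet, mode="periodization", level=levels)
    approx, details_coarse_first = coeffs[0], coeffs[1:]
    return approx, details_coarse_first[::-1]  # fine (level 1) first


def reconstruct_level(series_len: int, coeffs_all: list, which: int,
                      wavelet: str) -> np.ndarray:
    """Inverse transform keeping only one part (0 = approximation,
    j >= 1 = detail level j counted coarse-to-fine as stored by wavedec)."""
    kept = [c if i == which else np.zeros_like(c)
            for i, c in enumerate(coeffs_all)]
    rec = pywt.waverec(kept, wavelet, mode="periodization")
    return rec[:series_len]


def to_band_signals(series: np.ndarray, fs: float, n_bands: int = 6,
                    method: str = "wavelet_details", wavelet: str = "sym8",
                    channel: str = "ch") -> BandSignals:
    """Split one channel into ``n_bands`` dyadic bands at full time resolution.

    Band j (j = 1 highest) is the level-j wavelet detail reconstructed to
    the input length; the final approximation (everything below the last
    band floor) is kept separately. Bands are named after the clinical EEG
    band whose range they overlap most (falling back to ``d<j>`` on
    ambiguity), ordered highest frequency first.
    """
    x = np.asarray(series, dtype=float)
    if n_bands < 1:
        raise ValueError("n_bands must be >= 1")
    if method != "wavelet_details":
        raise ValueError(f"unknown decomposition method: {method!r}")
    floor = fs / 2.0 ** (n_bands + 1)
    if floor < _MIN_BAND_FLOOR_HZ:
        raise ValueError(
            f"lowest band floor {floor:.3g} Hz below the resolvable "
            f"{_MIN_BAND_FLOOR_HZ} Hz; reduce n_bands or raise fs")
    coeffs = pywt.wavedec(x, wavelet, mode="periodization", level=n_bands)
    ranges = [(fs / 2.0 ** (j + 1), fs / 2.0 ** j) for j in range(1, n_bands + 1)]
    names = band_names(fs, n_bands)
    bands: dict = {}
    for j in range(1, n_bands + 1):
        # coeffs index: 0 approx, 1 coarsest detail (level n_bands) ... so
        # detail level j sits at index n_bands - j + 1
        rec = reconstruct_level(x.size, coeffs, n_bands - j + 1, wavelet)
        bands[names[j - 1]] = (rec, ranges[j - 1])
    approx = reconstruct_level(x.size, coeffs, 0, wavelet)
    return BandSignals(source_channel=channel, fs=fs, bands=bands,
                       approximation=approx, method=method, wavelet=wavelet)


def band_names(fs: float, n_bands: int) -> list[str]:
    """Name dyadic detail levels by maximal overlap with clinical bands."""
    names: list[str] = []
    for j in range(1, n_bands + 1):
        lo, hi = fs / 2.0 ** (j + 1), fs / 2.0 ** j
        best, best_ov = None, 0.0
        for cname, (clo, chi) in CLINICAL_BANDS.items():
            ov = max(0.0, min(hi, chi) - max(lo, clo))
            if ov > best_ov:
                best, best_ov = cname, ov
        label = best if best is not None and best not in names else f"d{j}"
        names.append(label)
    return names


def band_power(series: np.ndarray) -> float:
    """Mean squared amplitude of the series."""
    x = np.asarray(series, dtype=float)
    if x.size == 0:
        raise ValueError("empty series")
    return float(np.mean(x ** 2))
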