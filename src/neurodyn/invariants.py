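"""Complexity and chaos measures computed directly from a time series, and
the per-recording feature extractor that evaluates the full measure set on
every (channel, frequency band) pair.

The default measure set has 15 entries: band power, the nine recurrence-plot
statistics, sample entropy, correlation dimension, the detrended-fluctuation
exponent, the rescaled-range Hurst exponent, and the largest Lyapunov
exponent. Approximate and permutation entropy are available but off by
default. Every measure is deterministic given the series and its parameters;
degenerate inputs yield a finite 0 placeholder plus a quality flag rather
than NaN so that downstream tensors stay dense.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from scipy.spatial.distance import cdist

from . import bands as _bands
from . import recurrence as _rec
from .io import Recording


class DegenerateSeriesError(ValueError):
    """The input admits no meaningful value for the requested measure."""


# ---------------------------------------------------------------------------
# Entropy family
# ---------------------------------------------------------------------------

def _template_matrix(x: np.ndarray, m: int) -> np.ndarray:
    n = x.size - m + 1
    idx = np.arange(n)[:, None] + np.arange(m)[None, :]
    return x[idx]


def sample_entropy(series: np.ndarray, m: int = 2, r: float = 0.2) -> float:
    """Sample entropy: -ln of the conditional probability that templates
    matching for m points (within Chebyshev tolerance) still match at m+1.

    ``r`` is a fraction of the series standard deviation. Self-matches are
    excluded. Both template lengths use the same n-m template count so the
    ratio is a true conditional probability. If no m-template pair matches
    (or no pair survives at m+1) the value is undefined; 0 is returned with
    a warning, consistent with the dense-output convention.
    """
    x = np.asarray(series, dtype=float)
    if x.size <= m + 1:
        raise ValueError(f"series of length {x.size} too short for m={m}")
    r_abs = r * x.std()
    n_templates = x.size - m  # common count for both lengths
    tm = _template_matrix(x, m)[:n_templates]
    tm1 = _template_matrix(x, m + 1)
    b = _match_pairs(tm, r_abs)
    a = _match_pairs(tm1, r_abs)
    if b == 0 or a == 0:
        warnings.warn("sample entropy undefined (no template matches); "
                      "returning 0")
        return 0.0
    return float(-np.log(a / b))


def _match_pairs(templates: np.ndarray, r_abs: float) -> int:
    # unordered pairs (i < j) with Chebyshev distance <= r_abs
    tree = cKDTree(templates)
    total = tree.count_neighbors(tree, r_abs, p=np.inf)
    return int((total - templates.shape[0]) // 2)


def approximate_entropy(series: np.ndarray, m: int = 2, r: float = 0.2) -> float:
    """Approximate entropy (Pincus): phi_m - phi_{m+1} with self-matches
    included, r a fraction of the series SD."""
    x = np.asarray(series, dtype=float)
    if x.size <= m + 1:
        raise ValueError(f"series of length {x.size} too short for m={m}")
    r_abs = r * x.std()

    def phi(mm: int) -> float:
        tm = _template_matrix(x, mm)
        d = cdist(tm, tm, metric="chebyshev")
        c = (d <= r_abs).mean(axis=1)  # self-match included
        return float(np.mean(np.log(c)))

    return phi(m) - phi(m + 1)


def permutation_entropy(series: np.ndarray, order: int = 3, delay: int = 1,
                        normalize: bool = False) -> float:
    """Shannon entropy (nats) of the ordinal-pattern distribution.

    Ties are broken by order of occurrence (stable sort), so the measure is
    deterministic on discrete-valued data. With ``normalize`` the value is
    divided by ln(order!) to land in [0, 1].
    """
    x = np.asarray(series, dtype=float)
    n_pat = x.size - (order - 1) * delay
    if n_pat < 1:
        raise ValueError("series too short for the requested order and delay")
    idx = np.arange(n_pat)[:, None] + delay * np.arange(order)[None, :]
    patterns = np.argsort(x[idx], axis=1, kind="stable")
    _, counts = np.unique(patterns, axis=0, return_counts=True)
    p = counts / counts.sum()
    h = float(-(p * np.log(p)).sum())
    if normalize:
        h /= float(np.log(float(math.factorial(order))))
    return h


# ---------------------------------------------------------------------------
# Correlation dimension (Grassberger-Procaccia)
# ---------------------------------------------------------------------------

def correlation_dimension(series: np.ndarray, m: int = 5, tau: int = 1,
                          radii: np.ndarray | None = None,
                          theiler: int | None = None,
                          max_points: int = 1200,
                          min_count: int = 10) -> float:
    """Correlation dimension D2 by the Grassberger-Procaccia algorithm.

    The correlation sum C(eps) — the fraction of embedded point pairs
    (Theiler-excluded) closer than eps — scales as eps^D2 on the attractor.
    D2 is the slope of log C vs log eps over an automatically selected
    scaling region: among all windows of at least half the admissible radii,
    the one with the best linear fit (highest R^2) is used. Long series are
    subsampled by a deterministic stride to cap the O(n^2) pair count.

    Raises :class:`DegenerateSeriesError` when no scaling region exists.
    """
    traj = _rec.delay_embed(np.asarray(series, float), m, tau)
    pts = traj.points
    if pts.shape[0] > max_points:
        stride = int(np.ceil(pts.shape[0] / max_points))
        pts = pts[::stride]
    theiler = tau if theiler is None else theiler
    n = pts.shape[0]
    d = cdist(pts, pts)
    i, j = np.triu_indices(n, k=theiler + 1)
    dists = d[i, j]
    dists = dists[dists > 0]
    if dists.size < 100:
        raise DegenerateSeriesError("too few distinct point pairs")
    if radii is None:
        lo = np.quantile(dists, 0.001)
        hi = np.quantile(dists, 0.5)
        if lo <= 0 or hi <= lo:
            raise DegenerateSeriesError("degenerate distance distribution")
        radii = np.logspace(np.log10(lo), np.log10(hi), 24)
    counts = np.searchsorted(np.sort(dists), radii, side="right")
    valid = counts >= min_count
    if valid.sum() < 4:
        raise DegenerateSeriesError("no scaling region (too few radii with "
                                    "enough pairs)")
    log_r = np.log(radii[valid])
    log_c = np.log(counts[valid] / dists.size)
    return _best_window_slope(log_r, log_c, min_len=max(4, valid.sum() // 2))


def _best_window_slope(x: np.ndarray, y: np.ndarray, min_len: int) -> float:
    """Slope of the contiguous window (length >= min_len) with max R^2,
    via prefix sums (O(1) per candidate window)."""
    n = x.size
    cx, cy = np.concatenate([[0.0], np.cumsum(x)]), np.concatenate([[0.0], np.cumsum(y)])
    cxx = np.concatenate([[0.0], np.cumsum(x * x)])
    cyy = np.concatenate([[0.0], np.cumsum(y * y)])
    cxy = np.concatenate([[0.0], np.cumsum(x * y)])
    best_slope, best_r2 = 0.0, -np.inf
    for start in range(0, n - min_len + 1):
        for stop in range(start + min_len, n + 1):
            k = stop - start
            sx = cx[stop] - cx[start]
            sy = cy[stop] - cy[start]
            sxx = cxx[stop] - cxx[start]
            syy = cyy[stop] - cyy[start]
            sxy = cxy[stop] - cxy[start]
            vxx = sxx - sx * sx / k
            vyy = syy - sy * sy / k
            vxy = sxy - sx * sy / k
            if vxx <= 0 or vyy <= 0:
                continue
            r2 = vxy * vxy / (vxx * vyy)
            if r2 > best_r2:
                best_r2, best_slope = r2, vxy / vxx
    return float(best_slope)


# ---------------------------------------------------------------------------
# DFA and Hurst
# ---------------------------------------------------------------------------

def dfa(series: np.ndarray, scales: np.ndarray | None = None,
        order: int = 1) -> float:
    """Detrended fluctuation exponent alpha.

    The series is integrated (cumulative sum of deviations from the mean),
    split into non-overlapping windows of each scale (scanned from both
    ends), detrended per window by a polynomial of the given order, and the
    RMS residual F(s) is regressed on the scale in log-log coordinates.
    alpha = 0.5 for uncorrelated noise, 1.5 for its running sum.
    """
    x = np.asarray(series, dtype=float)
    n = x.size
    if scales is None:
        scales = np.unique(np.floor(
            np.logspace(np.log10(4), np.log10(n // 4), 16)).astype(int))
    scales = np.asarray(scales, dtype=int)
    if scales.size < 4:
        raise ValueError("need at least 4 scales")
    if scales.max() > n // 4:
        raise ValueError("largest scale exceeds n/4")
    profile = np.cumsum(x - x.mean())
    flucts = []
    used_scales = []
    for s in scales:
        n_win = n // s
        if n_win < 2:
            continue
        segs = []
        for arr in (profile[: n_win * s], profile[n - n_win * s:]):
            w = arr.reshape(n_win, s)
            t = np.arange(s)
            coef = np.polynomial.polynomial.polyfit(t, w.T, order)
            trend = np.polynomial.polynomial.polyval(t, coef)
            segs.append(np.mean((w - trend) ** 2, axis=1))
        flucts.append(np.sqrt(np.mean(np.concatenate(segs))))
        used_scales.append(s)
    if len(used_scales) < 2:
        raise ValueError("not enough usable scales")
    slope = np.polyfit(np.log(used_scales), np.log(flucts), 1)[0]
    return float(slope)


def _expected_rs(n: int) -> float:
    """Anis-Lloyd expected R/S of white noise for window size n."""
    i = np.arange(1, n)
    s = np.sum(np.sqrt((n - i) / i))
    front = (n - 0.5) / n
    return front * s / np.sqrt(n * np.pi / 2.0)


def hurst_rs(series: np.ndarray, window_sizes: np.ndarray | None = None,
             corrected: bool = True) -> float:
    """Hurst exponent by rescaled-range (R/S) analysis.

    For each window size the series is split into non-overlapping windows;
    R/S is the range of the cumulative mean-adjusted sum divided by the
    window SD, averaged over windows. H is the log-log slope. The raw R/S
    statistic is biased upward for short windows; with ``corrected`` the
    Anis-Lloyd expected white-noise R/S curve is subtracted and 0.5 added,
    which centres white noise at H = 0.5.
    """
    x = np.asarray(series, dtype=float)
    n = x.size
    if n < 256:
        raise ValueError("need at least 256 samples for R/S analysis")
    if window_sizes is None:
        window_sizes = np.unique(np.floor(
            np.logspace(np.log10(16), np.log10(n // 2), 12)).astype(int))
    rs_vals, ns = [], []
    for w in window_sizes:
        n_win = n // w
        if n_win < 1:
            continue
        segs = x[: n_win * w].reshape(n_win, w)
        mean = segs.mean(axis=1, keepdims=True)
        dev = segs - mean
        z = np.cumsum(dev, axis=1)
        rng_ = z.max(axis=1) - z.min(axis=1)
        sd = segs.std(axis=1)
        ok = sd > 0
        if not ok.any():
            continue
        rs_vals.append(float(np.mean(rng_[ok] / sd[ok])))
        ns.append(w)
    if len(ns) < 2:
        raise DegenerateSeriesError("too few usable window sizes")
    log_n = np.log2(np.asarray(ns, dtype=float))
    log_rs = np.log2(rs_vals)
    if corrected:
        log_exp = np.log2([_expected_rs(w) for w in ns])
        return float(0.5 + np.polyfit(log_n, log_rs - log_exp, 1)[0])
    return float(np.polyfit(log_n, log_rs, 1)[0])


# ---------------------------------------------------------------------------
# Largest Lyapunov exponent (Rosenstein)
# ---------------------------------------------------------------------------

def lyapunov_max(series: np.ndarray, m: int = 3, tau: int = 1,
                 fs: float = 1.0, theiler: int | None = None,
                 max_steps: int | None = None,
                 fit_range: tuple[int, int] | None = None,
                 max_ref_points: int | None = None) -> float:
    """Largest Lyapunov exponent by the Rosenstein nearest-neighbour method.

    Each embedded point is paired with its nearest neighbour outside a
    temporal exclusion window; the mean log separation <ln d(i)> is tracked
    over i steps and the exponent is the slope of its initial linear rise,
    in units of 1/s (1/iteration when fs = 1). Without an explicit
    ``fit_range`` the slope is fitted from step 1 up to the step where the
    curve first reaches 70% of its way to the saturation plateau.
    """
    x = np.asarray(series, dtype=float)
    traj = _rec.delay_embed(x, m, tau)
    pts = traj.points
    n = pts.shape[0]
    if theiler is None:
        theiler = max(tau, _mean_period(x))
    if max_steps is None:
        max_steps = min(max(20, int(0.1 * n)), n // 4)
    tree = cKDTree(pts)
    # nearest neighbour outside the temporal exclusion window; distances at
    # round-off scale are treated as identical points, not neighbours
    d_floor = 1e-8 * float(np.sqrt(np.mean(pts ** 2)) + 1e-300)
    ref = np.arange(n)
    if max_ref_points is not None and n > max_ref_points:
        ref = ref[:: int(np.ceil(n / max_ref_points))]
    nn_ref = np.full(ref.size, -1)
    k_query = min(2 * theiler + 5, n)
    while True:
        dists, idxs = tree.query(pts[ref], k=k_query)
        ok = (np.abs(idxs - ref[:, None]) > theiler) & (dists > d_floor)
        has = ok.any(axis=1)
        first = np.argmax(ok, axis=1)
        nn_ref[has] = idxs[has, first[has]]
        if has.all() or k_query >= min(n, 512):
            break
        k_query = min(n, 4 * k_query)  # exact recurrences crowd the query
    valid = nn_ref >= 0
    if not valid.any():
        raise DegenerateSeriesError("no valid nearest neighbours")
    base = ref[valid]
    nn = np.full(n, -1)
    nn[base] = nn_ref[valid]
    div = np.full((base.size, max_steps + 1), np.nan)
    for step in range(max_steps + 1):
        sel = (base + step < n) & (nn[base] + step < n)
        ii = base[sel]
        if ii.size == 0:
            break
        diff = pts[ii + step] - pts[nn[ii] + step]
        d2 = np.einsum("ij,ij->i", diff, diff)
        good = d2 > 0
        row = np.full(ii.size, np.nan)
        row[good] = 0.5 * np.log(d2[good])
        div[sel, step] = row
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        y = np.nanmean(div, axis=0)
    ok = np.isfinite(y)
    y, steps = y[ok], np.nonzero(ok)[0]
    if y.size < 4:
        raise DegenerateSeriesError("divergence curve too short")
    if fit_range is None:
        sat = np.mean(y[-max(1, y.size // 4):])
        if sat - y[0] < 0.5:
            # no exponential separation (periodic or converging dynamics):
            # the whole curve is the linear region
            lo, hi = 0, y.size - 1
        else:
            target = y[0] + 0.7 * (sat - y[0])
            above = np.nonzero(y >= target)[0]
            stop = int(above[0]) if above.size else y.size - 1
            stop = max(stop, 3)
            lo, hi = 0, stop
    else:
        lo, hi = fit_range
        hi = min(hi, y.size - 1)
    sel = (steps >= lo) & (steps <= hi)
    if sel.sum() < 2:
        raise DegenerateSeriesError("empty Lyapunov fit range")
    slope = np.polyfit(steps[sel], y[sel], 1)[0]
    return float(slope * fs)


def _mean_period(x: np.ndarray) -> int:
    """Mean period estimate from the power-spectrum mean frequency."""
    f = np.fft.rfftfreq(x.size)
    p = np.abs(np.fft.rfft(x - x.mean())) ** 2
    denom = np.sum(p[1:])
    if denom == 0:
        return 1
    mean_f = np.sum(f[1:] * p[1:]) / denom
    return max(1, int(round(1.0 / mean_f))) if mean_f > 0 else 1


# ---------------------------------------------------------------------------
# Per-recording feature extraction
# ---------------------------------------------------------------------------

#: The default 15-measure set: power + 9 RQA + 5 direct complexity measures.
DEFAULT_MEASURES = ["power"] + _rec.RQA_MEASURES + [
    "sampen", "corr_dim", "dfa", "hurst", "lyap"]

OPTIONAL_MEASURES = ["apen", "permen"]


@dataclass
class FeatureConfig:
    """Parameters of the per-recording feature extractor.

    Embedding uses a per-band delay from the autocorrelation zero crossing
    (capped so the trajectory keeps enough points) and a fixed default
    dimension m = 3; the recurrence threshold is set in fixed-recurrence-
    rate mode at ``target_rr`` (default 0.05). ``rqa_max_points`` caps the
    embedded trajectory length fed to the O(n^2) recurrence computation by
    deterministic stride subsampling.
    """

    n_bands: int = 6
    wavelet: str = "sym8"
    measures: list[str] = field(default_factory=lambda: list(DEFAULT_MEASURES))
    embed_m: int = 3
    embed_tau: int | None = None  # None -> per-band autocorrelation zero
    target_rr: float = 0.05
    lmin: int = 2
    rqa_max_points: int = 1200
    entropy_m: int = 2
    entropy_r: float = 0.2
    entropy_max_points: int = 2000
    lyap_max_points: int = 2000
    lyap_max_steps: int = 60
    lyap_ref_points: int = 400
    perm_order: int = 3
    d2_m: int = 5
    n_epochs: int = 1
    min_series_len: int = 256
    include_network: bool = False
    network_seed: int = 0

    def __post_init__(self) -> None:
        known = set(DEFAULT_MEASURES) | set(OPTIONAL_MEASURES)
        unknown = [m for m in self.measures if m not in known]
        if unknown:
            raise ValueError(f"unknown measure name(s): {unknown}")


def extract_features(recording: Recording, config: FeatureConfig | None = None
                     ) -> pd.DataFrame:
    """All configured measures for every (channel, band) of one recording.

    Returns a tidy frame with one row per (channel, band), one column per
    measure, plus a boolean ``flag_<measure>`` column marking values that had
    to fall back to the 0 placeholder (degenerate input, failed scaling
    region ...). Row count = n_channels * n_bands; value count =
    rows * len(measures).
    """
    cfg = config or FeatureConfig()
    rows = []
    for ch_name, ch_data in zip(recording.ch_names, recording.data):
        too_short = ch_data.size < cfg.min_series_len
        bs = _bands.to_band_signals(ch_data, recording.fs, cfg.n_bands,
                                    wavelet=cfg.wavelet, channel=ch_name)
        for band_name in bs.names:
            series = bs.series(band_name)
            row: dict = {"channel": ch_name, "band": band_name}
            values, flags = _epoch_averaged_measures(
                series, recording.fs, cfg, force_flag=too_short)
            row.update(values)
            row.update({f"flag_{k}": v for k, v in flags.items()})
            rows.append(row)
    return pd.DataFrame(rows)


def _epoch_averaged_measures(series: np.ndarray, fs: float,
                             cfg: FeatureConfig, force_flag: bool = False
                             ) -> tuple[dict, dict]:
    """Average each measure over ``cfg.n_epochs`` equal disjoint epochs.

    Epoch averaging reduces the realization variance of the estimators (the
    standard practice for EEG features); a value is flagged only when it is
    degenerate in every epoch."""
    n_ep = max(1, int(cfg.n_epochs))
    if n_ep == 1:
        return _measures_for_series(series, fs, cfg, force_flag=force_flag)
    ep_len = series.size // n_ep
    acc: dict[str, list[float]] = {}
    flg: dict[str, bool] = {}
    for e in range(n_ep):
        seg = series[e * ep_len: (e + 1) * ep_len]
        vals, flags = _measures_for_series(seg, fs, cfg,
                                           force_flag=force_flag)
        for k, v in vals.items():
            if not flags[k]:
                acc.setdefault(k, []).append(v)
            flg.setdefault(k, True)
            flg[k] = flg[k] and flags[k]
    out = {k: (float(np.mean(acc[k])) if not flg[k] else 0.0) for k in flg}
    return out, flg


def _measures_for_series(series: np.ndarray, fs: float, cfg: FeatureConfig,
                         force_flag: bool = False
                         ) -> tuple[dict[str, float], dict[str, bool]]:
    values: dict[str, float] = {}
    flags: dict[str, bool] = {}

    def put(name: str, fn) -> None:
        if name not in cfg.measures:
            return
        if force_flag:
            values[name], flags[name] = 0.0, True
            return
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                v = float(fn())
            if not np.isfinite(v):
                raise DegenerateSeriesError("non-finite value")
            values[name], flags[name] = v, False
        except (DegenerateSeriesError, ValueError):
            values[name], flags[name] = 0.0, True

    put("power", lambda: _bands.band_power(series))

    rqa_wanted = [m for m in _rec.RQA_MEASURES if m in cfg.measures]
    if rqa_wanted or cfg.include_network:
        try:
            rqa_vals, net_vals = _rqa_block(series, cfg)
            for name in rqa_wanted:
                values[name], flags[name] = rqa_vals[name], False
            if cfg.include_network:
                for name, v in net_vals.items():
                    values[name], flags[name] = v, False
        except (DegenerateSeriesError, ValueError):
            for name in rqa_wanted:
                values[name], flags[name] = 0.0, True
            if cfg.include_network:
                from .network import NETWORK_MEASURES
                for name in NETWORK_MEASURES:
                    values[name], flags[name] = 0.0, True
        if force_flag:
            for name in rqa_wanted:
                values[name], flags[name] = 0.0, True

    tau = cfg.embed_tau or _safe_delay(series)
    # O(n^2) measures run on a leading segment (entropies, Lyapunov keep
    # temporal structure) or a stride subsample (D2: spatial geometry only)
    ent_series = series[: cfg.entropy_max_points]
    lyap_series = series[: cfg.lyap_max_points]
    put("sampen", lambda: sample_entropy(ent_series, cfg.entropy_m,
                                         cfg.entropy_r))
    put("apen", lambda: approximate_entropy(ent_series, cfg.entropy_m,
                                            cfg.entropy_r))
    put("permen", lambda: permutation_entropy(series, cfg.perm_order))
    put("corr_dim", lambda: correlation_dimension(
        series, m=cfg.d2_m, tau=tau, max_points=cfg.rqa_max_points))
    put("dfa", lambda: dfa(series))
    put("hurst", lambda: hurst_rs(series))
    put("lyap", lambda: lyapunov_max(lyap_series, m=cfg.embed_m, tau=tau,
                                     fs=fs, max_steps=cfg.lyap_max_steps,
                                     max_ref_points=cfg.lyap_ref_points))
    return values, flags


def _safe_delay(series: np.ndarray, cap_frac: float = 0.05) -> int:
    try:
        tau = _rec.select_delay(series, "autocorr_zero")
    except ValueError:
        return 1
    return int(max(1, min(tau, max(1, int(cap_frac * series.size)))))


def _rqa_block(series: np.ndarray, cfg: FeatureConfig
               ) -> tuple[dict[str, float], dict[str, float]]:
    tau = cfg.embed_tau or _safe_delay(series)
    traj = _rec.delay_embed(series, cfg.embed_m, tau)
    pts = traj.points
    if pts.shape[0] > cfg.rqa_max_points:
        stride = int(np.ceil(pts.shape[0] / cfg.rqa_max_points))
        pts = pts[::stride]
        theiler = max(1, tau // stride)
    else:
        theiler = tau
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        R = _rec.recurrence_matrix(pts, target_rr=cfg.target_rr,
                                   theiler=theiler)
        rqa = _rec.rqa_measures(R, lmin=cfg.lmin)
    net: dict[str, float] = {}
    if cfg.include_network:
        from .network import rn_adjacency, rn_measures
        net = rn_measures(rn_adjacency(R), seed=cfg.network_seed)
        net.pop("connected", None)
    return rqa, net
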