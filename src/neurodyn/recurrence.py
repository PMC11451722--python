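"""Phase-space reconstruction and recurrence quantification analysis.

A scalar series is delay-embedded into m-dimensional state vectors
(x_i, x_{i+tau}, ..., x_{i+(m-1)tau}); by the embedding theorems these
reconstruct the geometry of the underlying attractor. The recurrence matrix
marks time pairs whose embedded states lie within distance epsilon; here the
threshold is chosen as the empirical distance quantile that yields a
prescribed recurrence rate (default 0.05), so plots from different signals
are comparable. The quantitative measures (determinism, laminarity, line
entropies, trapping time ...) are statistics of the diagonal, vertical and
white-vertical line-length histograms of that binary matrix.

Conventions: a Theiler band |i - j| <= theiler (always including the line of
identity) is excluded from recurrence-rate bookkeeping, from diagonal-line
scans and from vertical-line scans; white-vertical (recurrence-time) runs are
scanned on the raw matrix with the identity line intact, counting only runs
bounded by recurrences on both ends (uncensored recurrence times).
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import pdist, squareform


@dataclass
class EmbeddedTrajectory:
    points: np.ndarray  # (n_points, m)
    m: int
    tau: int
    n_source: int

    @property
    def n_points(self) -> int:
        return self.points.shape[0]


@dataclass
class RecurrenceMatrix:
    matrix: np.ndarray  # (n, n) uint8, symmetric, unit diagonal
    epsilon: float
    target_rr: float | None
    metric: str
    theiler: int
    degenerate: bool = False

    @property
    def n_points(self) -> int:
        return self.matrix.shape[0]

    def recurrence_rate(self) -> float:
        """Achieved density outside the Theiler band."""
        n = self.n_points
        band_ones = sum(int(np.diagonal(self.matrix, off).sum())
                        for off in range(-self.theiler, self.theiler + 1))
        band_cells = sum(n - abs(off)
                         for off in range(-self.theiler, self.theiler + 1))
        allowed = n * n - band_cells
        if allowed <= 0:
            return 0.0
        return (float(self.matrix.sum()) - band_ones) / allowed


@dataclass
class LineHistogram:
    kind: str  # diagonal | vertical | white_vertical
    counts: Counter = field(default_factory=Counter)
    lmin: int = 1

    def total_lines(self, lmin: int | None = None) -> int:
        lmin = self.lmin if lmin is None else lmin
        return sum(c for l, c in self.counts.items() if l >= lmin)

    def total_points(self, lmin: int | None = None) -> int:
        lmin = self.lmin if lmin is None else lmin
        return sum(l * c for l, c in self.counts.items() if l >= lmin)

    def max_length(self) -> int:
        return max(self.counts) if self.counts else 0

    def mean_length(self, lmin: int | None = None) -> float:
        nl = self.total_lines(lmin)
        return self.total_points(lmin) / nl if nl else 0.0

    def entropy(self, lmin: int | None = None) -> float:
        """Shannon entropy (natural log) of the length distribution >= lmin."""
        lmin = self.lmin if lmin is None else lmin
        counts = np.array([c for l, c in self.counts.items() if l >= lmin],
                          dtype=float)
        if counts.size == 0 or counts.sum() == 0:
            return 0.0
        p = counts / counts.sum()
        return float(-(p * np.log(p)).sum())


# ---------------------------------------------------------------------------
# Embedding parameter selection
# ---------------------------------------------------------------------------

def _autocorr(x: np.ndarray, max_lag: int) -> np.ndarray:
    x = x - x.mean()
    n = x.size
    f = np.fft.rfft(x, 2 * n)
    acf = np.fft.irfft(f * np.conj(f))[: max_lag + 1]
    return acf / acf[0]


def select_delay(series: np.ndarray, method: str = "autocorr_zero",
                 max_lag: int | None = None, n_bins: int = 16) -> int:
    """Embedding delay from the autocorrelation or mutual-information curve.

    ``autocorr_zero``: first lag where the autocorrelation crosses zero
    (quarter period for a sinusoid). ``autocorr_1_over_e``: first lag below
    1/e. ``mutual_info_min``: first local minimum of the binned mutual
    information.
    """
    x = np.asarray(series, dtype=float)
    if x.size < 10:
        raise ValueError("series too short for delay selection")
    if np.ptp(x) == 0:
        raise ValueError("constant series: delay is undefined")
    if max_lag is None:
        max_lag = max(2, x.size // 4)
    if method in ("autocorr_zero", "autocorr_1_over_e"):
        acf = _autocorr(x, max_lag)
        thresh = 0.0 if method == "autocorr_zero" else 1.0 / np.e
        below = np.nonzero(acf[1:] <= thresh)[0]
        if not below.size:
            return max_lag
        k = int(below[0] + 1)
        # the crossing lies between k-1 and k: return whichever bracket lag
        # is nearer to the threshold (finite-length estimates can leave the
        # true crossing lag epsilon above it)
        if k > 1 and abs(acf[k - 1] - thresh) < abs(acf[k] - thresh):
            return k - 1
        return k
    if method == "mutual_info_min":
        mi = np.array([_mutual_info(x, lag, n_bins)
                       for lag in range(1, max_lag + 1)])
        for i in range(1, mi.size - 1):
            if mi[i] < mi[i - 1] and mi[i] <= mi[i + 1]:
                return i + 1
        return int(np.argmin(mi)) + 1
    raise ValueError(f"unknown delay method: {method!r}")


def _mutual_info(x: np.ndarray, lag: int, n_bins: int) -> float:
    a, b = x[:-lag], x[lag:]
    h, _, _ = np.histogram2d(a, b, bins=n_bins)
    p = h / h.sum()
    px = p.sum(axis=1, keepdims=True)
    py = p.sum(axis=0, keepdims=True)
    nz = p > 0
    return float((p[nz] * np.log(p[nz] / (px @ py)[nz])).sum())


@dataclass
class EmbeddingDim:
    m: int
    converged: bool
    fnn_fractions: list[float]


def select_embedding_dim(series: np.ndarray, tau: int,
                         max_m: int = 8, rtol: float = 15.0,
                         atol: float = 2.0,
                         threshold: float = 0.05) -> EmbeddingDim:
    """Smallest embedding dimension by the false-nearest-neighbour test.

    A neighbour in dimension m is "false" if adding the (m+1)-th coordinate
    stretches the pair by more than ``rtol`` relative to its m-dim distance,
    or beyond ``atol`` times the series spread. Returns the first m whose
    false fraction drops below ``threshold``; stochastic signals never
    saturate and come back as ``max_m`` with ``converged=False``.
    """
    x = np.asarray(series, dtype=float)
    sd = x.std()
    if sd == 0:
        raise ValueError("constant series")
    fractions: list[float] = []
    for m in range(1, max_m + 1):
        n_pts = x.size - m * tau  # need coordinate m+1 available
        if n_pts < 10:
            raise ValueError("series too short for requested max_m and tau")
        emb = delay_embed(x[: x.size - tau], m, tau).points[:n_pts]
        nxt = x[m * tau: m * tau + n_pts]
        d = squareform(pdist(emb))
        np.fill_diagonal(d, np.inf)
        # exclude temporally adjacent points from the neighbour search
        for off in range(1, tau + 1):
            idx = np.arange(n_pts - off)
            d[idx, idx + off] = np.inf
            d[idx + off, idx] = np.inf
        # distances at round-off scale are exact recurrences, not neighbours
        d[d <= 1e-8 * sd] = np.inf
        nn = np.argmin(d, axis=1)
        dm = d[np.arange(n_pts), nn]
        ok = np.isfinite(dm) & (dm > 0)
        stretch = np.abs(nxt - nxt[nn])
        false = ((stretch[ok] / dm[ok] > rtol)
                 | (np.sqrt(dm[ok] ** 2 + stretch[ok] ** 2) / sd > atol))
        frac = float(false.mean()) if ok.any() else 1.0
        fractions.append(frac)
        if frac < threshold:
            return EmbeddingDim(m=m, converged=True, fnn_fractions=fractions)
    warnings.warn("false-nearest-neighbour fraction never fell below "
                  f"{threshold}; returning max_m={max_m}")
    return EmbeddingDim(m=max_m, converged=False, fnn_fractions=fractions)


def delay_embed(series: np.ndarray, m: int, tau: int) -> EmbeddedTrajectory:
    """Delay embedding: row i = (x_i, x_{i+tau}, ..., x_{i+(m-1)tau})."""
    x = np.asarray(series, dtype=float)
    if m < 1 or tau < 1:
        raise ValueError("m and tau must be >= 1")
    n_pts = x.size - (m - 1) * tau
    if n_pts < 2:
        raise ValueError(
            f"series of length {x.size} too short for m={m}, tau={tau}")
    idx = np.arange(n_pts)[:, None] + tau * np.arange(m)[None, :]
    return EmbeddedTrajectory(points=x[idx], m=m, tau=tau, n_source=x.size)


# ---------------------------------------------------------------------------
# Recurrence matrix
# ---------------------------------------------------------------------------

def recurrence_matrix(traj: EmbeddedTrajectory | np.ndarray,
                      target_rr: float | None = None,
                      epsilon: float | None = None,
                      metric: str = "euclidean",
                      theiler: int = 0) -> RecurrenceMatrix:
    """Thresholded pairwise-distance matrix of an embedded trajectory.

    Exactly one of ``target_rr`` and ``epsilon`` must be given. In fixed-RR
    mode the threshold is the ``target_rr`` quantile (k-th order statistic)
    of the pairwise distances outside the Theiler band, which pins the
    achieved off-diagonal density at the target up to ties.
    """
    pts = traj.points if isinstance(traj, EmbeddedTrajectory) else np.asarray(traj, float)
    if pts.ndim == 1:
        pts = pts[:, None]
    n = pts.shape[0]
    if (target_rr is None) == (epsilon is None):
        raise ValueError("give exactly one of target_rr or epsilon")
    if theiler < 0:
        raise ValueError("theiler must be >= 0")
    dist = squareform(pdist(pts, metric=metric))
    degenerate = False
    if target_rr is not None:
        if not 0.0 < target_rr < 1.0:
            raise ValueError("target_rr must lie in (0, 1)")
        if n < 10:
            raise ValueError("fixed-RR mode needs at least 10 points")
        i, j = np.triu_indices(n, k=theiler + 1)
        d_off = dist[i, j]
        if d_off.size == 0:
            raise ValueError("Theiler window leaves no admissible pairs")
        if np.all(d_off == 0):
            warnings.warn("all embedded points identical; recurrence matrix "
                          "is all ones")
            epsilon = 0.0
            degenerate = True
        else:
            k = max(1, int(np.floor(target_rr * d_off.size)))
            epsilon = float(np.partition(d_off, k - 1)[k - 1])
    # tolerant comparison so round-off jitter inside a tie group (exactly
    # periodic signals) cannot fragment otherwise-uniform diagonals
    mat = (dist <= epsilon * (1.0 + 1e-9) + 1e-300).astype(np.uint8)
    return RecurrenceMatrix(matrix=mat, epsilon=float(epsilon),
                            target_rr=target_rr, metric=metric,
                            theiler=theiler, degenerate=degenerate)


# ---------------------------------------------------------------------------
# Line histograms and RQA measures
# ---------------------------------------------------------------------------

_SEP = 2  # separator sentinel breaking runs between packed segments


def _pack_segments(segments: list[np.ndarray]) -> np.ndarray:
    """Concatenate 0/1 segments with a separator so runs cannot bridge."""
    total = sum(s.size + 1 for s in segments)
    out = np.full(total, _SEP, dtype=np.int8)
    pos = 0
    for s in segments:
        out[pos: pos + s.size] = s
        pos += s.size + 1
    return out


def _run_length_counts(flat: np.ndarray, value: int,
                       bounded_by_ones: bool = False) -> Counter:
    """Histogram of maximal runs of ``value`` in a packed 1-D array.

    With ``bounded_by_ones`` only runs whose both flanking elements equal 1
    are kept (used for uncensored white-vertical runs)."""
    eq = np.concatenate([[False], flat == value, [False]])
    d = np.diff(eq.astype(np.int8))
    starts = np.nonzero(d == 1)[0]
    ends = np.nonzero(d == -1)[0]
    lengths = ends - starts
    if bounded_by_ones and lengths.size:
        lv = np.where(starts > 0, flat[np.maximum(starts - 1, 0)], -1)
        rv = np.where(ends < flat.size, flat[np.minimum(ends, flat.size - 1)],
                      -1)
        lengths = lengths[(lv == 1) & (rv == 1)]
    if lengths.size == 0:
        return Counter()
    vals, counts = np.unique(lengths, return_counts=True)
    return Counter(dict(zip(vals.tolist(), counts.tolist())))


def line_histograms(R: RecurrenceMatrix, lmin: int = 2
                    ) -> tuple[LineHistogram, LineHistogram, LineHistogram]:
    """Diagonal, vertical and white-vertical line-length histograms.

    Diagonal runs are scanned on every diagonal with offset > theiler on the
    upper triangle and doubled (the matrix is symmetric). Vertical runs are
    scanned per column after zeroing the Theiler band. White-vertical runs
    are maximal 0-runs per column of the raw matrix bounded by recurrences
    on both sides (censored boundary runs are skipped). The histograms are
    exhaustive: every qualifying run of every length is counted.
    """
    mat = R.matrix
    n = R.n_points
    diag_flat = _pack_segments([np.diagonal(mat, offset=off)
                                for off in range(R.theiler + 1, n)])
    diag = _run_length_counts(diag_flat, 1)
    for length in diag:
        diag[length] *= 2  # symmetric: count both triangles
    masked = mat.copy()
    for off in range(-R.theiler, R.theiler + 1):
        idx = np.arange(max(0, -off), min(n, n - off))
        masked[idx + off, idx] = 0
    sep_row = np.full((1, n), _SEP, dtype=np.int8)
    vert_flat = np.vstack([masked.astype(np.int8), sep_row]).T.ravel()
    vert = _run_length_counts(vert_flat, 1)
    white_flat = np.vstack([mat.astype(np.int8), sep_row]).T.ravel()
    white = _run_length_counts(white_flat, 0, bounded_by_ones=True)
    return (LineHistogram("diagonal", diag, lmin),
            LineHistogram("vertical", vert, lmin),
            LineHistogram("white_vertical", white, 1))


#: Measure names of the RQA block, in reporting order.
RQA_MEASURES = ["rr", "det", "lam", "lentr", "lmean", "lmax", "tt",
                "vert_ent", "white_vert_ent"]


def rqa_measures(R: RecurrenceMatrix, lmin: int = 2) -> dict[str, float]:
    """The nine recurrence-plot statistics.

    rr: density of recurrence points outside the Theiler band.
    det: fraction of those points lying on diagonal lines of length >= lmin.
    lam: fraction of (Theiler-excluded) vertical-scan points on vertical
         lines >= lmin.
    lentr: Shannon entropy (nats) of the diagonal line-length distribution.
    lmean / lmax: mean (>= lmin) and maximal diagonal line length.
    tt: trapping time, the mean vertical line length >= lmin.
    vert_ent: Shannon entropy of the vertical line-length distribution.
    white_vert_ent: Shannon entropy of the recurrence-time (white vertical
         line) distribution.

    Statistics of an empty histogram are reported as 0 (never NaN) so that
    downstream tensors stay dense; callers can detect the condition from the
    histograms themselves.
    """
    if lmin < 2:
        raise ValueError("lmin must be >= 2")
    diag, vert, white = line_histograms(R, lmin)
    rr = R.recurrence_rate()
    diag_points_all = diag.total_points(lmin=1)
    vert_points_all = vert.total_points(lmin=1)
    det = diag.total_points() / diag_points_all if diag_points_all else 0.0
    lam = vert.total_points() / vert_points_all if vert_points_all else 0.0
    return {
        "rr": rr,
        "det": det,
        "lam": lam,
        "lentr": diag.entropy(),
        "lmean": diag.mean_length(),
        "lmax": float(diag.max_length()),
        "tt": vert.mean_length(),
        "vert_ent": vert.entropy(),
        "white_vert_ent": white.entropy(),
    }


def export_recurrence_plot(R: RecurrenceMatrix, path) -> None:
    """Save the binary matrix as CSV (``.csv``) or a PNG image (``.png``)."""
    from pathlib import Path

    path = Path(path)
    if path.suffix == ".csv":
        np.savetxt(path, R.matrix, fmt="%d", delimiter=",")
    elif path.suffix == ".png":
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
        fig, ax = plt.subplots(figsize=(4, 4))
        ax.imshow(R.matrix, cmap="binary", origin="lower", interpolation="none")
        ax.set_xlabel("time index")
        ax.set_ylabel("time index")
        fig.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(fig)
    else:
        raise ValueError("use a .csv or .png suffix")
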