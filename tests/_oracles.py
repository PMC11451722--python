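"""Independent brute-force reference implementations used only by tests.

Everything here is written in the most literal way possible (plain Python
loops over definitions) so it shares no code path with the package.
"""

from collections import Counter

import numpy as np


# ---------------------------------------------------------------------------
# Recurrence-plot line scanning
# ---------------------------------------------------------------------------

def runs_in_vector(vec, value):
    """(start, length) pairs of maximal runs of ``value``."""
    runs, start = [], None
    for i, v in enumerate(list(vec) + [None]):
        if v == value and start is None:
            start = i
        elif v != value and start is not None:
            runs.append((start, i - start))
            start = None
    return runs


def diagonal_histogram(mat, theiler):
    """Count maximal 1-runs on every diagonal with |offset| > theiler."""
    n = len(mat)
    counts = Counter()
    for off in range(theiler + 1, n):
        for sign in (+1, -1):
            if sign > 0:
                diag = [mat[i][i + off] for i in range(n - off)]
            else:
                diag = [mat[i + off][i] for i in range(n - off)]
            for _, length in runs_in_vector(diag, 1):
                counts[length] += 1
    return counts


def vertical_histogram(mat, theiler):
    """Maximal 1-runs per column, Theiler band (|i-j| <= theiler) removed."""
    n = len(mat)
    counts = Counter()
    for j in range(n):
        col = [mat[i][j] if abs(i - j) > theiler else 0 for i in range(n)]
        for _, length in runs_in_vector(col, 1):
            counts[length] += 1
    return counts


def white_vertical_histogram(mat):
    """Maximal 0-runs per column bounded by 1s on both ends (raw matrix)."""
    n = len(mat)
    counts = Counter()
    for j in range(n):
        col = [mat[i][j] for i in range(n)]
        for start, length in runs_in_vector(col, 0):
            if start > 0 and start + length < n:
                counts[length] += 1
    return counts


def shannon_entropy(counts, lmin):
    vals = [c for length, c in counts.items() if length >= lmin]
    total = sum(vals)
    if total == 0:
        return 0.0
    return -sum((c / total) * np.log(c / total) for c in vals)


def rqa_from_matrix(mat, theiler, lmin=2):
    """All nine recurrence measures straight from the definitions."""
    n = len(mat)
    allowed = [(i, j) for i in range(n) for j in range(n)
               if abs(i - j) > theiler]
    rr = sum(mat[i][j] for i, j in allowed) / len(allowed) if allowed else 0.0
    diag = diagonal_histogram(mat, theiler)
    vert = vertical_histogram(mat, theiler)
    white = white_vertical_histogram(mat)

    def points(counts, lo):
        return sum(length * c for length, c in counts.items() if length >= lo)

    def lines(counts, lo):
        return sum(c for length, c in counts.items() if length >= lo)

    det = points(diag, lmin) / points(diag, 1) if points(diag, 1) else 0.0
    lam = points(vert, lmin) / points(vert, 1) if points(vert, 1) else 0.0
    lmean = (points(diag, lmin) / lines(diag, lmin)
             if lines(diag, lmin) else 0.0)
    lmax = max(diag) if diag else 0
    tt = (points(vert, lmin) / lines(vert, lmin)
          if lines(vert, lmin) else 0.0)
    return {
        "rr": rr,
        "det": det,
        "lam": lam,
        "lentr": shannon_entropy(diag, lmin),
        "lmean": lmean,
        "lmax": float(lmax),
        "tt": tt,
        "vert_ent": shannon_entropy(vert, lmin),
        "white_vert_ent": shannon_entropy(white, 1),
    }


# ---------------------------------------------------------------------------
# Entropy template counting
# ---------------------------------------------------------------------------

def sample_entropy_direct(x, m, r):
    x = np.asarray(x, dtype=float)
    r_abs = r * x.std()
    n = len(x)

    def count(mm, n_templates):
        c = 0
        for i in range(n_templates):
            for j in range(i + 1, n_templates):
                if max(abs(x[i + k] - x[j + k]) for k in range(mm)) <= r_abs:
                    c += 1
        return c

    b = count(m, n - m)
    a = count(m + 1, n - m)
    if a == 0 or b == 0:
        return 0.0
    return -np.log(a / b)


def approximate_entropy_direct(x, m, r):
    x = np.asarray(x, dtype=float)
    r_abs = r * x.std()
    n = len(x)

    def phi(mm):
        n_t = n - mm + 1
        logs = []
        for i in range(n_t):
            c = 0
            for j in range(n_t):
                if max(abs(x[i + k] - x[j + k]) for k in range(mm)) <= r_abs:
                    c += 1
            logs.append(np.log(c / n_t))
        return np.mean(logs)

    return phi(m) - phi(m + 1)


def permutation_entropy_direct(x, order):
    x = np.asarray(x, dtype=float)
    patterns = Counter()
    for i in range(len(x) - order + 1):
        window = x[i: i + order]
        pattern = tuple(sorted(range(order), key=lambda k: (window[k], k)))
        patterns[pattern] += 1
    total = sum(patterns.values())
    return -sum((c / total) * np.log(c / total) for c in patterns.values())


# ---------------------------------------------------------------------------
# Graph measures by exhaustive enumeration
# ---------------------------------------------------------------------------

def betweenness_direct(adj):
    """Betweenness centrality by explicit BFS shortest-path enumeration,
    normalized the way networkx normalizes undirected graphs."""
    n = len(adj)
    bc = [0.0] * n
    for s in range(n):
        for t in range(s + 1, n):
            paths = _all_shortest_paths(adj, s, t)
            if not paths:
                continue
            for v in range(n):
                if v in (s, t):
                    continue
                through = sum(1 for p in paths if v in p)
                bc[v] += through / len(paths)
    norm = (n - 1) * (n - 2) / 2.0
    return [b / norm for b in bc]


def _all_shortest_paths(adj, s, t):
    n = len(adj)
    from collections import deque
    dist = {s: 0}
    queue = deque([s])
    while queue:
        u = queue.popleft()
        for v in range(n):
            if adj[u][v] and v not in dist:
                dist[v] = dist[u] + 1
                queue.append(v)
    if t not in dist:
        return []
    paths = []

    def walk(path):
        u = path[-1]
        if u == t:
            paths.append(tuple(path))
            return
        for v in range(n):
            if adj[u][v] and dist.get(v) == dist[u] + 1:
                walk(path + [v])

    walk([s])
    return paths
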