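"""Fourth-order feature tensors and (supervised) canonical polyadic
factorization.

Per-subject feature tables are stacked into a tensor of shape
subjects x sensors x bands x measures, z-scored per measure, and decomposed
into R rank-1 components by alternating least squares (CP-ALS):

    T  ~=  sum_r  w_r  a_r o b_r o c_r o d_r

with unit-norm factor columns and weights w sorted descending. The
supervised variant augments the least-squares objective with a
ridge-penalized regression of the behavioral target on the subject scores,

    || T - [[w; A, B, C, D]] ||^2  +  gamma ( || y - [A, X_cov] beta ||^2
                                              + ridge * ||beta||^2 ),

so the subject-mode update is pulled toward components whose scores predict
the target. At gamma = 0 the update equations reduce exactly to plain
CP-ALS. Missing/flagged entries are handled by expectation-maximization
imputation (masked cells are refilled from the current reconstruction each
sweep), so they never influence the fit. Out-of-sample subjects get scores
by least-squares projection of their feature slices onto the fixed
non-subject factors — no target information is used, which is what permits
leakage-free per-fold factorization downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.linalg import khatri_rao

MODE_NAMES = ["subject", "sensor", "band", "measure"]


@dataclass
class FeatureTensor:
    """subjects x sensors x bands x measures array with labels and mask.

    ``mask`` is True where the value is missing or quality-flagged; masked
    cells hold the placeholder 0.
    """

    values: np.ndarray
    mask: np.ndarray
    labels: dict[str, list[str]]
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.values.ndim != 4:
            raise ValueError("feature tensor must be 4-way")
        if self.values.shape != self.mask.shape:
            raise ValueError("values and mask shapes differ")
        for ax, name in enumerate(MODE_NAMES):
            if len(self.labels[name]) != self.values.shape[ax]:
                raise ValueError(f"label count mismatch on mode {name!r}")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.values.shape

    def save(self, dirpath: str | Path) -> Path:
        """Persist as a directory: arrays in one ``.npz``, labels in JSON."""
        from .io import save_json

        dirpath = Path(dirpath)
        dirpath.mkdir(parents=True, exist_ok=True)
        np.savez(dirpath / "tensor.npz", values=self.values, mask=self.mask)
        save_json({"labels": self.labels, "meta": self.meta},
                  dirpath / "labels.json")
        return dirpath

    @classmethod
    def load(cls, dirpath: str | Path) -> "FeatureTensor":
        from .io import load_json

        dirpath = Path(dirpath)
        arrs = np.load(dirpath / "tensor.npz")
        info = load_json(dirpath / "labels.json")
        return cls(values=arrs["values"], mask=arrs["mask"],
                   labels=info["labels"], meta=info.get("meta", {}))


@dataclass
class CPFactors:
    """Result of a (supervised) CP decomposition."""

    weights: np.ndarray                 # (R,)
    factors: list[np.ndarray]           # [(N,R), (Ns,R), (Nf,R), (Nm,R)]
    rank: int
    n_iter: int
    fit: float
    converged: bool
    seed: int
    beta: np.ndarray | None = None      # supervised regression coefficients
    gamma: float = 0.0
    labels: dict | None = None

    @property
    def subject_scores(self) -> np.ndarray:
        return self.factors[0]

    def export_csv(self, dirpath: str | Path) -> Path:
        dirpath = Path(dirpath)
        dirpath.mkdir(parents=True, exist_ok=True)
        cols = [f"factor_{r + 1}" for r in range(self.rank)]
        for mode, fac in zip(MODE_NAMES, self.factors):
            idx = (self.labels or {}).get(mode) if self.labels else None
            pd.DataFrame(fac, columns=cols, index=idx).to_csv(
                dirpath / f"factors_{mode}.csv",
                index_label=mode)
        pd.DataFrame({"weight": self.weights}, index=cols).to_csv(
            dirpath / "weights.csv", index_label="factor")
        return dirpath


@dataclass
class SupervisionSpec:
    """Target and covariates coupled into the factorization.

    ``gamma`` balances reconstruction against prediction loss; ``"auto"``
    sets it to ten times the number of observed tensor cells per subject,
    which makes the coupling term dominant enough to reshape the loadings.
    ``ridge`` shrinks the regression coefficients so the coupling cannot be
    satisfied by inflating beta instead of aligning a component with the
    target. The target is standardized internally.
    """

    target: np.ndarray
    covariates: np.ndarray | None = None
    gamma: float | str = "auto"
    ridge: float = 10.0
    mode: str = "coupled_regression"

    def __post_init__(self) -> None:
        self.target = np.asarray(self.target, dtype=float).ravel()
        if not np.all(np.isfinite(self.target)):
            raise ValueError("target contains non-finite values")
        if self.covariates is not None:
            self.covariates = np.atleast_2d(np.asarray(self.covariates, float))
            if self.covariates.shape[0] != self.target.size:
                self.covariates = self.covariates.T
            if self.covariates.shape[0] != self.target.size:
                raise ValueError("covariate rows must align with target")
        if isinstance(self.gamma, (int, float)) and self.gamma < 0:
            raise ValueError("gamma must be >= 0")


# ---------------------------------------------------------------------------
# Assembly and normalization
# ---------------------------------------------------------------------------

def assemble_tensor(tables: dict[str, pd.DataFrame],
                    cohort: pd.DataFrame) -> FeatureTensor:
    """Stack per-subject feature tables into a 4-way tensor.

    ``tables`` maps subject id -> the frame produced by
    :func:`neurodyn.invariants.extract_features`. Subjects follow cohort-row
    order; sensor/band/measure axes use sorted labels shared by all
    subjects. Entries that are absent or quality-flagged are masked.
    """
    ids = list(cohort["subject_id"])
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate subject ids in cohort")
    missing = [s for s in ids if s not in tables]
    if missing:
        raise ValueError(f"no feature table for subject(s): {missing}")

    ref = tables[ids[0]]
    measures = sorted(c for c in ref.columns
                      if c not in ("channel", "band")
                      and not c.startswith("flag_"))
    sensors = sorted(ref["channel"].unique())
    bands_ = sorted(ref["band"].unique())
    for sid in ids:
        t = tables[sid]
        m_s = sorted(c for c in t.columns if c not in ("channel", "band")
                     and not c.startswith("flag_"))
        if m_s != measures:
            raise ValueError(f"subject {sid}: measure set differs")
        if sorted(t["band"].unique()) != bands_:
            raise ValueError(f"subject {sid}: band labels differ")

    shape = (len(ids), len(sensors), len(bands_), len(measures))
    values = np.zeros(shape)
    mask = np.ones(shape, dtype=bool)
    s_idx = {s: i for i, s in enumerate(sensors)}
    b_idx = {b: i for i, b in enumerate(bands_)}
    for n, sid in enumerate(ids):
        t = tables[sid]
        for _, row in t.iterrows():
            if row["channel"] not in s_idx:
                raise ValueError(
                    f"subject {sid}: unknown channel {row['channel']!r}")
            i, j = s_idx[row["channel"]], b_idx[row["band"]]
            for k, meas in enumerate(measures):
                flagged = bool(row.get(f"flag_{meas}", False))
                values[n, i, j, k] = 0.0 if flagged else float(row[meas])
                mask[n, i, j, k] = flagged
    labels = {"subject": ids, "sensor": sensors, "band": bands_,
              "measure": measures}
    return FeatureTensor(values=values, mask=mask, labels=labels)


def normalize_tensor(T: FeatureTensor, scheme: str = "zscore_per_measure"
                     ) -> FeatureTensor:
    """Z-score each measure slice over its unmasked entries.

    Constant slices are set to zero and recorded in the meta flags; the
    per-measure mean/SD are stored so :func:`denormalize_tensor` can invert
    the transform.
    """
    if scheme != "zscore_per_measure":
        raise ValueError(f"unknown normalization scheme: {scheme!r}")
    values = T.values.copy()
    means, sds, degenerate = [], [], []
    for k in range(values.shape[3]):
        sl = values[..., k]
        obs = sl[~T.mask[..., k]]
        if obs.size < 2 or obs.std() == 0:
            mu, sd = (obs.mean() if obs.size else 0.0), 1.0
            degenerate.append(T.labels["measure"][k])
            values[..., k] = 0.0
        else:
            mu, sd = obs.mean(), obs.std()
            values[..., k] = (sl - mu) / sd
        means.append(float(mu))
        sds.append(float(sd))
    values[T.mask] = 0.0
    meta = dict(T.meta)
    meta["normalization"] = {"scheme": scheme, "mean": means, "sd": sds,
                             "degenerate_measures": degenerate}
    return FeatureTensor(values=values, mask=T.mask.copy(),
                         labels={k: list(v) for k, v in T.labels.items()},
                         meta=meta)


def denormalize_tensor(T: FeatureTensor) -> FeatureTensor:
    norm = T.meta.get("normalization")
    if norm is None:
        raise ValueError("tensor carries no normalization record")
    values = T.values.copy()
    for k, (mu, sd) in enumerate(zip(norm["mean"], norm["sd"])):
        values[..., k] = values[..., k] * sd + mu
    values[T.mask] = 0.0
    meta = {k: v for k, v in T.meta.items() if k != "normalization"}
    return FeatureTensor(values=values, mask=T.mask.copy(),
                         labels={k: list(v) for k, v in T.labels.items()},
                         meta=meta)


# ---------------------------------------------------------------------------
# CP-ALS core
# ---------------------------------------------------------------------------

def _unfold(T: np.ndarray, mode: int) -> np.ndarray:
    return np.moveaxis(T, mode, 0).reshape(T.shape[mode], -1)


def _kr_others(factors: list[np.ndarray], skip: int) -> np.ndarray:
    """Khatri-Rao product of all factors except ``skip``, matching the
    C-order unfolding used by :func:`_unfold`."""
    mats = [f for i, f in enumerate(factors) if i != skip]
    out = mats[0]
    for m in mats[1:]:
        out = khatri_rao(out, m)
    return out


def reconstruct(F: CPFactors) -> np.ndarray:
    """Dense tensor from weights and factor matrices."""
    A = F.factors[0] * F.weights
    Z = _kr_others(F.factors, 0)
    shape = tuple(f.shape[0] for f in F.factors)
    return (A @ Z.T).reshape(shape)


def explained_fit(T: FeatureTensor | np.ndarray, F: CPFactors,
                  mask: np.ndarray | None = None) -> float:
    """1 - ||T - T_hat|| / ||T|| over unmasked entries."""
    values, mask = _coerce(T, mask)
    rec = reconstruct(F)
    if rec.shape != values.shape:
        raise ValueError("factor shapes do not match the tensor")
    obs = ~mask
    denom = np.linalg.norm(values[obs])
    if denom == 0:
        raise ValueError("zero-norm tensor")
    return float(1.0 - np.linalg.norm((values - rec)[obs]) / denom)


def _coerce(T, mask):
    if isinstance(T, FeatureTensor):
        return T.values, T.mask
    values = np.asarray(T, dtype=float)
    if mask is None:
        mask = np.zeros(values.shape, dtype=bool)
    return values, np.asarray(mask, dtype=bool)


def cp_decompose(T: FeatureTensor | np.ndarray, rank: int, seed: int = 0,
                 tol: float = 1e-8, max_iter: int = 500,
                 n_starts: int = 5,
                 mask: np.ndarray | None = None) -> CPFactors:
    """Unsupervised CP decomposition by multi-start masked ALS.

    Runs ``n_starts`` seeded random initializations to full convergence and
    keeps the best objective; the reconstruction error is non-increasing
    across sweeps within each start. Masked entries are imputed from the
    running reconstruction (EM), so they carry no weight in the fit.
    """
    return _cp_als(T, rank, sup=None, seed=seed, tol=tol,
                   max_iter=max_iter, n_starts=n_starts, mask=mask)


def supervised_cp(T: FeatureTensor | np.ndarray, rank: int,
                  sup: SupervisionSpec, seed: int = 0, tol: float = 1e-8,
                  max_iter: int = 500, n_starts: int = 5,
                  mask: np.ndarray | None = None) -> CPFactors:
    """Ridge-coupled supervised CP decomposition (see module docstring).

    With ``sup.gamma == 0`` the arithmetic reduces exactly to
    :func:`cp_decompose` at the same seed.
    """
    return _cp_als(T, rank, sup=sup, seed=seed, tol=tol,
                   max_iter=max_iter, n_starts=n_starts, mask=mask)


def _cp_als(T, rank, sup, seed, tol, max_iter, n_starts, mask):
    values, mask = _coerce(T, mask)
    labels = T.labels if isinstance(T, FeatureTensor) else None
    if rank < 1:
        raise ValueError("rank must be >= 1")
    if not np.all(np.isfinite(values[~mask])):
        raise ValueError("tensor contains non-finite unmasked entries")

    gamma, y_std, X_cov = 0.0, None, None
    if sup is not None:
        if sup.target.size != values.shape[0]:
            raise ValueError("supervision target length must equal the "
                             "subject-mode dimension")
        gamma = sup.gamma
        if gamma == "auto":
            gamma = 10.0 * float((~mask).sum()) / values.shape[0]
        y = sup.target
        sd = y.std()
        if sd == 0:
            raise ValueError("constant supervision target")
        y_std = (y - y.mean()) / sd
        if sup.covariates is not None:
            X_cov = sup.covariates - sup.covariates.mean(axis=0)
            if np.linalg.matrix_rank(X_cov) < X_cov.shape[1]:
                raise ValueError("rank-deficient covariate matrix")

    ridge = sup.ridge if sup is not None else 0.0
    # deterministic HOSVD-style start first, then seeded random restarts;
    # best final objective wins (the SVD start usually does, which keeps
    # refits of overlapping data close to each other)
    starts: list = ["svd"]
    starts += [int(s.generate_state(1)[0] % (2 ** 31))
               for s in np.random.SeedSequence(seed).spawn(max(n_starts - 1, 0))]
    best = None
    for s in starts:
        result = _cp_als_single(values, mask, rank, gamma, y_std, X_cov,
                                ridge, s, tol, max_iter)
        if best is None or result["objective"] < best["objective"]:
            best = result

    factors, beta = best["factors"], best["beta"]
    weights, factors = _normalize_factors(factors)
    fit = explained_fit(values, CPFactors(weights, factors, rank, 0, 0.0,
                                          True, seed), mask=mask)
    return CPFactors(weights=weights, factors=factors, rank=rank,
                     n_iter=best["n_iter"], fit=fit,
                     converged=best["converged"], seed=seed, beta=beta,
                     gamma=float(gamma), labels=labels)


def _cp_als_single(values, mask, rank, gamma, y_std, X_cov, ridge,
                   seed, tol, max_iter):
    shape = values.shape
    if seed == "svd":
        factors = [_svd_init(values, mode, rank) for mode in range(4)]
    else:
        rng = np.random.default_rng(seed)
        factors = [rng.standard_normal((dim, rank)) for dim in shape]
    if y_std is not None and gamma > 0:
        # supervised warm start: seed one component with the target profile
        # and the dominant rank-1 structure of the target-covariance tensor
        # sum_i y_i X_i, so the coupled component starts inside a basin
        # whose non-subject loadings already carry the target pattern
        factors[0][:, 0] = y_std
        cov = np.tensordot(y_std, values, axes=(0, 0)) / y_std.size
        for mode, vec in enumerate(_rank1_pattern(cov)):
            factors[mode + 1][:, 0] = vec
    beta = np.zeros(rank + (X_cov.shape[1] if X_cov is not None else 0))
    work = values.copy()
    work[mask] = 0.0
    any_masked = bool(mask.any())
    prev_obj, converged, it = np.inf, False, 0
    for it in range(1, max_iter + 1):
        if any_masked:
            rec = _rebuild(factors)
            work[mask] = rec[mask]
        if y_std is not None:
            # refit the regression on the current scores before the coupled
            # subject-mode update
            D = (np.hstack([factors[0], X_cov]) if X_cov is not None
                 else factors[0])
            G = D.T @ D + ridge * np.eye(D.shape[1])
            beta = np.linalg.solve(G, D.T @ y_std)
        for mode in range(4):
            Z = _kr_others(factors, mode)
            V = Z.T @ Z
            rhs = _unfold(work, mode) @ Z
            if mode == 0 and y_std is not None:
                beta_a = beta[:rank]
                resid = y_std - (X_cov @ beta[rank:] if X_cov is not None
                                 else 0.0)
                M = V + gamma * np.outer(beta_a, beta_a)
                rhs = rhs + gamma * np.outer(resid, beta_a)
                factors[mode] = _solve_right(M, rhs)
            else:
                factors[mode] = _solve_right(V, rhs)
        if y_std is not None:
            D = (np.hstack([factors[0], X_cov]) if X_cov is not None
                 else factors[0])
            G = D.T @ D + ridge * np.eye(D.shape[1])
            beta = np.linalg.solve(G, D.T @ y_std)
        obj = _objective(work, factors, gamma, y_std, X_cov, beta, rank,
                         ridge)
        if np.isfinite(prev_obj) and \
                prev_obj - obj <= tol * max(abs(prev_obj), 1e-30):
            converged = True
            prev_obj = obj
            break
        prev_obj = obj
    return {"factors": factors, "beta": beta if y_std is not None else None,
            "objective": prev_obj, "n_iter": it, "converged": converged}


def _rank1_pattern(G: np.ndarray, n_iter: int = 20) -> list[np.ndarray]:
    """Dominant rank-1 factors (unit norm) of a small 3-way tensor by
    alternating power iteration."""
    vecs = []
    for mode in range(3):
        u, s, _ = np.linalg.svd(_unfold(G, mode), full_matrices=False)
        vecs.append(u[:, 0])
    contractions = ["ijk,j,k->i", "ijk,i,k->j", "ijk,i,j->k"]
    for _ in range(n_iter):
        for mode in range(3):
            others = [v for i, v in enumerate(vecs) if i != mode]
            contracted = np.einsum(contractions[mode], G, *others)
            nrm = np.linalg.norm(contracted)
            if nrm == 0:
                break
            vecs[mode] = contracted / nrm
    return vecs


def _svd_init(values: np.ndarray, mode: int, rank: int) -> np.ndarray:
    """Leading left singular vectors of the mode unfolding (zero-padded
    columns when the mode dimension is below the rank)."""
    u, _, _ = np.linalg.svd(_unfold(values, mode), full_matrices=False)
    dim = values.shape[mode]
    if u.shape[1] >= rank:
        return u[:, :rank].copy()
    out = np.zeros((dim, rank))
    out[:, : u.shape[1]] = u
    return out


def _solve_right(M: np.ndarray, rhs: np.ndarray) -> np.ndarray:
    """Solve X M = rhs for X, with pseudo-inverse fallback."""
    try:
        return np.linalg.solve(M.T, rhs.T).T
    except np.linalg.LinAlgError:
        return rhs @ np.linalg.pinv(M)


def _rebuild(factors: list[np.ndarray]) -> np.ndarray:
    Z = _kr_others(factors, 0)
    shape = tuple(f.shape[0] for f in factors)
    return (factors[0] @ Z.T).reshape(shape)


def _objective(work, factors, gamma, y_std, X_cov, beta, rank, ridge):
    err = float(np.sum((work - _rebuild(factors)) ** 2))
    if y_std is None or gamma == 0:
        return err + (0.0 if y_std is None else 0.0)
    D = np.hstack([factors[0], X_cov]) if X_cov is not None else factors[0]
    pred_loss = float(np.sum((y_std - D @ beta) ** 2))
    return err + gamma * (pred_loss + ridge * float(beta @ beta))


def _normalize_factors(factors):
    rank = factors[0].shape[1]
    weights = np.ones(rank)
    out = []
    for f in factors:
        norms = np.linalg.norm(f, axis=0)
        norms[norms == 0] = 1.0
        weights = weights * norms
        out.append(f / norms)
    # sign convention: make each column's largest-magnitude subject loading
    # positive, folding signs into the other modes pairwise
    for r in range(rank):
        for mode in range(1, 4):
            if out[mode][np.argmax(np.abs(out[mode][:, r])), r] < 0:
                out[mode][:, r] *= -1
                out[0][:, r] *= -1
    order = np.argsort(weights)[::-1]
    return weights[order], [f[:, order] for f in out]


def project_subjects(F: CPFactors, slices: np.ndarray,
                     mask: np.ndarray | None = None) -> np.ndarray:
    """Subject scores for new data given fixed non-subject factors.

    ``slices`` has shape (n_new, Ns, Nf, Nm). Each subject's observed
    entries are regressed onto the weighted Khatri-Rao basis of the sensor,
    band and measure factors; the returned scores live on the same scale as
    the training subject factor.
    """
    slices = np.asarray(slices, dtype=float)
    if slices.ndim == 3:
        slices = slices[None]
    n_new = slices.shape[0]
    Zw = _kr_others(F.factors, 0) * F.weights
    X = slices.reshape(n_new, -1)
    if mask is None:
        scores, *_ = np.linalg.lstsq(Zw, X.T, rcond=None)
        return scores.T
    mask = np.asarray(mask, dtype=bool).reshape(n_new, -1)
    out = np.zeros((n_new, F.rank))
    for i in range(n_new):
        obs = ~mask[i]
        if obs.sum() < F.rank:
            continue
        sol, *_ = np.linalg.lstsq(Zw[obs], X[i, obs], rcond=None)
        out[i] = sol
    return out
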