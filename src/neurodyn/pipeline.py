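"""End-to-end pipeline: simulate -> features -> tensor -> factorize -> predict.

Every stage reads and writes plain files under one working directory, so a
run is resumable: a stage whose outputs already exist is skipped. The fully
resolved configuration (a JSON-serializable dataclass tree) is written next
to the artifacts, and together with the seed it determines every output.
"""

from __future__ import annotations

import dataclasses
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .invariants import FeatureConfig, extract_features
from .io import (read_cohort_csv, read_recording, save_json, load_json,
                 write_cohort_csv, write_recording_csv)
from .predict import crossval_factor_regression
from .simulate import SyntheticCohortSpec, generate_cohort
from .tensor import FeatureTensor, assemble_tensor, normalize_tensor

log = logging.getLogger("neurodyn")


@dataclass
class TensorConfig:
    rank: int = 3
    gamma: float | str = "auto"
    normalization: str = "zscore_per_measure"
    seed: int = 0
    n_starts: int = 3
    tol: float = 1e-7
    max_iter: int = 200


@dataclass
class CVConfig:
    k: int = 5
    regressor: str = "random_forest"
    seed: int = 0
    supervised: bool = True
    use_sex_covariate: bool = False


@dataclass
class PipelineConfig:
    """Resolved configuration of one pipeline run (losslessly serializable)."""

    workdir: str = "neurodyn_run"
    simulate: SyntheticCohortSpec | None = None
    features: FeatureConfig = field(default_factory=FeatureConfig)
    tensor: TensorConfig = field(default_factory=TensorConfig)
    cv: CVConfig = field(default_factory=CVConfig)
    recordings_dir: str | None = None   # existing data instead of simulation
    cohort_csv: str | None = None
    target_column: str = "age_months"

    def to_json(self, path: str | Path) -> Path:
        return save_json(_dataclass_to_dict(self), path)

    @classmethod
    def from_json(cls, path: str | Path) -> "PipelineConfig":
        return _config_from_dict(load_json(path))


def _dataclass_to_dict(obj):
    if dataclasses.is_dataclass(obj):
        return {f.name: _dataclass_to_dict(getattr(obj, f.name))
                for f in dataclasses.fields(obj)}
    if isinstance(obj, dict):
        return {k: _dataclass_to_dict(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_dataclass_to_dict(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


def _config_from_dict(d: dict) -> "PipelineConfig":
    sim = d.get("simulate")
    if sim is not None:
        sim = dict(sim)
        if sim.get("age_range") is not None:
            sim["age_range"] = tuple(sim["age_range"])
        sim = SyntheticCohortSpec(**sim)
    return PipelineConfig(
        workdir=d.get("workdir", "neurodyn_run"),
        simulate=sim,
        features=FeatureConfig(**d.get("features", {})),
        tensor=TensorConfig(**d.get("tensor", {})),
        cv=CVConfig(**d.get("cv", {})),
        recordings_dir=d.get("recordings_dir"),
        cohort_csv=d.get("cohort_csv"),
        target_column=d.get("target_column", "age_months"),
    )


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------

def stage_simulate(cfg: PipelineConfig) -> Path:
    """Write the synthetic cohort (one recording CSV per subject + cohort CSV)."""
    wd = Path(cfg.workdir)
    rec_dir = wd / "recordings"
    cohort_path = wd / "cohort.csv"
    if cohort_path.exists() and rec_dir.exists():
        log.info("simulate: outputs exist, skipping")
        return rec_dir
    if cfg.simulate is None:
        raise ValueError("config has no simulation spec")
    rec_dir.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    recs, cohort = generate_cohort(cfg.simulate)
    for rec in recs:
        write_recording_csv(rec, rec_dir / f"{rec.meta['subject_id']}.csv")
    write_cohort_csv(cohort, cohort_path)
    log.info("simulate: %d subjects in %.1fs", len(recs), time.time() - t0)
    return rec_dir


def stage_features(cfg: PipelineConfig) -> Path:
    """Extract per-subject feature tables (one CSV per subject)."""
    wd = Path(cfg.workdir)
    rec_dir = Path(cfg.recordings_dir) if cfg.recordings_dir else wd / "recordings"
    cohort = read_cohort_csv(cfg.cohort_csv or wd / "cohort.csv")
    feat_dir = wd / "features"
    feat_dir.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    n_done = 0
    for sid in cohort["subject_id"]:
        out = feat_dir / f"{sid}.csv"
        if out.exists():
            continue
        candidates = [rec_dir / f"{sid}.csv", rec_dir / f"{sid}.edf"]
        path = next((p for p in candidates if p.exists()), None)
        if path is None:
            raise FileNotFoundError(f"no recording found for subject {sid}")
        rec = read_recording(path)
        table = extract_features(rec, cfg.features)
        table.to_csv(out, index=False)
        n_done += 1
    log.info("features: %d subjects computed in %.1fs", n_done,
             time.time() - t0)
    return feat_dir


def stage_tensor(cfg: PipelineConfig) -> Path:
    """Assemble and normalize the 4-way feature tensor."""
    wd = Path(cfg.workdir)
    out = wd / "tensor"
    if (out / "tensor.npz").exists():
        log.info("tensor: output exists, skipping")
        return out
    cohort = read_cohort_csv(cfg.cohort_csv or wd / "cohort.csv")
    feat_dir = wd / "features"
    tables = {sid: pd.read_csv(feat_dir / f"{sid}.csv")
              for sid in cohort["subject_id"]}
    T = assemble_tensor(tables, cohort)
    T = normalize_tensor(T, cfg.tensor.normalization)
    T.save(out)
    return out


def stage_factorize(cfg: PipelineConfig) -> Path:
    """Factorize the full tensor once (for inspection / loading plots)."""
    from .tensor import SupervisionSpec, cp_decompose, supervised_cp

    wd = Path(cfg.workdir)
    out = wd / "factors"
    if (out / "weights.csv").exists():
        log.info("factorize: output exists, skipping")
        return out
    T = FeatureTensor.load(wd / "tensor")
    cohort = read_cohort_csv(cfg.cohort_csv or wd / "cohort.csv")
    target = cohort[cfg.target_column].to_numpy(dtype=float)
    tc = cfg.tensor
    if cfg.cv.supervised:
        cov = (cohort[["sex"]].to_numpy(dtype=float)
               if cfg.cv.use_sex_covariate and "sex" in cohort else None)
        sup = SupervisionSpec(target=target, covariates=cov, gamma=tc.gamma)
        F = supervised_cp(T, tc.rank, sup, seed=tc.seed, tol=tc.tol,
                          max_iter=tc.max_iter, n_starts=tc.n_starts)
    else:
        F = cp_decompose(T, tc.rank, seed=tc.seed, tol=tc.tol,
                         max_iter=tc.max_iter, n_starts=tc.n_starts)
    F.export_csv(out)
    save_json({"fit": F.fit, "n_iter": F.n_iter, "converged": F.converged,
               "gamma": F.gamma, "rank": F.rank, "seed": F.seed,
               "version": __version__}, out / "factorization.json")
    return out


def stage_predict(cfg: PipelineConfig) -> Path:
    """Per-fold factorization + regression; writes metrics and predictions."""
    wd = Path(cfg.workdir)
    out = wd / "predictions"
    if (out / "results.json").exists():
        log.info("predict: output exists, skipping")
        return out
    out.mkdir(parents=True, exist_ok=True)
    T = FeatureTensor.load(wd / "tensor")
    cohort = read_cohort_csv(cfg.cohort_csv or wd / "cohort.csv")
    target = cohort[cfg.target_column].to_numpy(dtype=float)
    cov = (cohort[["sex"]].to_numpy(dtype=float)
           if cfg.cv.use_sex_covariate and "sex" in cohort else None)
    res = crossval_factor_regression(
        T, target, rank=cfg.tensor.rank, k=cfg.cv.k,
        supervised=cfg.cv.supervised, gamma=cfg.tensor.gamma,
        covariates=cov, regressor=cfg.cv.regressor, seed=cfg.cv.seed,
        n_starts=cfg.tensor.n_starts, tol=cfg.tensor.tol,
        max_iter=cfg.tensor.max_iter)
    save_json(res.to_dict(), out / "results.json")
    pd.DataFrame({
        "subject_id": cohort["subject_id"],
        "target": res.target,
        "prediction": res.predictions,
        "fold": res.fold_assignment,
    }).to_csv(out / "predictions.csv", index=False)
    return out


STAGES = {
    "simulate": stage_simulate,
    "features": stage_features,
    "tensor": stage_tensor,
    "factorize": stage_factorize,
    "predict": stage_predict,
}


def run_pipeline(cfg: PipelineConfig, stages: list[str] | None = None) -> Path:
    """Run the requested stages (default: all applicable) in order."""
    wd = Path(cfg.workdir)
    wd.mkdir(parents=True, exist_ok=True)
    cfg.to_json(wd / "config.json")
    if stages is None:
        stages = [s for s in STAGES
                  if s != "simulate" or cfg.simulate is not None]
    for name in stages:
        if name not in STAGES:
            raise ValueError(f"unknown stage: {name!r}")
        log.info("stage %s ...", name)
        try:
            STAGES[name](cfg)
        except Exception as exc:
            raise RuntimeError(f"stage {name!r} failed: {exc}") from exc
    return wd
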