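"""End-to-end pipeline: simulate -> multi-seed train -> select -> compare.

Stages are cached by content hash (config slice + input files), so a rerun
on a completed directory recomputes nothing; a machine-readable manifest
records versions, seeds and per-stage metrics.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .features import FeatureMatrix, rectify
from .model import (PointEmbedding, PriorSpec, TrainConfig, VICE)
from .reliability import RunCollection, select_best_run, split_half_reliability
from .rsa import (dims_needed, match_dimensions, rsm_correlation,
                  rsm_from_embedding)
from .synthetic import GroundTruth, generate_embedding, generate_features, \
    simulate_dataset
from .triplets import TripletDataset

__all__ = ["PipelineConfig", "run_pipeline"]

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Configuration for one pipeline run; see ``from_yaml`` for file form."""

    out_dir: str
    # inputs: either existing files, or synthetic generation settings
    features_path: str | None = None
    triplets_path: str | None = None
    synth: dict = field(default_factory=dict)  # m, k, sparsity, n, mode, d
    train: dict = field(default_factory=dict)  # TrainConfig fields
    prior: dict = field(default_factory=dict)  # PriorSpec fields
    n_seeds: int = 32
    base_seed: int = 0
    compare: dict = field(default_factory=dict)  # context, n_ctx, fraction

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def validate(self) -> None:
        for name in ("features_path", "triplets_path"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"{name}: no such file {p!r}")
        if self.triplets_path is None and not self.synth:
            raise ValueError("provide triplets_path or a synth block")
        if self.n_seeds < 1:
            raise ValueError("n_seeds must be >= 1")

    @property
    def seeds(self) -> list[int]:
        return [self.base_seed + i for i in range(self.n_seeds)]


def _hash(*parts: object) -> str:
    h = hashlib.sha256()
    for p in parts:
        if isinstance(p, (str, Path)) and Path(str(p)).is_file():
            h.update(Path(str(p)).read_bytes())
        else:
            h.update(json.dumps(p, sort_keys=True, default=str).encode())
    return h.hexdigest()[:16]


class _Manifest:
    def __init__(self, path: Path) -> None:
        self.path = path
        self.data = json.loads(path.read_text()) if path.exists() else {
            "version": __version__, "stages": {}}

    def fresh(self, stage: str, key: str, outputs: list[Path]) -> bool:
        rec = self.data["stages"].get(stage)
        return (rec is not None and rec["hash"] == key
                and all(Path(o).exists() for o in rec["outputs"]))

    def record(self, stage: str, key: str, outputs: list[Path],
               metrics: dict) -> None:
        self.data["stages"][stage] = {
            "hash": key, "outputs": [str(o) for o in outputs],
            "metrics": metrics, "time": time.time()}
        self.path.write_text(json.dumps(self.data, indent=2))

    def metrics(self, stage: str) -> dict:
        return self.data["stages"][stage]["metrics"]


def _log(stage: str, **kv) -> None:
    logger.info(json.dumps({"stage": stage, **kv}))


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute all stages; returns the run directory.

    Any stage whose inputs (by content hash) are unchanged and whose
    outputs exist is skipped. A stage failure propagates with the stage
    name attached.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = _Manifest(out / "manifest.json")
    try:
        feats_path, trips_path = _stage_inputs(config, out, manifest)
        run_paths = _stage_train(config, out, manifest, trips_path)
        best_path = _stage_reliability(config, out, manifest, run_paths)
        _stage_compare(config, out, manifest, best_path, feats_path)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage failed: {exc}") from exc
    return out


def _stage_inputs(config: PipelineConfig, out: Path, manifest: _Manifest
                  ) -> tuple[Path | None, Path]:
    if config.triplets_path is not None:
        return (Path(config.features_path) if config.features_path else None,
                Path(config.triplets_path))
    s = dict(config.synth)
    key = _hash("synth", s, config.base_seed)
    feats_path = out / "features.npz"
    trips_path = out / "triplets.tsv"
    truth_path = out / "truth_embedding.tsv"
    outputs = [feats_path, trips_path, truth_path]
    if not manifest.fresh("inputs", key, outputs):
        truth = GroundTruth(
            generate_embedding(s.get("m", 60), s.get("k", 6),
                               s.get("sparsity", 0.6), s.get("scale", 1.0),
                               config.base_seed),
            noise_sd=s.get("noise_sd", 0.1), seed=config.base_seed)
        truth.embedding.save(truth_path)
        feats = generate_features(truth, s.get("d", 2 * s.get("k", 6)))
        feats.save(feats_path)
        data = simulate_dataset(truth, s.get("n", 50_000),
                                s.get("mode", "argmax"),
                                s.get("temperature", 1.0), config.base_seed)
        data.save(trips_path)
        manifest.record("inputs", key, outputs,
                        {"m": truth.embedding.m, "k": truth.embedding.k,
                         "n": data.n})
        _log("inputs", n=data.n, m=truth.embedding.m)
    return feats_path, trips_path


def _stage_train(config: PipelineConfig, out: Path, manifest: _Manifest,
                 trips_path: Path) -> list[Path]:
    key = _hash("train", trips_path, config.train, config.prior, config.seeds)
    runs_dir = out / "runs"
    runs_dir.mkdir(exist_ok=True)
    paths = [runs_dir / f"embedding_seed{s}.tsv" for s in config.seeds]
    if not manifest.fresh("train", key, paths):
        data = TripletDataset.load(trips_path)
        cfg = TrainConfig(**config.train)
        prior = PriorSpec(**config.prior)
        metrics = {}
        for seed, path in zip(config.seeds, paths):
            res = VICE(data, cfg, prior).fit(seed=seed)
            res.point_estimate().save(path)
            metrics[f"seed_{seed}"] = {"n_dims": res.n_dims,
                                       "epochs": res.n_epochs,
                                       "accuracy": res.accuracy(data)}
            _log("train", seed=seed, n_dims=res.n_dims, epochs=res.n_epochs)
        manifest.record("train", key, paths, metrics)
    return paths


def _stage_reliability(config: PipelineConfig, out: Path, manifest: _Manifest,
                       run_paths: list[Path]) -> Path:
    key = _hash("reliability", *run_paths)
    report = out / "reliability.tsv"
    best_path = out / "embedding_selected.tsv"
    outputs = [report, best_path]
    if not manifest.fresh("reliability", key, outputs):
        runs = RunCollection([PointEmbedding.load(p) for p in run_paths],
                             list(config.seeds))
        if len(run_paths) >= 2:
            rel = split_half_reliability(runs)
            best = select_best_run(runs, rel)
        else:
            rel, best = np.array([np.nan]), 0
        with open(report, "w") as fh:
            fh.write("seed\treliability_r\n")
            for s, r in zip(config.seeds, rel):
                fh.write(f"{s}\t{r:.6f}\n")
        runs.runs[best].save(best_path)
        manifest.record("reliability", key, outputs,
                        {"best_seed": config.seeds[best],
                         "reliability": [float(r) for r in rel]})
        _log("reliability", best_seed=config.seeds[best])
    return best_path


def _stage_compare(config: PipelineConfig, out: Path, manifest: _Manifest,
                   best_path: Path, feats_path: Path | None) -> None:
    if feats_path is None:
        return
    key = _hash("compare", best_path, feats_path, config.compare)
    report = out / "comparison.json"
    if manifest.fresh("compare", key, [report]):
        return
    opts = dict(config.compare)
    Y = PointEmbedding.load(best_path)
    feats = rectify(FeatureMatrix.load(feats_path))
    ref_emb = PointEmbedding(feats.values, list(feats.object_ids))
    context = opts.get("context", "all" if Y.m <= 300 else "sampled")
    ref_rsm = rsm_from_embedding(ref_emb, context)
    emb_rsm = rsm_from_embedding(Y, context)
    match = match_dimensions(Y, ref_emb, unique=opts.get("unique", True))
    metrics = {
        "rsm_r": rsm_correlation(emb_rsm, ref_rsm),
        "matched_r": [round(r, 4) for r in match.correlations],
        "n_dims": Y.k,
    }
    try:
        metrics["dims_needed_95"] = dims_needed(
            Y, ref_rsm, match.source_dims,
            opts.get("variance_fraction", 0.95), context=context)
    except ValueError:
        metrics["dims_needed_95"] = None
    report.write_text(json.dumps(metrics, indent=2))
    manifest.record("compare", key, [report], metrics)
    _log("compare", rsm_r=metrics["rsm_r"])
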