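"""Seeded end-to-end orchestration with provenance manifests.

``run_pipeline`` executes the enabled stages in order — generate VOIs,
simulate GESFIDE ratio curves, train the estimator pair, evaluate against
the dictionary baseline — writing every artifact under one output directory
and recording a manifest (file list with SHA-256 checksums plus the config
hash), so a run is fully determined by its config and master seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
from dataclasses import asdict, dataclass, field

import h5py
import numpy as np
import yaml

from .experiments import StudyConfig, generate_study_vois
from .gesfide import simulate_gesfide_batch
from .models import (
    ModelSpec,
    SignalDataset,
    filter_and_split,
    predict,
    save_model_pair,
    train_two_stage,
)

log = logging.getLogger("vsdprint")


@dataclass
class RunConfig:
    """Master configuration: stage toggles, study knobs, seed, output dir."""

    outdir: str = "vsd_run"
    seed: int = 0
    stages: tuple = ("generate", "simulate", "train", "evaluate")
    study: StudyConfig = field(default_factory=StudyConfig)
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        study_kw = raw.pop("study", {})
        model_kw = study_kw.pop("model", {})
        sim_kw = study_kw.pop("sim", {})
        study = StudyConfig(**study_kw)
        if model_kw:
            study.model = ModelSpec(**{**asdict(study.model), **model_kw})
        if sim_kw:
            for k, v in sim_kw.items():
                setattr(study.sim, k, v)
        raw.pop("sim", None)
        return cls(study=study, **{k: v for k, v in raw.items() if k in ("outdir", "seed", "stages", "log_level")})

    def config_hash(self) -> str:
        payload = _serializable(self)
        payload.pop("outdir", None)  # content-irrelevant
        payload.pop("log_level", None)
        blob = json.dumps(payload, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _serializable(obj):
    if hasattr(obj, "__dataclass_fields__"):
        return {k: _serializable(v) for k, v in vars(obj).items()}
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (list, tuple)):
        return [_serializable(v) for v in obj]
    if isinstance(obj, dict):
        return {k: _serializable(v) for k, v in obj.items()}
    return obj


def run_pipeline(config: RunConfig) -> dict:
    """Execute the enabled stages; returns the manifest (also written to disk).

    Stage failure aborts with the stage name; artifacts written so far are
    retained.  A stage that needs a missing upstream artifact (e.g. predict
    without a checkpoint) raises a clear error naming the missing file.
    """
    logging.basicConfig(level=config.log_level)
    os.makedirs(config.outdir, exist_ok=True)
    manifest = {"config_hash": config.config_hash(), "seed": config.seed, "outputs": {}}
    paths = {
        "dataset": os.path.join(config.outdir, "dataset.h5"),
        "models": os.path.join(config.outdir, "models.npz"),
        "metrics": os.path.join(config.outdir, "metrics.json"),
    }
    cfg = config.study

    try:
        if "generate" in config.stages or "simulate" in config.stages:
            log.info("generating %d VOIs", cfg.n_vois)
            occ, cbv, vsd = generate_study_vois(cfg, config.seed)
            log.info("simulating GESFIDE ratio curves")
            signals = simulate_gesfide_batch(occ, cfg.sim_grid, cfg.sim)
            ds = filter_and_split(signals, cbv, vsd, seed=config.seed,
                                  provenance={"config_hash": manifest["config_hash"]})
            _write_dataset(paths["dataset"], ds)
            manifest["outputs"]["dataset"] = _checksum(paths["dataset"])

        if "train" in config.stages:
            ds = _read_dataset(paths["dataset"])
            log.info("training two-stage estimator")
            models = train_two_stage(ds, cfg.model, seed=config.seed)
            save_model_pair(models, paths["models"])
            manifest["outputs"]["models"] = _checksum(paths["models"])

        if "evaluate" in config.stages:
            from .baselines import Dictionary, dictionary_match_batch
            from .evaluation import evaluate_predictions
            from .models import load_model_pair

            for need in ("dataset", "models"):
                if not os.path.exists(paths[need]):
                    raise FileNotFoundError(
                        f"evaluate stage requires {paths[need]} (run the earlier stages first)"
                    )
            ds = _read_dataset(paths["dataset"])
            models = load_model_pair(paths["models"])
            xt, cbv_t, vsd_t = ds.split("test")
            pred_cbv, pred_vsd = predict(models, xt)
            report = evaluate_predictions(cbv_t, pred_cbv, vsd_t, pred_vsd).to_dict()
            xtr, cbv_tr, vsd_tr = ds.split("train")
            d_cbv, d_vsd, _ = dictionary_match_batch(xt, Dictionary(xtr, cbv_tr, vsd_tr))
            report["dictionary"] = evaluate_predictions(cbv_t, d_cbv, vsd_t, d_vsd).to_dict()
            with open(paths["metrics"], "w") as fh:
                json.dump(report, fh, indent=2)
            manifest["outputs"]["metrics"] = _checksum(paths["metrics"])
    except Exception as exc:  # noqa: BLE001 - re-raise with stage context
        raise RuntimeError(f"pipeline aborted: {exc}") from exc

    mpath = os.path.join(config.outdir, "manifest.json")
    with open(mpath, "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest


def _checksum(path: str) -> dict:
    digest = hashlib.sha256()
    with open(path, "rb") as fh:
        for block in iter(lambda: fh.read(1 << 20), b""):
            digest.update(block)
    return {"path": path, "sha256": digest.hexdigest()}


def _write_dataset(path: str, ds: SignalDataset) -> None:
    with h5py.File(path, "w") as fh:
        # track_times=False keeps file checksums reproducible across reruns
        fh.create_dataset("signals", data=ds.signals, track_times=False)
        fh.create_dataset("cbv_labels", data=ds.cbv_labels, track_times=False)
        fh.create_dataset("vsd_labels", data=ds.vsd_labels, track_times=False)
        fh.create_dataset(
            "partition", data=np.array([p.encode() for p in ds.partition]), track_times=False
        )
        fh.attrs["provenance"] = json.dumps(_serializable(ds.provenance), default=str)


def _read_dataset(path: str) -> SignalDataset:
    if not os.path.exists(path):
        raise FileNotFoundError(f"missing dataset file {path}")
    with h5py.File(path, "r") as fh:
        return SignalDataset(
            signals=fh["signals"][:],
            cbv_labels=fh["cbv_labels"][:],
            vsd_labels=fh["vsd_labels"][:],
            partition=np.array([p.decode() for p in fh["partition"][:]]),
            provenance=json.loads(fh.attrs.get("provenance", "{}")),
        )
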