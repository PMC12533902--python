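"""End-to-end reproducible pipeline: generate -> preprocess -> extract ->
select -> split -> train -> evaluate, with every intermediate persisted and
a manifest of hashes and seeds.

A single global seed deterministically derives every stage seed, so two runs
with the same configuration produce identical artifacts.
"""

from __future__ import annotations

import dataclasses
import hashlib
import logging
import time
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import io as cio
from .datatypes import BeatTable, FeatureTable, ImageSet
from .features import extract_all
from .metrics import classification_report
from .model import CiladConfig, SplitSpec, build_cilad, predict, split_data, train_model
from .preprocess import (DenoiseSpec, clean_metadata, hist_equalize, impute_mean,
                         minmax_normalize, resize_bilinear, wavelet_denoise,
                         winsorize_outliers)
from .select import score_features, select_top
from .synthetic_data import (gen_cardiac_images, gen_ecg_beats, gen_metadata,
                             gen_patient_records)

log = logging.getLogger("cilad.pipeline")

MODALITIES = ("ecg", "image", "tabular", "metadata")


def derive_seed(global_seed: int, stage: str) -> int:
    """Deterministically derive a stage seed below 2**31 from the global seed."""
    return (int(global_seed) * 1000003 + zlib.crc32(stage.encode())) % (2 ** 31)


@dataclass
class PipelineConfig:
    """Every tunable parameter of every stage, with desk-scale defaults."""

    seed: int = 0
    out_dir: str = "pipeline_out"
    log_level: str = "INFO"
    skip_select: bool = False
    generate: dict = field(default_factory=lambda: {
        "ecg": {"n_per_class": 80, "n_classes": 5, "beat_len": 187,
                "noise_sd": 0.05, "separation": 1.0},
        "image": {"n_per_class": 20, "size": 64, "n_classes": 3},
        "tabular": {"n": 600, "n_signal": 5, "n_noise": 8,
                    "missing_frac": 0.05, "outlier_frac": 0.02},
        "metadata": {"n": 600, "duplicate_frac": 0.05},
    })
    preprocess: dict = field(default_factory=lambda: {
        "wavelet": "db4", "level": 3, "threshold_rule": "universal-hard",
        "normalize_lo": 0.0, "normalize_hi": 1.0,
        "image_size": 64, "levels": 256,
        "zscore_threshold": 3.0, "winsorize": True,
    })
    features: dict = field(default_factory=lambda: {
        "glcm_distance": 1, "glcm_levels": 16, "lbp_radius": 1, "lbp_points": 8,
        "qrs_theta": 0.2,
    })
    select: dict = field(default_factory=lambda: {
        "alpha": 0.5, "k_neighbors": 10, "n_iterations": None, "top_k": 10,
    })
    model: dict = field(default_factory=lambda: {
        "epochs": 5, "batch_size": 32, "lr": 1e-3, "kernel": 3, "pool": 2,
        "filters1": 32, "filters2": 64, "inception_branch": 16,
        "lstm_units": 64, "path2_filters": 128, "fc": [128, 64],
        "dropout": 0.5, "head_dropout": 0.5,
    })
    metrics: dict = field(default_factory=lambda: {"averaging": "macro"})
    split: dict = field(default_factory=lambda: {"train_fraction": 0.8,
                                                 "stratified": True})
    nutri: dict = field(default_factory=lambda: {
        "horizon": 5, "n_items": 20, "profile": "hypertension",
        "alpha": 1.0, "beta": 1.0, "gamma_pref": 0.5, "delta_div": 0.3,
        "eta_cost": 0.1, "lambda_viol": 1.0, "rho": 0.5, "kappa_cost": 0.05,
    })
    ppo: dict = field(default_factory=lambda: {
        "clip_eps": 0.2, "c_entropy": 0.01, "c_value": 0.5, "gamma": 0.99,
        "lam": 0.95, "lr": 3e-4, "update_epochs": 4, "minibatch": 64,
        "rollout": 1024, "updates": 50,
    })

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        data = cio.read_yaml(path)
        cfg = cls()
        for key, value in data.items():
            if not hasattr(cfg, key):
                raise ValueError(f"unknown config block {key!r}")
            current = getattr(cfg, key)
            if isinstance(current, dict) and isinstance(value, dict):
                for sub_key, sub_value in value.items():
                    if isinstance(current.get(sub_key), dict):
                        current[sub_key].update(sub_value)
                    else:
                        current[sub_key] = sub_value
            else:
                setattr(cfg, key, value)
        return cfg


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


class Manifest:
    def __init__(self, config: PipelineConfig, modality: str):
        from . import __version__
        self.entries: list[dict] = []
        self.info = {"version": __version__, "seed": config.seed,
                     "modality": modality, "config": config.to_dict()}

    def record(self, stage: str, path: Path, t0: float) -> None:
        entry = {"stage": stage, "file": str(path), "sha256": _sha256(path),
                 "wall_time_s": round(time.time() - t0, 3)}
        self.entries.append(entry)
        log.info("stage=%s file=%s sha=%s", stage, path.name,
                 entry["sha256"][:12])

    def write(self, path: Path) -> None:
        cio.write_json({"info": self.info, "stages": self.entries}, path)


# --------------------------------------------------------------------------
# Stage implementations per modality
# --------------------------------------------------------------------------

def _generate(config: PipelineConfig, modality: str):
    seed = derive_seed(config.seed, f"generate/{modality}")
    g = config.generate[modality]
    if modality == "ecg":
        return gen_ecg_beats(seed=seed, **g)
    if modality == "image":
        return gen_cardiac_images(seed=seed, **g)
    if modality == "tabular":
        return gen_patient_records(seed=seed, **g)
    return gen_metadata(seed=seed, **g)


def _preprocess(config: PipelineConfig, modality: str, data):
    p = config.preprocess
    if modality == "ecg":
        spec = DenoiseSpec(p["wavelet"], p["level"], p["threshold_rule"])
        signals = np.stack([
            minmax_normalize(wavelet_denoise(beat, spec),
                             p["normalize_lo"], p["normalize_hi"])
            for beat in data.signals])
        return BeatTable(signals, data.labels, data.fs)
    if modality == "image":
        size = p["image_size"]
        images, masks = [], []
        for img, mask in zip(data.images, data.masks or [None] * len(data)):
            eq = hist_equalize(img, p["levels"])
            images.append(np.rint(resize_bilinear(eq, size, size)).astype(int))
            if mask is not None:
                masks.append(resize_bilinear(mask.astype(float), size, size) > 0.5)
        return ImageSet(images, data.labels, masks or None, levels=p["levels"])
    if modality == "tabular":
        table = impute_mean(data)
        if p["winsorize"]:
            for col in table.frame.columns:
                table.frame[col] = winsorize_outliers(
                    table.frame[col].to_numpy(), p["zscore_threshold"])
        return table
    cleaned = clean_metadata(data)
    return impute_mean(cleaned)


def _train_eval(config: PipelineConfig, features: FeatureTable,
                manifest_dir: Path | None = None) -> dict:
    m = dict(config.model)
    seed = derive_seed(config.seed, "train")
    n_classes = int(np.max(features.labels)) + 1
    cfg = CiladConfig(input_len=features.n_features, n_classes=n_classes,
                      seed=seed, fc=tuple(m.pop("fc")), **m)
    spec = SplitSpec(config.split["train_fraction"], config.split["stratified"],
                     derive_seed(config.seed, "split"))
    train, test = split_data(features, spec)
    net = build_cilad(cfg)
    history = train_model(net, train.values, train.labels,
                          val=(test.values, test.labels), config=cfg)
    _, labels = predict(net, test.values)
    report = classification_report(test.labels, labels,
                                   averaging=config.metrics["averaging"])
    if manifest_dir is not None:
        history.to_csv(manifest_dir / "history.csv", index=False)
    return {"report": report, "history": history, "n_features": features.n_features,
            "n_train": len(train.labels), "n_test": len(test.labels)}


def run_pipeline(config: PipelineConfig, modality: str) -> dict:
    """Run the full chain for one modality; artifacts land in
    ``config.out_dir/<modality>`` with a manifest.  Returns a dict with the
    evaluation report and stage outputs."""
    if modality not in MODALITIES:
        raise ValueError(f"modality must be one of {MODALITIES}")
    for block in ("generate", "preprocess", "features", "select", "model",
                  "metrics", "split"):
        if getattr(config, block, None) is None:
            raise ValueError(f"missing config block {block!r}")
    logging.basicConfig(level=getattr(logging, config.log_level, logging.INFO))
    out = Path(config.out_dir) / modality
    out.mkdir(parents=True, exist_ok=True)
    manifest = Manifest(config, modality)

    t0 = time.time()
    raw = _generate(config, modality)
    if modality == "ecg":
        cio.write_beats_csv(raw, out / "raw_beats.csv")
        manifest.record("generate", out / "raw_beats.csv", t0)
    elif modality == "image":
        cio.write_imageset(raw, out / "raw_images")
        manifest.record("generate", out / "raw_images" / "labels.csv", t0)
    else:
        cio.write_records_csv(raw, out / "raw_records.csv")
        manifest.record("generate", out / "raw_records.csv", t0)

    t0 = time.time()
    clean = _preprocess(config, modality, raw)

    features = extract_all("ecg" if modality == "ecg" else
                           "image" if modality == "image" else
                           "tabular" if modality == "tabular" else "metadata",
                           clean)
    cio.write_features_csv(features, out / "features.csv")
    manifest.record("extract", out / "features.csv", t0)

    selected_names = features.names
    if not config.skip_select:
        t0 = time.time()
        s = config.select
        scores = score_features(features, alpha=s["alpha"],
                                k_neighbors=min(s["k_neighbors"],
                                                _min_class_size(features) - 1),
                                n_iterations=s["n_iterations"],
                                seed=derive_seed(config.seed, "select"))
        top = select_top(scores, k=min(s["top_k"], features.n_features))
        features = FeatureTable([features.names[j] for j in top],
                                features.values[:, top], features.labels)
        selected_names = features.names
        frame = scores_frame(scores)
        frame.to_csv(out / "selection_scores.csv", index=False)
        manifest.record("select", out / "selection_scores.csv", t0)

    t0 = time.time()
    result = _train_eval(config, features, manifest_dir=out)
    cio.write_json(result["report"].to_dict(), out / "report.json")
    manifest.record("evaluate", out / "report.json", t0)
    manifest.write(out / "manifest.json")
    return {"report": result["report"], "history": result["history"],
            "selected_features": selected_names,
            "n_features": result["n_features"], "out_dir": str(out)}


def _min_class_size(features: FeatureTable) -> int:
    _, counts = np.unique(features.labels, return_counts=True)
    return int(counts.min())


def scores_frame(scores):
    import pandas as pd
    return pd.DataFrame({
        "feature": scores.names, "relieff": scores.relieff,
        "pearson": scores.pearson, "relieff_scaled": scores.relieff_scaled,
        "pearson_scaled": scores.pearson_scaled, "combined": scores.combined,
        "rank": scores.rank,
    })
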