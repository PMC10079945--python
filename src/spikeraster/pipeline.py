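"""End-to-end orchestration: simulate -> window -> rasterize -> train -> report.

All randomness flows from one top-level seed; each stage derives its own
sub-seed by hashing the stage name, so stages are independently
re-runnable yet jointly reproducible from (config, seed).
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path

import numpy as np
import yaml

from . import metrics as metrics_mod
from .model import CNNConfig, build_model, resize_for_model, save_model
from .preprocess import (SplitSpec, WindowSet, balance_noise, l2_normalize,
                         rescale_unit_interval, save_windowset, segment, split,
                         write_split_manifest)
from .raster import RasterConfig, rasterize_windowset, write_image_batch
from .synth import SimulationConfig, SpikeParams, save_recording, simulate_recording

__all__ = [
    "PipelineConfig",
    "derive_seed",
    "run_pipeline",
    "scaled_down_config",
    "smoke_config",
]

log = logging.getLogger("spikeraster")


def derive_seed(master: int, stage: str) -> int:
    """Deterministic per-stage sub-seed, below 2**31."""
    digest = hashlib.sha256(f"{master}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


@dataclass(frozen=True)
class PipelineConfig:
    """Nested configuration of the whole experiment."""

    simulation: SimulationConfig = SimulationConfig()
    split: SplitSpec = SplitSpec()
    raster: RasterConfig = RasterConfig()
    cnn: CNNConfig = CNNConfig()
    window_len: int = 56
    noise_cap_ratio: float = 1.18
    save_images: bool = True
    log_level: str = "INFO"

    def reseeded(self, master: int) -> "PipelineConfig":
        """Propagate one top-level seed to every stage."""
        return replace(
            self,
            simulation=replace(self.simulation, seed=derive_seed(master, "simulate")),
            split=replace(self.split, seed=derive_seed(master, "split")),
            cnn=replace(self.cnn, seed=derive_seed(master, "train")),
        )

    # -- YAML round trip --------------------------------------------------
    def to_yaml(self, path: str | Path | None = None) -> str:
        doc = asdict(self)
        doc["simulation"]["templates"] = [asdict(p) for p in self.simulation.templates]
        doc["cnn"]["input_size"] = list(self.cnn.input_size)
        doc["cnn"]["conv_feature_maps"] = list(self.cnn.conv_feature_maps)
        text = yaml.safe_dump(doc, sort_keys=False)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_yaml(cls, source: str | Path) -> "PipelineConfig":
        text = Path(source).read_text() if Path(str(source)).exists() else str(source)
        doc = yaml.safe_load(text) or {}
        sim = doc.get("simulation", {})
        if "templates" in sim:
            sim["templates"] = tuple(SpikeParams(**p) for p in sim["templates"])
        cnn = doc.get("cnn", {})
        if "input_size" in cnn:
            cnn["input_size"] = tuple(cnn["input_size"])
        if "conv_feature_maps" in cnn:
            cnn["conv_feature_maps"] = tuple(cnn["conv_feature_maps"])
        return cls(
            simulation=SimulationConfig(**sim),
            split=SplitSpec(**doc.get("split", {})),
            raster=RasterConfig(**doc.get("raster", {})),
            cnn=CNNConfig(**cnn),
            **{k: doc[k] for k in
               ("window_len", "noise_cap_ratio", "save_images", "log_level")
               if k in doc},
        )


def _images_to_arrays(images, target) -> np.ndarray:
    return np.stack([resize_for_model(img, target) for img in images])


def run_pipeline(cfg: PipelineConfig, out_dir: str | Path | None = None,
                 seed: int | None = None) -> metrics_mod.MetricsReport:
    """Execute every stage and return the final evaluation report.

    With ``out_dir`` set, each stage's artifacts (recordings, window
    CSVs, split manifest, raster images with manifests when
    ``cfg.save_images``, model checkpoint, training history, predictions
    and the metrics report) are written beneath it.  With ``seed`` set,
    per-stage seeds are derived from it, overriding the per-stage seeds
    in the config.
    """
    logging.basicConfig(
        level=getattr(logging, cfg.log_level.upper(), logging.INFO),
        format="%(asctime)s %(name)s %(message)s")
    if seed is not None:
        cfg = cfg.reseeded(seed)
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
        cfg.to_yaml(out / "config.yaml")

    t0 = time.time()
    # --- simulate --------------------------------------------------------
    recordings = [
        simulate_recording(cfg.simulation, recording_index=i)
        for i in range(cfg.simulation.n_recordings)
    ]
    log.info("[simulate] %d recordings of %.0f s at snr=%.2f",
             len(recordings), cfg.simulation.duration, cfg.simulation.snr)
    if out is not None:
        rec_dir = out / "recordings"
        rec_dir.mkdir(exist_ok=True)
        for i, rec in enumerate(recordings):
            save_recording(rec, rec_dir / f"rec{i:02d}")

    # --- preprocess ------------------------------------------------------
    parts = []
    for i, rec in enumerate(recordings):
        values = rescale_unit_interval(l2_normalize(rec.samples))
        parts.append(segment(rec, cfg.window_len, values=values,
                             support_len=cfg.simulation.support_samples,
                             recording_id=f"rec{i:02d}"))
    ws = WindowSet(
        np.vstack([p.values for p in parts]),
        sum((p.labels for p in parts), []),
        sum((p.sources for p in parts), []),
    )
    ws = balance_noise(ws, cfg.noise_cap_ratio,
                       seed=derive_seed(cfg.split.seed, "balance"))
    train_ws, test_ws = split(ws, cfg.split)
    log.info("[preprocess] %d windows %s -> train %d / test %d",
             len(ws), ws.class_counts, len(train_ws), len(test_ws))
    if out is not None:
        save_windowset(train_ws, out / "train_windows.csv")
        save_windowset(test_ws, out / "test_windows.csv")
        write_split_manifest(out / "split_manifest.json", cfg.split, train_ws, test_ws)

    # --- rasterize -------------------------------------------------------
    train_imgs = rasterize_windowset(train_ws, cfg.raster)
    test_imgs = rasterize_windowset(test_ws, cfg.raster)
    h, w = train_imgs[0].shape if train_imgs else (cfg.raster.n_rows, 0)
    log.info("[rasterize] %d train + %d test images of %dx%d",
             len(train_imgs), len(test_imgs), h, w)
    if out is not None and cfg.save_images:
        write_image_batch(train_imgs, out / "images" / "train")
        write_image_batch(test_imgs, out / "images" / "test")

    # --- train -----------------------------------------------------------
    x_train = _images_to_arrays(train_imgs, cfg.cnn.input_size)
    x_test = _images_to_arrays(test_imgs, cfg.cnn.input_size)
    model = build_model(cfg.cnn)
    model.classes = sorted(set(ws.labels))  # task classes, split-independent
    model.fit(x_train, train_ws.labels, log=lambda m: log.info("[train] %s", m))
    if out is not None:
        save_model(model, out / "model")
        model.history.to_csv(out / "history.csv", index=False)

    # --- evaluate --------------------------------------------------------
    _, y_pred = model.predict(x_test)
    report = metrics_mod.evaluate(test_ws.labels, y_pred, classes=model.classes)
    log.info("[evaluate] overall accuracy %.2f%% (%.1f s total)",
             report.overall_accuracy, time.time() - t0)
    if out is not None:
        import pandas as pd
        pd.DataFrame({
            "source_id": [f"{s[0]}:{s[1]}" for s in test_ws.sources],
            "y_true": test_ws.labels,
            "y_pred": y_pred,
        }).to_csv(out / "predictions.csv", index=False)
        report.to_json(out / "report.json")
        report.to_frame().to_csv(out / "report.csv", index=False)
        manifest = {
            "stages": ["simulate", "preprocess", "rasterize", "train", "evaluate"],
            "accuracy": report.overall_accuracy,
            "n_train": len(train_ws), "n_test": len(test_ws),
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return report


def scaled_down_config(seed: int = 0, snr: float = 2.0) -> PipelineConfig:
    """Desk-scale version of the full experiment.

    Two 200 s recordings at one favorable SNR (~1,300 windows per spike
    class), coarser raster (r = 0.005, d = 4 -> 201x276 images) resized
    to 64x64, a thinner five-stage CNN, 10 epochs.  Runs on one CPU in
    minutes instead of supercomputer hours.
    """
    cfg = PipelineConfig(
        simulation=SimulationConfig(snr=snr, n_recordings=2),
        raster=RasterConfig(resolution=0.005, dummy=4),
        cnn=CNNConfig(input_size=(64, 64), conv_feature_maps=(32, 16, 16, 16, 16),
                      fc_size=128, n_classes=4, epochs=10),
        save_images=False,
    )
    return cfg.reseeded(seed)


def smoke_config(seed: int = 0) -> PipelineConfig:
    """Tiny configuration for fast smoke tests (seconds)."""
    cfg = PipelineConfig(
        simulation=SimulationConfig(duration=4.0, firing_rate=3.0, snr=4.0,
                                    n_recordings=1),
        raster=RasterConfig(resolution=0.01, dummy=2),
        cnn=CNNConfig(input_size=(32, 32), conv_feature_maps=(8, 8, 8, 8, 8),
                      fc_size=32, n_classes=4, epochs=2),
        save_images=True,
    )
    return cfg.reseeded(seed)
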