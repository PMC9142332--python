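"""End-to-end orchestration: denoise → stretch → wireframe → PFV → classifier.

The pipeline is configured by a :class:`PipelineConfig` (loadable from YAML;
unknown keys are rejected), runs in one of four modes — ``extract``,
``train``, ``evaluate``, ``predict`` — and writes every stage artifact with a
manifest (input hashes, config, seed) so deterministic stages reproduce
bit-for-bit.  Stages can be switched off individually, e.g. computing the
PFV on the raw binarized volume instead of the wireframe.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .classifier import (ClassifierConfig, TrainedModel, build_model,
                         load_model, predict_batch, save_model, train)
from .evaluation import EvalReport, compute_metrics, confusion_from_labels
from .patterns import build_vocabulary, extract_pfv, pfv_to_feature
from .preprocess import (AdaptiveMedianParams, StretchParams,
                         adaptive_median_filter, auto_stretch_limits,
                         contrast_stretch, DegenerateRangeError)
from .volumes import Volume, binarize, read_volume
from .wireframe import clap_wireframe

__all__ = ["PipelineConfig", "run_pipeline", "extract_features", "PipelineError"]

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failure, carrying the stage name and offending input."""

    def __init__(self, stage: str, path: object, cause: Exception):
        super().__init__(f"stage {stage!r} failed on input {path}: {cause}")
        self.stage, self.path, self.cause = stage, path, cause


@dataclass(frozen=True)
class DenoiseConfig:
    enabled: bool = True
    initial_window: int = 3
    max_window: int = 7
    mode: str = "3d"


@dataclass(frozen=True)
class StretchConfig:
    enabled: bool = True
    low_pct: float = 1.0
    high_pct: float = 99.0
    clip: bool = True


@dataclass(frozen=True)
class WireframeConfig:
    enabled: bool = True
    threshold: int = 128
    max_iterations: int = 100


@dataclass(frozen=True)
class PatternsConfig:
    stride: int = 3
    pad_value: int = 0
    normalize: str = "l1"


@dataclass(frozen=True)
class PipelineConfig:
    """Declarative run configuration with per-stage sections."""

    denoise: DenoiseConfig = field(default_factory=DenoiseConfig)
    stretch: StretchConfig = field(default_factory=StretchConfig)
    wireframe: WireframeConfig = field(default_factory=WireframeConfig)
    patterns: PatternsConfig = field(default_factory=PatternsConfig)
    classifier: ClassifierConfig = field(default_factory=ClassifierConfig)
    seed: int = 0
    output_dir: str = "pfv3d_run"
    verbosity: str = "INFO"

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        sections = {
            "denoise": DenoiseConfig, "stretch": StretchConfig,
            "wireframe": WireframeConfig, "patterns": PatternsConfig,
            "classifier": ClassifierConfig,
        }
        kwargs: dict = {}
        top_fields = {f.name for f in dataclasses.fields(cls)}
        for key, value in raw.items():
            if key not in top_fields:
                raise ValueError(f"unknown config key {key!r}")
            if key in sections:
                section_cls = sections[key]
                known = {f.name for f in dataclasses.fields(section_cls)}
                bad = set(value) - known
                if bad:
                    raise ValueError(f"unknown keys in section {key!r}: {sorted(bad)}")
                if key == "classifier" and "input_shape" in value:
                    value["input_shape"] = tuple(value["input_shape"])
                kwargs[key] = section_cls(**value)
            else:
                kwargs[key] = value
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    def to_dict(self) -> dict:
        return asdict(self)


def extract_features(v: Volume, cfg: PipelineConfig) -> np.ndarray:
    """Run one volume through denoise → stretch → wireframe → PFV → feature."""
    if cfg.denoise.enabled:
        params = AdaptiveMedianParams(
            initial_window=cfg.denoise.initial_window,
            max_window=min(cfg.denoise.max_window, min(v.shape) - (min(v.shape) + 1) % 2),
            mode=cfg.denoise.mode,
        )
        v = adaptive_median_filter(v, params)
    if cfg.stretch.enabled:
        try:
            limits = auto_stretch_limits(v, cfg.stretch.low_pct, cfg.stretch.high_pct)
            v = contrast_stretch(v, limits, clip=cfg.stretch.clip)
        except DegenerateRangeError:
            logger.info("histogram too concentrated; skipping contrast stretch")
    mask = binarize(v, cfg.wireframe.threshold)
    if cfg.wireframe.enabled:
        mask = clap_wireframe(mask, cfg.wireframe.max_iterations).mask
    pfv = extract_pfv(mask, stride=cfg.patterns.stride, pad_value=cfg.patterns.pad_value)
    logger.info("extracted PFV: %d windows over padded shape %s",
                pfv.n_windows, pfv.padded_shape)
    return pfv_to_feature(pfv, normalize=cfg.patterns.normalize)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_manifest(out_dir: Path, cfg: PipelineConfig, mode: str,
                    inputs: Sequence[Path], artifacts: dict,
                    partial: bool = False) -> None:
    manifest = {
        "pfv3d_version": __version__,
        "mode": mode,
        "seed": cfg.seed,
        "config": cfg.to_dict(),
        "inputs": {str(p): _sha256(p) for p in inputs if Path(p).is_file()},
        "artifacts": {k: str(v) for k, v in artifacts.items()},
        "partial": partial,
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))


def _feature_frame(names, features, labels=None) -> pd.DataFrame:
    vocab = build_vocabulary()
    cols = [vocab[i].name for i in range(256)]
    df = pd.DataFrame(np.asarray(features), columns=cols)
    df.insert(0, "sample", names)
    if labels is not None:
        df.insert(1, "label", labels)
    return df


def run_pipeline(inputs: Sequence[tuple[str | Path, Optional[str]]],
                 cfg: PipelineConfig,
                 mode: str,
                 model_path: Optional[str | Path] = None) -> dict:
    """Execute one pipeline mode over a list of (volume-path, label) pairs.

    Modes: ``extract`` writes features.csv; ``train`` additionally fits the
    configured head and writes model.npz; ``evaluate`` scores a saved model
    and writes report.json; ``predict`` writes predictions.json.  Returns a
    dict of artifact paths plus in-memory results.
    """
    if mode not in ("extract", "train", "evaluate", "predict"):
        raise ValueError(f"unknown mode {mode!r}")
    out_dir = Path(cfg.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, cfg.verbosity, logging.INFO))

    if mode in ("evaluate", "predict"):
        if model_path is None or not Path(model_path).exists():
            raise PipelineError(mode, model_path, FileNotFoundError(
                f"model checkpoint not found: {model_path}"))
        model = load_model(model_path)
    else:
        model = None

    names, labels, features = [], [], []
    paths = [Path(p) for p, _ in inputs]
    for path, label in inputs:
        path = Path(path)
        try:
            v = read_volume(path)
            feat = extract_features(v, cfg)
        except Exception as exc:  # annotate with the failing stage/input
            _write_manifest(out_dir, cfg, mode, paths, {}, partial=True)
            raise PipelineError("extract", path, exc) from exc
        names.append(path.name)
        labels.append(label)
        features.append(feat)

    artifacts: dict = {}
    df = _feature_frame(names, features,
                        labels if any(l is not None for l in labels) else None)
    features_path = out_dir / "features.csv"
    df.to_csv(features_path, index=False)
    artifacts["features"] = features_path
    result: dict = {"features": df, "artifacts": artifacts}

    if mode == "train":
        if any(l is None for l in labels):
            raise PipelineError("train", "labels", ValueError("every input needs a label"))
        spec = build_model(cfg.classifier)
        model = train(spec, list(zip(features, labels)), cfg.classifier)
        ckpt = out_dir / "model.npz"
        save_model(model, ckpt)
        artifacts["model"] = ckpt
        result["model"] = model
    elif mode == "evaluate":
        probs = predict_batch(model, features)
        predicted = [model.class_labels[i] for i in probs.argmax(axis=1)]
        report = compute_metrics(
            confusion_from_labels(labels, predicted, list(model.class_labels))
        )
        report_path = out_dir / "report.json"
        report_path.write_text(report.to_json())
        artifacts["report"] = report_path
        result["report"] = report
        result["predicted"] = predicted
    elif mode == "predict":
        probs = predict_batch(model, features)
        predicted = [model.class_labels[i] for i in probs.argmax(axis=1)]
        pred_path = out_dir / "predictions.json"
        pred_path.write_text(json.dumps(
            {n: {"label": str(p), "probabilities":
                 dict(zip(map(str, model.class_labels), map(float, row)))}
             for n, p, row in zip(names, predicted, probs)}, indent=2))
        artifacts["predictions"] = pred_path
        result["predicted"] = predicted

    _write_manifest(out_dir, cfg, mode, paths, artifacts)
    return result
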