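"""End-to-end orchestration: simulate/load -> enhance -> segment ->
features -> select -> train/predict -> evaluate.

A single master seed derives one sub-seed per stage (CRC32 of the stage
name mixed with the master), so the whole run is a pure function of the
inputs, the configuration and the master seed. Outputs land in a run
directory: the feature table, the selection report, the trained model,
the metrics report and a reproducibility record.
"""

from __future__ import annotations

import json
import platform
import warnings
import zlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .elm import ELMModel, TrainConfig, predict, train
from .enhancement import enhance_contrast
from .image_io import GrayImage, read_image
from .metrics import confusion, report
from .phantom import PhantomSpec, generate_dataset
from .segmentation import SegmentationConfig, extract_tumor_mask, segment
from .selection import select_features
from .texture import FeatureTable, FeatureVector, extract_features

__all__ = ["PipelineConfig", "run_pipeline", "validate_config", "derive_seed"]

STAGES = ("simulate", "enhance", "segment", "features", "select", "train", "evaluate")


def derive_seed(master: int, stage: str) -> int:
    """Deterministic per-stage sub-seed below 2**31."""
    return (int(master) * 1000003 + zlib.crc32(stage.encode())) % (2**31 - 1)


@dataclass
class SimulateConfig:
    n_per_class: int = 25
    size: tuple[int, int] = (128, 128)
    noise_model: str = "gaussian"
    noise_sigma: float = 0.02


@dataclass
class EnhanceConfig:
    enabled: bool = True
    rescale: bool = True
    sk_form: str = "third_moment"
    window: int | None = None


@dataclass
class FeatureConfig:
    W: int = 8
    ngtdm_window: int = 3
    tumor_rule: str = "brightest"


@dataclass
class SelectConfig:
    enabled: bool = True
    bins: int = 10
    threshold_mode: str = "max_prob"
    threshold_param: float = 0.5


@dataclass
class ElmConfig:
    # moderate hidden-layer size plus a small ridge: near-interpolating
    # H on small feature tables generalizes poorly
    H: int | None = 40
    activation: str = "sigmoid"
    ridge: float = 1e-3


@dataclass
class PipelineConfig:
    """Nested stage configuration with one master seed."""

    seed: int = 0
    train_frac: float = 0.8
    simulate: SimulateConfig = field(default_factory=SimulateConfig)
    enhance: EnhanceConfig = field(default_factory=EnhanceConfig)
    segmentation: SegmentationConfig = field(
        default_factory=lambda: SegmentationConfig(
            c=5, spatial_enabled=True, init="kmeans"
        )
    )
    features: FeatureConfig = field(default_factory=FeatureConfig)
    select: SelectConfig = field(default_factory=SelectConfig)
    elm: ElmConfig = field(default_factory=ElmConfig)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        kwargs: dict = {}
        nested = {
            "simulate": SimulateConfig,
            "enhance": EnhanceConfig,
            "segmentation": SegmentationConfig,
            "features": FeatureConfig,
            "select": SelectConfig,
            "elm": ElmConfig,
        }
        for key, val in raw.items():
            if key in nested:
                sub = nested[key](**val)
                if key == "simulate" and isinstance(sub.size, list):
                    sub.size = tuple(sub.size)
                kwargs[key] = sub
            elif key in ("seed", "train_frac"):
                kwargs[key] = val
            else:
                raise ValueError(f"unknown config section or key: {key!r}")
        return cls(**kwargs)

    @classmethod
    def from_toml(cls, path: str | Path) -> "PipelineConfig":
        import tomllib

        with open(path, "rb") as fh:
            return cls.from_dict(tomllib.load(fh))


def validate_config(source: str | Path | dict) -> list[str]:
    """Parse and check a config without executing anything.

    Returns a list of human-readable diagnostics; empty means valid.
    """
    diags: list[str] = []
    try:
        if isinstance(source, dict):
            cfg = PipelineConfig.from_dict(source)
        else:
            cfg = PipelineConfig.from_toml(source)
    except Exception as exc:  # parse/shape errors reported, not raised
        return [f"config error: {exc}"]
    if not (0 < cfg.train_frac < 1):
        diags.append("train_frac must lie in (0, 1)")
    if not cfg.segmentation.m > 1:
        diags.append("fuzzifier must exceed 1")
    if not (0 < cfg.segmentation.eps <= 1):
        diags.append("eps must lie in (0, 1]")
    try:
        cfg.segmentation.validate()
    except ValueError as exc:
        msg = str(exc)
        if "fuzzifier" not in msg and "eps" not in msg:
            diags.append(msg)
    if cfg.simulate.n_per_class < 1:
        diags.append("simulate.n_per_class must be >= 1")
    if cfg.simulate.noise_sigma < 0:
        diags.append("simulate.noise_sigma must be non-negative")
    if cfg.features.W < 2:
        diags.append("features.W must be >= 2")
    if cfg.select.bins < 2:
        diags.append("select.bins must be >= 2")
    if cfg.elm.ridge < 0:
        diags.append("elm.ridge must be non-negative")
    return diags


def _clean_roi(mask: np.ndarray) -> np.ndarray:
    """Morphological cleanup of a cluster mask into one coherent ROI.

    Binary opening removes isolated noise pixels, then the largest
    connected component is kept. A mask that vanishes entirely (no
    coherent bright region) comes back empty, which downstream feature
    extraction treats as "no tumor ROI" (whole-image features).
    """
    from scipy import ndimage as ndi

    opened = ndi.binary_opening(mask, structure=np.ones((3, 3), bool))
    if not opened.any():
        return opened
    comp, ncomp = ndi.label(opened)
    sizes = ndi.sum_labels(opened, comp, index=np.arange(1, ncomp + 1))
    return comp == (1 + int(np.argmax(sizes)))


def _sample_to_features(img: GrayImage, cfg: PipelineConfig, seg_seed: int):
    """Enhance, segment and featurize one image; returns (vector, mask)."""
    from dataclasses import replace

    if cfg.enhance.enabled:
        enhanced = enhance_contrast(
            img,
            rescale=cfg.enhance.rescale,
            window=cfg.enhance.window,
            sk_form=cfg.enhance.sk_form,
        ).as_gray()
        # re-normalize into [0, 1] for quantization downstream
        p = enhanced.pixels
        lo, hi = p.min(), p.max()
        work = GrayImage((p - lo) / (hi - lo) if hi > lo else np.zeros_like(p))
    else:
        work = img
    seg_cfg = replace(cfg.segmentation, seed=seg_seed)
    part, lmap = segment(work, seg_cfg)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # large-mask warning is expected for no-tumor
        mask = extract_tumor_mask(lmap, part, rule=cfg.features.tumor_rule)
    mask = _clean_roi(mask)
    vec = extract_features(
        work,
        mask,
        W=cfg.features.W,
        ngtdm_window=cfg.features.ngtdm_window,
    )
    return vec, mask


def build_feature_table(
    images: list[GrayImage], labels: list[str], cfg: PipelineConfig
) -> FeatureTable:
    seg_seed = derive_seed(cfg.seed, "segment")
    vectors: list[FeatureVector] = []
    for img in images:
        vec, _ = _sample_to_features(img, cfg, seg_seed)
        vectors.append(vec)
    return FeatureTable.from_vectors(vectors, labels)


def run_pipeline(
    cfg: PipelineConfig,
    out_dir: str | Path,
    images: list[GrayImage] | None = None,
    labels: list[str] | None = None,
    until: str = "evaluate",
) -> dict:
    """Execute the staged pipeline and write artifacts under ``out_dir``.

    Without explicit ``images``/``labels`` a phantom dataset is simulated
    from the config. ``until`` stops after the named stage. Returns a
    dict with the stage outputs produced (feature table, kept features,
    metrics report, ...).
    """
    if until not in STAGES:
        raise ValueError(f"unknown stage: {until!r}")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    result: dict = {}

    if images is None:
        sim_seed = derive_seed(cfg.seed, "simulate")
        base = PhantomSpec(
            size=cfg.simulate.size,
            noise_model=cfg.simulate.noise_model,
            noise_sigma=cfg.simulate.noise_sigma,
        )
        samples, manifest = generate_dataset(
            cfg.simulate.n_per_class, seed=sim_seed, base_spec=base
        )
        images = [s.image for s in samples]
        labels = [s.class_label for s in samples]
        manifest.to_csv(out / "manifest.csv", index=False)
        result["manifest"] = manifest
    if labels is None:
        raise ValueError("labels are required with explicit images")
    stage_idx = STAGES.index(until)
    if stage_idx < STAGES.index("features"):
        _write_repro(cfg, out)
        return result

    table = build_feature_table(images, labels, cfg)
    table.to_csv(out / "features.csv")
    result["features"] = table
    if stage_idx < STAGES.index("select"):
        _write_repro(cfg, out)
        return result

    from sklearn.model_selection import train_test_split

    split_seed = derive_seed(cfg.seed, "split")
    idx = np.arange(len(table.labels))
    train_idx, test_idx = train_test_split(
        idx,
        train_size=cfg.train_frac,
        random_state=split_seed,
        stratify=table.labels.values,
    )
    train_tab = FeatureTable(
        data=table.data.iloc[train_idx].reset_index(drop=True),
        labels=table.labels.iloc[train_idx].reset_index(drop=True),
    )

    if cfg.select.enabled:
        sel = select_features(
            train_tab,
            bins=cfg.select.bins,
            threshold_mode=cfg.select.threshold_mode,
            threshold_param=cfg.select.threshold_param,
        )
        kept = sel.kept_names
        (out / "selection.json").write_text(
            json.dumps(
                {
                    "kept": kept,
                    "threshold": sel.threshold,
                    "scores": [
                        {"name": s.name, "entropy": s.entropy, "score": s.score}
                        for s in sel.scores
                    ],
                },
                indent=2,
                sort_keys=True,
            )
        )
    else:
        kept = table.feature_names
    result["kept_features"] = kept
    if stage_idx < STAGES.index("train"):
        _write_repro(cfg, out)
        return result

    elm_seed = derive_seed(cfg.seed, "elm")
    X_train = train_tab.data[kept].to_numpy(float)
    y_train = train_tab.labels.to_numpy()
    # hidden nodes stay below the training sample count
    H_eff = min(cfg.elm.H, len(train_idx) - 1) if cfg.elm.H is not None else None
    model = train(
        X_train,
        y_train,
        TrainConfig(
            H=H_eff,
            activation=cfg.elm.activation,
            seed=elm_seed,
            ridge=cfg.elm.ridge,
        ),
    )
    model.to_json(out / "model.json")
    result["model"] = model
    if stage_idx < STAGES.index("evaluate"):
        _write_repro(cfg, out)
        return result

    X_test = table.data.iloc[test_idx][kept].to_numpy(float)
    y_test = table.labels.iloc[test_idx].to_numpy()
    y_pred = predict(model, X_test)
    cm = confusion(y_test, y_pred, classes=sorted(set(labels)))
    rep = report(cm)
    report_payload = {
        "metrics": rep.as_dict(),
        "confusion": cm.counts.tolist(),
        "classes": [str(c) for c in cm.classes],
        "n_train": int(len(train_idx)),
        "n_test": int(len(test_idx)),
        "kept_features": kept,
    }
    (out / "report.json").write_text(json.dumps(report_payload, indent=2, sort_keys=True))
    result["report"] = report_payload
    result["confusion"] = cm
    result["class_report"] = rep
    _write_repro(cfg, out)
    return result


def _write_repro(cfg: PipelineConfig, out: Path) -> None:
    record = {
        "config": asdict(cfg),
        "derived_seeds": {s: derive_seed(cfg.seed, s) for s in (*STAGES, "split")},
        "package_version": __version__,
        "python": platform.python_version(),
        "numpy": np.__version__,
        "pandas": pd.__version__,
    }
    (out / "repro.json").write_text(json.dumps(record, indent=2, sort_keys=True, default=str))
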