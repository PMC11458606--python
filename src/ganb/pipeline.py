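"""End-to-end orchestration: phantoms -> Fourier preprocessing ->
adversarial training -> discriminator features -> naive-Bayes risk
classification -> evaluation.

The configuration is a validated, schema-checked tree (unknown keys are
rejected) that mirrors the per-stage module parameters.  Every random
draw goes through one seeded generator per stage, with stage seeds derived
deterministically from the global seed, so a run is reproducible
byte-for-byte (timings aside).

Also provides :func:`threshold_segment`, a deliberately simple
intensity-based lumen segmenter (hierarchical Otsu + largest bright
connected component) used to exercise the overlap metrics end to end.
"""

from __future__ import annotations

import hashlib
import json
import time
import warnings
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Optional

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, model_validator
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label

from . import fourier, metrics, naive_bayes, phantom
from .features import FeatureTable, augment_with_synthetic, extract_features
from .gan import TrainConfig, train_gan
from .phantom import MASK_LABELS, PhantomSpec

__all__ = [
    "PipelineConfig",
    "RunReport",
    "load_config",
    "validate_config",
    "run_pipeline",
    "threshold_segment",
    "stage_seed",
]


class _Block(BaseModel):
    model_config = ConfigDict(extra="forbid")


class PhantomBlock(_Block):
    n: int = 200
    image_size: int = 32
    class_mix: float = 0.5
    noise_sd: float = 0.02
    vessel_radius: float = 12.0


class PreprocBlock(_Block):
    kind: Literal["low", "high", "band", "allpass"] = "band"
    d1: float = 2.0
    d2: Optional[float] = None  # None -> image_size / 4
    gaussian_rolloff: bool = False


class GanBlock(_Block):
    epochs: int = 150
    batch_size: int = 32
    learning_rate: float = 0.002
    optimizer: Literal["sgd", "adam"] = "adam"
    latent_dim: int = 32
    gen_hidden: int = 128
    gen_channels: int = 16
    disc_channels: int = 8
    disc_hidden: int = 64


class FeatureBlock(_Block):
    layer_index: int = -2  # penultimate discriminator block
    augment: bool = False
    n_per_class: int = 50


class NbBlock(_Block):
    family: Literal["gaussian", "multinomial"] = "gaussian"
    alpha: float = 1.0
    smoothing_mode: Literal["standard", "unnormalized"] = "standard"
    n_bins: int = 8


class PipelineConfig(_Block):
    phantom: PhantomBlock = PhantomBlock()
    preproc: PreprocBlock = PreprocBlock()
    gan: GanBlock = GanBlock()
    feature: FeatureBlock = FeatureBlock()
    nb: NbBlock = NbBlock()
    seed: int = 0
    split: float = 0.7
    out_dir: Optional[str] = None

    @model_validator(mode="after")
    def _check(self):
        if not 0.0 < self.split < 1.0:
            raise ValueError("split must be in (0, 1)")
        return self

    def config_hash(self) -> str:
        payload = json.dumps(self.model_dump(), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def validate_config(raw: dict | None) -> PipelineConfig:
    """Schema-validate a raw mapping; unknown keys are rejected by name."""
    return PipelineConfig.model_validate(raw or {})


def load_config(path: str | Path) -> PipelineConfig:
    """Load a YAML or JSON config file; an empty file yields full defaults."""
    text = Path(path).read_text()
    raw = yaml.safe_load(text) if text.strip() else {}
    return validate_config(raw)


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed derived from the global seed by name hash."""
    return (global_seed * 1_000_003 + zlib.crc32(stage.encode())) % (2**31)


@dataclass
class RunReport:
    config_hash: str
    n_train: int
    n_test: int
    classification: dict
    segmentation: dict
    risk_table: pd.DataFrame
    timings: dict = field(default_factory=dict)
    manifest: dict = field(default_factory=dict)


def threshold_segment(image: np.ndarray) -> np.ndarray:
    """Lumen mask by hierarchical Otsu thresholding.

    A first Otsu cut separates the vessel from the background; a second cut
    within the foreground isolates the brightest (contrast-filled) tissue.
    The largest bright connected component is returned as a {0, 1} mask.
    Blank images yield an empty mask with a warning.  The mask is invariant
    under positive linear rescaling of the intensities (Otsu property).
    """
    img = np.asarray(image, dtype=float)
    if img.max() == img.min():
        warnings.warn("blank image: returning an empty mask")
        return np.zeros(img.shape, dtype=np.int64)
    fg = img > threshold_otsu(img)
    vals = img[fg]
    bright = img > (threshold_otsu(vals) if np.unique(vals).size > 1 else img.min())
    comps = cc_label(bright)
    if comps.max() == 0:
        warnings.warn("no bright component found: returning an empty mask")
        return np.zeros(img.shape, dtype=np.int64)
    sizes = np.bincount(comps.ravel())[1:]
    largest = 1 + int(np.argmax(sizes))
    return (comps == largest).astype(np.int64)


def _stratified_split(labels: list[str], split: float, rng: np.random.Generator):
    train_idx, test_idx = [], []
    labels = np.asarray(labels)
    for cls in np.unique(labels):
        idx = np.flatnonzero(labels == cls)
        rng.shuffle(idx)
        k = int(round(split * idx.size))
        train_idx.extend(idx[:k])
        test_idx.extend(idx[k:])
    return np.sort(train_idx), np.sort(test_idx)


def run_pipeline(config: PipelineConfig) -> RunReport:
    """Execute the full chain and evaluate on the held-out split."""
    timings: dict[str, float] = {}
    t0 = time.perf_counter()

    # --- cohort ----------------------------------------------------------
    pb = config.phantom
    base = PhantomSpec(image_size=pb.image_size, noise_sd=pb.noise_sd,
                       vessel_radius=pb.vessel_radius)
    cohort = phantom.generate_cohort(pb.n, pb.class_mix, base_spec=base,
                                     seed=stage_seed(config.seed, "phantom"))
    labels = [s.label for s in cohort]
    timings["phantom"] = time.perf_counter() - t0

    # --- preprocessing ---------------------------------------------------
    t = time.perf_counter()
    pp = config.preproc
    processed = np.stack([
        fourier.preprocess_image(s.image, kind=pp.kind, d1=pp.d1, d2=pp.d2,
                                 gaussian_rolloff=pp.gaussian_rolloff) / 255.0
        for s in cohort
    ])
    timings["preproc"] = time.perf_counter() - t

    # --- split -----------------------------------------------------------
    split_rng = np.random.default_rng(stage_seed(config.seed, "split"))
    train_idx, test_idx = _stratified_split(labels, config.split, split_rng)
    x_train, x_test = processed[train_idx], processed[test_idx]
    y_train = [labels[i] for i in train_idx]
    y_test = [labels[i] for i in test_idx]

    # --- adversarial training --------------------------------------------
    t = time.perf_counter()
    gb = config.gan
    tc = TrainConfig(learning_rate=gb.learning_rate, batch_size=gb.batch_size,
                     epochs=gb.epochs, seed=stage_seed(config.seed, "gan"),
                     optimizer=gb.optimizer, latent_dim=gb.latent_dim,
                     image_size=pb.image_size, gen_hidden=gb.gen_hidden,
                     gen_channels=gb.gen_channels, disc_channels=gb.disc_channels,
                     disc_hidden=gb.disc_hidden)
    G, D, history = train_gan(x_train, tc)
    class_gans = {}
    if config.feature.augment:
        for cls in sorted(set(y_train)):
            sub = x_train[np.asarray(y_train) == cls]
            tc_cls = TrainConfig(**{**tc.__dict__,
                                    "seed": stage_seed(config.seed, f"gan-{cls}")})
            g_cls, _, _ = train_gan(sub, tc_cls)
            class_gans[cls] = g_cls
    timings["gan"] = time.perf_counter() - t

    # --- features --------------------------------------------------------
    t = time.perf_counter()
    li = config.feature.layer_index
    train_tab = extract_features(D, x_train, layer_index=li, labels=y_train)
    test_tab = extract_features(D, x_test, layer_index=li, labels=y_test)
    if config.feature.augment and config.feature.n_per_class > 0:
        synth = augment_with_synthetic(class_gans, D, config.feature.n_per_class,
                                       layer_index=li,
                                       seed=stage_seed(config.seed, "augment"))
        train_tab = train_tab.concat(synth)
    timings["features"] = time.perf_counter() - t

    # --- naive Bayes -----------------------------------------------------
    t = time.perf_counter()
    nb_cfg = config.nb
    Xtr, Xte = train_tab.matrix, test_tab.matrix
    bin_edges = None
    if nb_cfg.family == "multinomial":
        Xtr, bin_edges = naive_bayes.discretize(Xtr, n_bins=nb_cfg.n_bins)
        Xte = naive_bayes.apply_bins(Xte, bin_edges)
    model = naive_bayes.fit(Xtr, train_tab.labels, family=nb_cfg.family,
                            alpha=nb_cfg.alpha, smoothing_mode=nb_cfg.smoothing_mode)
    model.bin_edges = bin_edges
    pred = naive_bayes.classify(model, Xte)
    post = naive_bayes.predict_posterior(model, Xte)
    scores = naive_bayes.risk_score(model, Xte)
    timings["nb"] = time.perf_counter() - t

    # --- evaluation ------------------------------------------------------
    t = time.perf_counter()
    counts = metrics.confusion_from_labels(pred, y_test, positive="high")
    _, auc = metrics.roc_auc(post[:, model.classes.index("high")], y_test)
    classification = {
        "accuracy": metrics.accuracy(counts),
        "recall": metrics.recall(counts),
        "precision": metrics.precision(counts),
        "auc": auc,
        "confusion": counts.__dict__,
    }
    # exercise the overlap metrics with the baseline lumen segmenter
    seg_rows = {}
    for j, i_test in enumerate(test_idx[: min(20, len(test_idx))]):
        smp = cohort[i_test]
        pred_mask = threshold_segment(smp.image)
        truth = (smp.masks == MASK_LABELS["lumen"]).astype(np.int64)
        seg_rows[f"case_{j}"] = {
            "dsc": metrics.dice(pred_mask, truth),
            "iou": metrics.iou(pred_mask, truth),
        }
    segmentation = {"per_case": seg_rows,
                    "aggregate": metrics.aggregate_metrics(seg_rows)}
    risk_table = pd.DataFrame({
        "true_label": y_test,
        "predicted": pred,
        "p_high": post[:, model.classes.index("high")],
        "risk_score": scores,
    })
    timings["eval"] = time.perf_counter() - t

    report = RunReport(
        config_hash=config.config_hash(),
        n_train=len(train_idx), n_test=len(test_idx),
        classification=classification, segmentation=segmentation,
        risk_table=risk_table, timings=timings,
    )
    if config.out_dir:
        report.manifest = _write_artifacts(config, report, cohort, model, history, (G, D, tc))
    return report


def _write_artifacts(config, report, cohort, model, history, gan_triplet):
    from .gan import save_gan

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    phantom.export_cohort(cohort, out / "cohort")
    G, D, tc = gan_triplet
    save_gan(G, D, tc, out / "gan")
    md, mg = history.epoch_means()
    pd.DataFrame({"epoch": range(1, len(md) + 1), "loss_d": md, "loss_g": mg}).to_csv(
        out / "training_history.csv", index=False)
    naive_bayes.save_model(model, out / "nb_model.json")
    report.risk_table.to_csv(out / "predictions.csv", index=False)
    summary = {
        "config_hash": report.config_hash,
        "n_train": report.n_train,
        "n_test": report.n_test,
        "classification": report.classification,
        "segmentation_aggregate": report.segmentation["aggregate"],
    }
    (out / "report.json").write_text(json.dumps(summary, indent=2))
    return {"out_dir": str(out), "files": sorted(p.name for p in out.iterdir())}
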