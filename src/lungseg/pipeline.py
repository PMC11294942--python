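"""End-to-end flows: preprocess -> segment (EM or network) -> evaluate -> report.

``run_em_pipeline`` runs the intensity-mixture segmenter per image (estimating
the segment count from the histogram unless K is fixed) and scores the
maximum-posterior labeling against the ground-truth masks when provided.
``run_train``/``run_eval`` split the dataset 70/15/15, train the network on
the training fold with validation monitoring, and evaluate the best
checkpoint on the held-out test fold.

Mixture component labels are arbitrary, so binary overlap metrics are
computed after choosing the foreground/background assignment that maximizes
Dice (partition metrics PRI/VOI/GCE are label-permutation invariant anyway).
"""

from __future__ import annotations

import hashlib
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import metrics as M
from .config import RunConfig
from .image import RasterImage, load_image, load_mask
from .mixture import EMConfig, KEstimateConfig, classify_pixels, estimate_K, fit_em
from .nn import NetworkSpec, TrainConfig, UNet, load_checkpoint, predict_mask
from .nn import save_checkpoint as _save_ckpt
from .nn import split_dataset, train
from .preprocess import (ClaheConfig, WienerConfig, WindowSpec,
                         preprocess_pipeline)
from .synthetic import PhantomSpec, make_dataset

__all__ = ["RunReport", "PipelineError", "run_em_pipeline", "run_train",
           "run_eval", "write_metrics_csv"]

log = logging.getLogger("lungseg")


class PipelineError(RuntimeError):
    pass


@dataclass
class RunReport:
    """Per-sample metric rows, aggregate, and provenance."""

    report: M.MetricsReport
    segmentations: list[np.ndarray] = field(default_factory=list)
    failures: list[tuple[str, str]] = field(default_factory=list)
    provenance: dict = field(default_factory=dict)

    def aggregate(self):
        return self.report.aggregate() if self.report.samples else {}


def _config_hash(cfg: RunConfig) -> str:
    blob = yaml.safe_dump(cfg.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _provenance(cfg: RunConfig, extra: dict | None = None) -> dict:
    prov = {"config_hash": _config_hash(cfg), "seed": cfg.seed,
            "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
            "segmenter": cfg.segmenter_name}
    if extra:
        prov.update(extra)
    return prov


def _load_inputs(cfg: RunConfig):
    """Resolve the configured input into (images, masks or None, ids)."""
    if cfg.images:
        images = [load_image(p) for p in cfg.images]
        masks = [load_mask(p) for p in cfg.masks] if cfg.masks else None
        ids = [Path(p).stem for p in cfg.images]
    else:
        s = cfg.synthetic
        spec = PhantomSpec(size=tuple(s.size), n_nodules=tuple(s.n_nodules),
                           nodule_radius=tuple(s.nodule_radius),
                           noise_sd=s.noise_sd, seed=cfg.seed)
        samples = make_dataset(spec, s.n, seed=cfg.seed)
        images = [smp.image for smp in samples]
        masks = [smp.nodule_mask.astype(np.int64) for smp in samples]
        ids = [f"phantom_{i:04d}" for i in range(len(samples))]
    return images, masks, ids


def _preprocess(cfg: RunConfig, image: RasterImage) -> RasterImage:
    p = cfg.preprocess
    return preprocess_pipeline(
        image, p.stages,
        window=WindowSpec(**p.window),
        clahe_cfg=ClaheConfig(**{**p.clahe, "tile_grid": tuple(p.clahe["tile_grid"])}),
        wiener_cfg=WienerConfig(**p.wiener),
        resize_to=tuple(p.resize_to),
    )


def _binary_align(pred_labels: np.ndarray, truth: np.ndarray) -> np.ndarray:
    """Pick the label subset whose indicator best matches the binary truth."""
    truth = truth.astype(bool)
    best_mask = np.zeros_like(truth)
    best_dice = 0.0
    remaining = list(np.unique(pred_labels))
    # greedy union: each pass adds the single label with the largest Dice gain
    while remaining:
        gains = [(M.dice(best_mask | (pred_labels == lab), truth), lab)
                 for lab in remaining]
        d, lab = max(gains)
        if d <= best_dice:
            break
        best_dice = d
        best_mask = best_mask | (pred_labels == lab)
        remaining.remove(lab)
    return best_mask


def _score(cfg: RunConfig, pred_labels, truth, prob=None, roi=None) -> dict[str, float]:
    row: dict[str, float] = {}
    binary = _binary_align(pred_labels, truth) if prob is None else np.asarray(pred_labels, bool)
    c = M.confusion(binary, truth, roi)
    stats = M.basic_stats(c)
    for name in cfg.evaluation.metrics:
        if name == "dice":
            row[name] = M.dice(binary, truth, roi)
        elif name == "iou":
            row[name] = M.iou(binary, truth, roi)
        elif name == "pri":
            row[name] = M.pri(pred_labels, truth, roi)
        elif name == "voi":
            row[name] = M.voi(pred_labels, truth, roi)
        elif name == "gce":
            row[name] = M.gce(pred_labels, truth, roi)
        elif name == "auc" and prob is not None:
            row[name] = M.roc_auc(prob, truth, roi)[0]
        elif name in stats:
            row[name] = stats[name]
    return row


def run_em_pipeline(cfg: RunConfig) -> RunReport:
    """Per image: preprocess -> (estimate K) -> fit EM -> classify -> score."""
    if cfg.em is None:
        raise PipelineError("EM segmenter not configured")
    images, masks, ids = _load_inputs(cfg)
    roi = load_mask(cfg.evaluation.roi) if cfg.evaluation.roi else None
    report = RunReport(M.MetricsReport(), provenance=_provenance(cfg))
    for idx, (img, sid) in enumerate(zip(images, ids)):
        try:
            pre = _preprocess(cfg, img)
            pixels = pre.pixels.ravel()
            K = cfg.em.K if cfg.em.K is not None else estimate_K(pixels, KEstimateConfig())
            em_cfg = EMConfig(tol=cfg.em.tol, max_iter=cfg.em.max_iter,
                              init_strategy=cfg.em.init, seed=cfg.seed,
                              shape=cfg.em.shape)
            trace = fit_em(pixels, K, em_cfg)
            log.debug("sample %s: K=%d, %d EM iterations, loglik %.2f",
                      sid, K, trace.iterations, trace.loglik_per_iter[-1])
            labels = classify_pixels(pre, trace.final)
            report.segmentations.append(labels)
            if masks is not None:
                truth = masks[idx]
                if truth.shape != labels.shape:
                    raise PipelineError(
                        f"mask shape {truth.shape} != image shape {labels.shape}")
                report.report.add(_score(cfg, labels, truth, roi=roi), sid)
        except Exception as exc:  # per-sample failures are logged and skipped
            log.warning("sample %s failed: %s", sid, exc)
            report.failures.append((sid, str(exc)))
    if len(report.failures) == len(images):
        raise PipelineError("all samples failed in the EM pipeline")
    return report


def _network_dataset(cfg: RunConfig):
    images, masks, ids = _load_inputs(cfg)
    if masks is None:
        raise PipelineError("network training requires ground-truth masks")
    data = [(

        _preprocess(cfg, img).pixels, np.asarray(msk, dtype=float))
        for img, msk in zip(images, masks)]
    return data, ids


def run_train(cfg: RunConfig):
    """Split per the configured fractions, train, keep the best checkpoint."""
    if cfg.network is None:
        raise PipelineError("network segmenter not configured")
    ncfg = cfg.network
    data, ids = _network_dataset(cfg)
    tcfg = TrainConfig(learning_rate=ncfg.learning_rate, batch_size=ncfg.batch_size,
                       epochs=ncfg.epochs, split_fractions=tuple(ncfg.split_fractions),
                       seed=cfg.seed, threshold=ncfg.threshold)
    tr_idx, va_idx, te_idx = split_dataset(data, tcfg)
    spec = NetworkSpec(input_size=data[0][0].shape, depth=ncfg.depth,
                       base_filters=ncfg.base_filters, dropout_rate=ncfg.dropout_rate,
                       l2_lambda=ncfg.l2_lambda, skip_mode=ncfg.skip_mode)
    model = UNet(spec, seed=cfg.seed)
    report = train(model, [data[i] for i in tr_idx], tcfg,
                   val_dataset=[data[i] for i in va_idx])
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    if report.best_state is not None:
        model.load_state_dict(report.best_state)
    ckpt = out / "checkpoint.npz"
    _save_ckpt(model, ckpt)
    report.to_csv(out / "training_curves.csv")
    prov = _provenance(cfg, {"checkpoint": str(ckpt),
                             "train_idx": tr_idx, "val_idx": va_idx,
                             "test_idx": te_idx, "best_epoch": report.best_epoch})
    return model, report, prov


def run_eval(cfg: RunConfig, model: UNet | None = None,
             provenance: dict | None = None) -> RunReport:
    """Evaluate a trained checkpoint on the held-out test fold."""
    if cfg.network is None:
        raise PipelineError("network segmenter not configured")
    if model is None:
        if not cfg.network.checkpoint:
            raise PipelineError("no checkpoint configured for evaluation")
        model = load_checkpoint(cfg.network.checkpoint)
    data, ids = _network_dataset(cfg)
    tcfg = TrainConfig(split_fractions=tuple(cfg.network.split_fractions), seed=cfg.seed)
    _, _, te_idx = split_dataset(data, tcfg)
    roi = load_mask(cfg.evaluation.roi) if cfg.evaluation.roi else None
    report = RunReport(M.MetricsReport(),
                       provenance=provenance or _provenance(cfg, {"test_idx": te_idx}))
    for i in te_idx:
        img, truth = data[i]
        mask, prob = predict_mask(model, img, cfg.network.threshold)
        report.segmentations.append(mask.astype(np.int64))
        report.report.add(_score(cfg, mask, truth.astype(bool), prob=prob, roi=roi),
                          ids[i])
    return report


def write_metrics_csv(report: RunReport, path) -> None:
    """Tidy (sample_id, metric, value) rows plus mean/std aggregate rows."""
    import csv

    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["sample_id", "metric", "value"])
        rep = report.report
        for sid, row in zip(rep.sample_ids, rep.samples):
            for name in rep.metric_names:
                if name in row:
                    writer.writerow([sid, name, repr(row[name])])
        if rep.samples:
            for name, (mean, std) in rep.aggregate().items():
                writer.writerow(["aggregate_mean", name, repr(mean)])
                writer.writerow(["aggregate_std", name, repr(std)])
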