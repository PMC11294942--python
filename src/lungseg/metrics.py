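"""Segmentation evaluation: overlap, confusion-matrix, partition-comparison
and ROC metrics, with mean +/- std aggregation across samples.

Partition metrics follow their canonical literature definitions: the
probabilistic Rand index reduces to the plain Rand index for a single ground
truth (fraction of pixel pairs whose co-membership relation agrees), variation
of information is Meila's H(S)+H(T)-2I(S;T) in bits, and the global
consistency error is Martin's refinement-tolerant error (the directional
minimum of the mean local refinement error).

Ratios with zero denominators are reported as ``nan`` (an "undefined" marker),
never raised.  All metrics accept an optional ``roi`` mask restricting the
evaluation to a region of interest (e.g. the lung fields).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ConfusionCounts",
    "MetricsReport",
    "confusion",
    "basic_stats",
    "dice",
    "iou",
    "pri",
    "voi",
    "gce",
    "roc_auc",
    "aggregate_report",
]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


def _as_flat(pred, truth, roi=None):
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {truth.shape}")
    pred, truth = pred.ravel(), truth.ravel()
    if roi is not None:
        roi = np.asarray(roi).ravel().astype(bool)
        if roi.size != pred.size:
            raise ValueError("roi shape mismatch")
        pred, truth = pred[roi], truth[roi]
    return pred, truth


def confusion(pred, truth, roi=None) -> ConfusionCounts:
    """Pixel-wise confusion counts; foreground (nonzero) is positive."""
    p, t = _as_flat(pred, truth, roi)
    p, t = p.astype(bool), t.astype(bool)
    return ConfusionCounts(
        tp=int(np.sum(p & t)),
        fp=int(np.sum(p & ~t)),
        fn=int(np.sum(~p & t)),
        tn=int(np.sum(~p & ~t)),
    )


def _ratio(num, den) -> float:
    return float(num) / float(den) if den > 0 else float("nan")


def basic_stats(c: ConfusionCounts) -> dict[str, float]:
    """Accuracy, sensitivity (recall), specificity, precision and F1."""
    sens = _ratio(c.tp, c.tp + c.fn)
    prec = _ratio(c.tp, c.tp + c.fp)
    return {
        "accuracy": _ratio(c.tp + c.tn, c.total),
        "sensitivity": sens,
        "specificity": _ratio(c.tn, c.tn + c.fp),
        "precision": prec,
        "f1": _ratio(2 * c.tp, 2 * c.tp + c.fp + c.fn),
    }


def dice(pred, truth, roi=None) -> float:
    """Dice coefficient 2|A^B|/(|A|+|B|); both-empty pairs score 1."""
    p, t = _as_flat(pred, truth, roi)
    p, t = p.astype(bool), t.astype(bool)
    denom = p.sum() + t.sum()
    if denom == 0:
        return 1.0
    return float(2 * np.sum(p & t) / denom)


def iou(pred, truth, roi=None) -> float:
    """Intersection over union; both-empty pairs score 1."""
    p, t = _as_flat(pred, truth, roi)
    p, t = p.astype(bool), t.astype(bool)
    union = np.sum(p | t)
    if union == 0:
        return 1.0
    return float(np.sum(p & t) / union)


def _contingency(seg, truth, roi=None) -> np.ndarray:
    s, t = _as_flat(seg, truth, roi)
    _, si = np.unique(s, return_inverse=True)
    _, ti = np.unique(t, return_inverse=True)
    table = np.zeros((si.max() + 1, ti.max() + 1), dtype=np.int64)
    np.add.at(table, (si, ti), 1)
    return table


def pri(seg, truth, roi=None) -> float:
    """Rand index: fraction of pixel pairs with agreeing co-membership."""
    table = _contingency(seg, truth, roi)
    n = table.sum()
    if n < 2:
        return 1.0
    pairs = n * (n - 1) / 2.0
    sum_nij = (table * (table - 1) / 2.0).sum()
    sum_a = (table.sum(axis=1) * (table.sum(axis=1) - 1) / 2.0).sum()
    sum_b = (table.sum(axis=0) * (table.sum(axis=0) - 1) / 2.0).sum()
    disagreements = sum_a + sum_b - 2.0 * sum_nij
    return float((pairs - disagreements) / pairs)


def voi(seg, truth, roi=None) -> float:
    """Variation of information H(S)+H(T)-2I(S;T), base-2 logs (bits)."""
    table = _contingency(seg, truth, roi).astype(float)
    n = table.sum()
    pij = table / n
    pa = pij.sum(axis=1)
    pb = pij.sum(axis=0)
    nz = pij > 0
    h_a = -np.sum(pa[pa > 0] * np.log2(pa[pa > 0]))
    h_b = -np.sum(pb[pb > 0] * np.log2(pb[pb > 0]))
    mi = np.sum(pij[nz] * np.log2(pij[nz] / (pa[:, None] * pb[None, :])[nz]))
    return float(max(h_a + h_b - 2.0 * mi, 0.0))


def gce(seg, truth, roi=None) -> float:
    """Martin's global consistency error.

    For pixel x, the local refinement error of S against T is
    |R(S,x)\\R(T,x)| / |R(S,x)|; GCE takes the mean over pixels in the less
    erroneous direction, so it is zero whenever one partition refines the
    other.
    """
    table = _contingency(seg, truth, roi).astype(float)
    n = table.sum()
    a = table.sum(axis=1)  # |R(S, x)| per S-class
    b = table.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        e_st = np.nansum(table * (a[:, None] - table) / a[:, None]) / n
        e_ts = np.nansum(table * (b[None, :] - table) / b[None, :]) / n
    return float(min(e_st, e_ts))


def roc_auc(scores, truth, roi=None):
    """ROC curve and area by threshold sweep over the unique scores.

    Ties move together (one threshold per unique score); the area uses
    trapezoidal integration.  A single-class truth yields ``nan`` and an
    empty curve.
    """
    s, t = _as_flat(scores, truth, roi)
    t = t.astype(bool)
    if t.all() or not t.any():
        return float("nan"), (np.array([]), np.array([]))
    from sklearn.metrics import roc_curve

    fpr, tpr, _ = roc_curve(t.astype(int), s.astype(float))
    return float(np.trapezoid(tpr, fpr)), (fpr, tpr)


@dataclass
class MetricsReport:
    """Named per-sample metric rows plus mean +/- std aggregation."""

    samples: list[dict[str, float]] = field(default_factory=list)
    sample_ids: list[str] = field(default_factory=list)

    def add(self, row: dict[str, float], sample_id: str | None = None) -> None:
        self.samples.append(dict(row))
        self.sample_ids.append(sample_id if sample_id is not None else str(len(self.samples) - 1))

    @property
    def metric_names(self) -> list[str]:
        names: list[str] = []
        for row in self.samples:
            for k in row:
                if k not in names:
                    names.append(k)
        return names

    def aggregate(self) -> dict[str, tuple[float, float]]:
        """Per-metric mean and population standard deviation over samples."""
        if not self.samples:
            raise ValueError("no samples to aggregate")
        out = {}
        for name in self.metric_names:
            vals = np.array([row[name] for row in self.samples if name in row], dtype=float)
            vals = vals[np.isfinite(vals)]
            if vals.size == 0:
                out[name] = (float("nan"), float("nan"))
            else:
                out[name] = (float(vals.mean()), float(vals.std()) if vals.size > 1 else 0.0)
        return out

    def format_table(self, percent: bool = True) -> str:
        """Render aggregates as 'metric  mean +/- std' lines."""
        scale = 100.0 if percent else 1.0
        unit = " (%)" if percent else ""
        lines = [f"{'Metric':<16}Mean ± Std{unit}"]
        for name, (m, s) in self.aggregate().items():
            lines.append(f"{name:<16}{m * scale:.2f} ± {s * scale:.2f}")
        return "\n".join(lines)


def aggregate_report(per_sample) -> MetricsReport:
    """Build a report from an iterable of per-sample metric dicts."""
    report = MetricsReport()
    for row in per_sample:
        report.add(row)
    if not report.samples:
        raise ValueError("need at least one sample row")
    return report
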