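"""Synthetic CT-like phantoms with paired ground truth.

Two generators:

* :func:`generate_mixture_image` draws each pixel's intensity from the
  logistic-type mixture component assigned to its region, exactly matching
  the distributional assumption of the EM segmenter — each of the K sectors
  of the image follows a logistic-type law with its own parameters.
* :func:`generate_lung_phantom` builds a stylized axial chest slice: two
  elliptical "lung fields" on a brighter body background, with bright
  nodule discs inside the lungs and additive Gaussian noise.  It is a
  statistical stand-in for annotated CT slices, not an anatomical simulator.

Default tissue intensities follow the fitted two-component pixel-intensity
model of real lung CT (lung interior ~60.5, surrounding tissue ~122 on an
8-bit scale) plus a brighter nodule class.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .distributions import LogisticTypeDist
from .image import RasterImage
from .mixture import MixtureParams

__all__ = ["PhantomSpec", "LabeledSample", "generate_mixture_image",
           "generate_lung_phantom", "make_dataset", "save_dataset",
           "DEFAULT_TISSUE_CLASSES"]

#: (label name, distribution) per tissue class; order fixes mask labels 0/1/2.
DEFAULT_TISSUE_CLASSES: tuple[tuple[str, LogisticTypeDist], ...] = (
    ("background", LogisticTypeDist(121.98, 11.348, 4.0)),
    ("lung", LogisticTypeDist(60.54, 9.709, 4.0)),
    ("nodule", LogisticTypeDist(200.0, 6.0, 4.0)),
)


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry and intensity model of a lung phantom."""

    size: tuple[int, int] = (128, 128)
    n_nodules: tuple[int, int] = (1, 3)
    nodule_radius: tuple[float, float] = (3.0, 8.0)
    tissue_classes: tuple[tuple[str, LogisticTypeDist], ...] = DEFAULT_TISSUE_CLASSES
    noise_sd: float = 2.0
    value_range: tuple[float, float] = (0.0, 255.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.size[0] < 8 or self.size[1] < 8:
            raise ValueError("phantom must be at least 8x8")
        if self.n_nodules[0] > self.n_nodules[1] or self.n_nodules[0] < 0:
            raise ValueError("n_nodules range must be non-degenerate")
        if self.nodule_radius[0] > self.nodule_radius[1] or self.nodule_radius[0] <= 0:
            raise ValueError("nodule_radius range must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass(frozen=True)
class LabeledSample:
    """A phantom image with its label mask and generating parameters."""

    image: RasterImage
    mask: np.ndarray
    truth_params: MixtureParams
    seed: int

    def __post_init__(self) -> None:
        if self.image.shape != self.mask.shape:
            raise ValueError("image and mask shapes differ")

    @property
    def nodule_mask(self) -> np.ndarray:
        """Binary mask of the nodule class (label 2)."""
        return self.mask == 2


def _truth_params(dists, areas) -> MixtureParams:
    areas = np.asarray(areas, dtype=float)
    w = areas / areas.sum()
    keep = w > 0
    return MixtureParams(tuple(d for d, k in zip(dists, keep) if k),
                         tuple(w[keep].tolist()))


def generate_mixture_image(params: MixtureParams, region_geometry,
                           seed: int = 0,
                           value_range=(0.0, 255.0)) -> LabeledSample:
    """Draw each pixel from the mixture component of its region label.

    ``region_geometry`` is an integer label layout whose values index
    ``params.components``.  Intensities are clamped to ``value_range``.
    """
    layout = np.asarray(region_geometry)
    labels = np.unique(layout)
    if labels.min() < 0 or labels.max() >= params.K:
        raise ValueError(
            f"layout labels {labels.tolist()} not within the {params.K} components")
    rng = np.random.default_rng(seed)
    img = np.empty(layout.shape, dtype=float)
    for lab in labels:
        sel = layout == lab
        img[sel] = params.components[int(lab)].rvs(int(sel.sum()), rng)
    img = np.clip(img, *value_range)
    return LabeledSample(RasterImage(img, value_range), layout.astype(np.int64),
                         params, seed)


def _ellipse_mask(h, w, cy, cx, ry, rx) -> np.ndarray:
    yy, xx = np.mgrid[0:h, 0:w]
    return ((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2 <= 1.0


def generate_lung_phantom(spec: PhantomSpec | None = None) -> LabeledSample:
    """Stylized chest slice: two elliptical lungs, nodules, noise.

    Mask labels: 0 background, 1 lung field, 2 nodule; every nodule disc lies
    entirely inside a lung field.  Fully seeded and reproducible.
    """
    spec = spec or PhantomSpec()
    rng = np.random.default_rng(spec.seed)
    h, w = spec.size
    mask = np.zeros((h, w), dtype=np.int64)

    # two lung ellipses with mild seeded jitter
    for cx_frac in (0.30, 0.70):
        cy = h * (0.50 + rng.uniform(-0.03, 0.03))
        cx = w * (cx_frac + rng.uniform(-0.02, 0.02))
        ry = h * rng.uniform(0.28, 0.34)
        rx = w * rng.uniform(0.13, 0.17)
        mask[_ellipse_mask(h, w, cy, cx, ry, rx)] = 1

    n_nod = int(rng.integers(spec.n_nodules[0], spec.n_nodules[1] + 1))
    lung = mask == 1
    yy, xx = np.mgrid[0:h, 0:w]
    for _ in range(n_nod):
        placed = False
        for _attempt in range(100):
            r = rng.uniform(*spec.nodule_radius)
            ys, xs = np.nonzero(lung)
            i = rng.integers(len(ys))
            cy, cx = ys[i], xs[i]
            disc = (yy - cy) ** 2 + (xx - cx) ** 2 <= r**2
            if np.all(mask[disc] >= 1):  # disc fully inside a lung field
                mask[disc] = 2
                placed = True
                break
        if not placed:
            raise RuntimeError(
                "could not place a nodule inside the lung fields after 100 attempts")

    dists = [d for _, d in spec.tissue_classes]
    img = np.empty((h, w), dtype=float)
    for lab in np.unique(mask):
        sel = mask == lab
        img[sel] = dists[int(lab)].rvs(int(sel.sum()), rng)
    if spec.noise_sd > 0:
        img += rng.normal(0.0, spec.noise_sd, size=img.shape)
    img = np.clip(img, *spec.value_range)

    areas = [np.sum(mask == lab) for lab in range(len(dists))]
    return LabeledSample(RasterImage(img, spec.value_range), mask,
                         _truth_params(dists, areas), spec.seed)


def make_dataset(spec: PhantomSpec, n: int, seed: int = 0) -> list[LabeledSample]:
    """``n`` phantoms with per-sample derived seeds ``seed + i``."""
    if n < 1:
        raise ValueError("n must be >= 1")
    from dataclasses import replace

    return [generate_lung_phantom(replace(spec, seed=seed + i)) for i in range(n)]


def save_dataset(samples, outdir) -> None:
    """Write paired image/mask PNGs and a manifest CSV."""
    import csv
    from pathlib import Path

    from .image import save_image, save_mask

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    with open(outdir / "manifest.csv", "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["sample_id", "seed", "n_nodules", "image", "mask",
                         "truth_locations", "truth_scales", "truth_weights"])
        for i, s in enumerate(samples):
            img_name, mask_name = f"sample_{i:04d}.png", f"sample_{i:04d}_mask.png"
            save_image(s.image, outdir / img_name)
            save_mask(s.mask, outdir / mask_name)
            n_nod = int(np.unique(s.mask[s.mask == 2]).size and
                        _count_components(s.mask == 2))
            writer.writerow([
                i, s.seed, n_nod, img_name, mask_name,
                ";".join(f"{c.location:g}" for c in s.truth_params.components),
                ";".join(f"{c.scale:g}" for c in s.truth_params.components),
                ";".join(f"{w:g}" for w in s.truth_params.weights),
            ])


def _count_components(binary: np.ndarray) -> int:
    from scipy import ndimage

    _, n = ndimage.label(binary)
    return int(n)
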