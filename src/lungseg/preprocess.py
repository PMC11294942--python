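"""CT preparation chain: Hounsfield windowing, CLAHE, adaptive Wiener
filtering, resizing, [0,1] normalization and rotation augmentation.

The default stage order (window -> CLAHE -> Wiener -> resize -> normalize)
follows the usual CT display/enhancement convention: map the diagnostic
Hounsfield window to the visible range, boost local contrast, denoise, then
bring the image to the network's working resolution and scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.transform import resize as _sk_resize

from .image import RasterImage

__all__ = [
    "WindowSpec",
    "ClaheConfig",
    "WienerConfig",
    "ConfigurationError",
    "LUNG_WINDOW",
    "SOFT_TISSUE_WINDOW",
    "hounsfield_window",
    "clahe",
    "wiener_filter",
    "resize",
    "normalize01",
    "augment_rotations",
    "preprocess_pipeline",
    "DEFAULT_STAGES",
]


class ConfigurationError(ValueError):
    pass


@dataclass(frozen=True)
class WindowSpec:
    """Hounsfield display window (center/width, HU)."""

    center: float
    width: float

    def __post_init__(self) -> None:
        if not (self.width > 0):
            raise ValueError("window width must be > 0")


#: Standard lung window: center -600 HU, width 1500 HU.
LUNG_WINDOW = WindowSpec(-600.0, 1500.0)
#: Standard soft-tissue window: center 50 HU, width 400 HU.
SOFT_TISSUE_WINDOW = WindowSpec(50.0, 400.0)


@dataclass(frozen=True)
class ClaheConfig:
    """Contrast-limited adaptive histogram equalization settings.

    ``clip_limit`` is the per-bin ceiling expressed as a fraction of the
    tile's pixel count; the clipped excess is redistributed uniformly over all
    bins (one pass, so a small residual above the ceiling can remain).
    """

    tile_grid: tuple[int, int] = (8, 8)
    clip_limit: float = 0.01
    n_bins: int = 256

    def __post_init__(self) -> None:
        if self.tile_grid[0] < 1 or self.tile_grid[1] < 1:
            raise ValueError("tile_grid entries must be >= 1")
        if not (self.clip_limit > 0):
            raise ValueError("clip_limit must be > 0")
        if self.n_bins < 2:
            raise ValueError("n_bins must be >= 2")


@dataclass(frozen=True)
class WienerConfig:
    """Local adaptive Wiener filter settings.

    ``noise_variance``: a fixed non-negative value, or "auto" to use the mean
    of the local variances (the usual adaptive estimate).
    """

    window: int = 3
    noise_variance: float | str = "auto"

    def __post_init__(self) -> None:
        if self.window < 1 or self.window % 2 == 0:
            raise ValueError("window must be odd and >= 1")
        if isinstance(self.noise_variance, str):
            if self.noise_variance != "auto":
                raise ValueError("noise_variance must be a number or 'auto'")
        elif self.noise_variance < 0:
            raise ValueError("noise_variance must be >= 0")


def hounsfield_window(image: RasterImage, spec: WindowSpec = LUNG_WINDOW) -> RasterImage:
    """Linearly map [center-width/2, center+width/2] HU onto [0,1], clamped."""
    lo = spec.center - spec.width / 2.0
    out = np.clip((image.pixels - lo) / spec.width, 0.0, 1.0)
    return RasterImage(out, (0.0, 1.0))


def _clip_histogram(hist: np.ndarray, ceiling: float) -> np.ndarray:
    """Clip bins at ``ceiling`` and spread the excess uniformly (single pass)."""
    excess = np.sum(np.maximum(hist - ceiling, 0.0))
    clipped = np.minimum(hist, ceiling)
    return clipped + excess / hist.size


def _tile_mapping(tile: np.ndarray, lo: float, hi: float, cfg: ClaheConfig) -> np.ndarray:
    """Equalization lookup table (bin index -> output value) for one tile."""
    bins = np.clip(((tile - lo) / (hi - lo) * cfg.n_bins).astype(int), 0, cfg.n_bins - 1)
    hist = np.bincount(bins.ravel(), minlength=cfg.n_bins).astype(float)
    ceiling = cfg.clip_limit * tile.size
    if np.isfinite(ceiling):
        hist = _clip_histogram(hist, ceiling)
    cdf = np.cumsum(hist)
    cdf /= cdf[-1]
    return lo + (hi - lo) * cdf


def clahe(image: RasterImage, cfg: ClaheConfig | None = None) -> RasterImage:
    """Contrast-limited adaptive histogram equalization.

    Per-tile clipped-histogram equalization mappings are blended by bilinear
    interpolation between tile centers; the output keeps the declared value
    range.  With a 1x1 tile grid and an unbounded clip limit this reduces to
    plain global histogram equalization.
    """
    cfg = cfg or ClaheConfig()
    rows, cols = cfg.tile_grid
    h, w = image.shape
    if rows > h or cols > w:
        raise ConfigurationError(f"tile grid {cfg.tile_grid} larger than image {image.shape}")
    lo, hi = image.value_range
    px = image.pixels

    # tile boundaries (tiles cover the image; last tile absorbs the remainder)
    r_edges = np.linspace(0, h, rows + 1).astype(int)
    c_edges = np.linspace(0, w, cols + 1).astype(int)
    luts = np.empty((rows, cols, cfg.n_bins))
    r_centers = np.empty(rows)
    c_centers = np.empty(cols)
    for i in range(rows):
        for j in range(cols):
            tile = px[r_edges[i]:r_edges[i + 1], c_edges[j]:c_edges[j + 1]]
            luts[i, j] = _tile_mapping(tile, lo, hi, cfg)
        r_centers[i] = (r_edges[i] + r_edges[i + 1] - 1) / 2.0
    for j in range(cols):
        c_centers[j] = (c_edges[j] + c_edges[j + 1] - 1) / 2.0

    bins = np.clip(((px - lo) / (hi - lo) * cfg.n_bins).astype(int), 0, cfg.n_bins - 1)

    # bilinear blend of the four surrounding tile mappings (clamped at borders)
    rr = np.arange(h, dtype=float)
    cc = np.arange(w, dtype=float)
    ri = np.clip(np.searchsorted(r_centers, rr) - 1, 0, max(rows - 2, 0))
    ci = np.clip(np.searchsorted(c_centers, cc) - 1, 0, max(cols - 2, 0))
    if rows > 1:
        rw = np.clip((rr - r_centers[ri]) / (r_centers[ri + 1] - r_centers[ri]), 0.0, 1.0)
    else:
        rw = np.zeros(h)
    if cols > 1:
        cw = np.clip((cc - c_centers[ci]) / (c_centers[ci + 1] - c_centers[ci]), 0.0, 1.0)
    else:
        cw = np.zeros(w)

    ri2 = np.minimum(ri + 1, rows - 1)
    ci2 = np.minimum(ci + 1, cols - 1)
    RW = rw[:, None]
    CW = cw[None, :]
    RI, CI = ri[:, None], ci[None, :]
    RI2, CI2 = ri2[:, None], ci2[None, :]
    out = (
        (1 - RW) * (1 - CW) * luts[RI, CI, bins]
        + (1 - RW) * CW * luts[RI, CI2, bins]
        + RW * (1 - CW) * luts[RI2, CI, bins]
        + RW * CW * luts[RI2, CI2, bins]
    )
    return RasterImage(np.clip(out, lo, hi), image.value_range)


def wiener_filter(image: RasterImage, cfg: WienerConfig | None = None) -> RasterImage:
    """Local adaptive Wiener denoising with reflective borders.

    out = m + max(0, v - v_n) / max(v, v_n) * (x - m) with local mean m and
    local variance v over the window; pixels whose neighborhood variance is at
    or below the noise floor collapse to the local mean.
    """
    cfg = cfg or WienerConfig()
    x = image.pixels
    mean = ndimage.uniform_filter(x, size=cfg.window, mode="reflect")
    var = ndimage.uniform_filter(x * x, size=cfg.window, mode="reflect") - mean**2
    var = np.maximum(var, 0.0)
    noise = float(var.mean()) if cfg.noise_variance == "auto" else float(cfg.noise_variance)
    gain = np.maximum(var - noise, 0.0) / np.maximum(var, noise if noise > 0 else 1e-300)
    out = mean + gain * (x - mean)
    lo, hi = image.value_range
    return RasterImage(np.clip(out, lo, hi), image.value_range)


def resize(image: RasterImage, target: tuple[int, int]) -> RasterImage:
    """Deterministic bilinear/area resampling to ``target`` (h, w)."""
    if target[0] < 1 or target[1] < 1:
        raise ValueError("target size must be >= 1x1")
    if tuple(target) == image.shape:
        return image
    down = target[0] < image.height or target[1] < image.width
    out = _sk_resize(image.pixels, target, order=1, anti_aliasing=down,
                     preserve_range=True, mode="reflect")
    lo, hi = image.value_range
    return RasterImage(np.clip(out, lo, hi), image.value_range)


def normalize01(image: RasterImage) -> RasterImage:
    """Min-max rescale to [0,1]; a constant image maps to all zeros."""
    x = image.pixels
    lo, hi = float(x.min()), float(x.max())
    out = np.zeros_like(x) if hi <= lo else (x - lo) / (hi - lo)
    return RasterImage(out, (0.0, 1.0))


def augment_rotations(image: RasterImage, mask: np.ndarray):
    """Eight rotated (image, mask) copies at 45-degree steps.

    Axis-aligned rotations (0/90/180/270) are exact grid rotations; the
    diagonal angles resample with bilinear interpolation for the image and
    nearest-neighbor for the mask, with reflective padding, about the center.
    """
    mask = np.asarray(mask)
    if image.shape != mask.shape:
        raise ValueError(f"image shape {image.shape} != mask shape {mask.shape}")
    lo, hi = image.value_range
    pairs = []
    for k, angle in enumerate(range(0, 360, 45)):
        if angle % 90 == 0:
            img_r = np.rot90(image.pixels, k=angle // 90)
            msk_r = np.rot90(mask, k=angle // 90)
        else:
            img_r = ndimage.rotate(image.pixels, angle, reshape=False, order=1,
                                   mode="reflect")
            msk_r = ndimage.rotate(mask, angle, reshape=False, order=0,
                                   mode="reflect")
        pairs.append((RasterImage(np.clip(img_r, lo, hi), image.value_range),
                      msk_r.copy()))
    return pairs


DEFAULT_STAGES = ("window", "clahe", "wiener", "resize", "normalize")


def preprocess_pipeline(
    image: RasterImage,
    stages=DEFAULT_STAGES,
    *,
    window: WindowSpec = LUNG_WINDOW,
    clahe_cfg: ClaheConfig | None = None,
    wiener_cfg: WienerConfig | None = None,
    resize_to: tuple[int, int] = (128, 128),
) -> RasterImage:
    """Apply the configured stages in order; an empty stage list is identity."""
    out = image
    for stage in stages:
        if stage == "window":
            out = hounsfield_window(out, window)
        elif stage == "clahe":
            out = clahe(out, clahe_cfg)
        elif stage == "wiener":
            out = wiener_filter(out, wiener_cfg)
        elif stage == "resize":
            out = resize(out, resize_to)
        elif stage == "normalize":
            out = normalize01(out)
        else:
            raise ConfigurationError(f"unknown preprocessing stage {stage!r}")
    return out
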