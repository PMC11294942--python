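"""Finite mixtures of logistic-type distributions fitted by EM.

Segmentation model: the flattened pixel intensities y_1..y_N of a CT slice are
treated as i.i.d. draws from a K-component mixture

    m(y) = sum_i w_i f(y; mu_i, sigma_i, p),

with f the logistic-type density (see :mod:`lungseg.distributions`).  The
E-step computes per-pixel responsibilities

    r_si = w_i f_i(y_s) / sum_j w_j f_j(y_s),

and the M-step re-estimates w_i as the mean responsibility and (mu_i, sigma_i)
by maximizing the responsibility-weighted log-likelihood of each component
numerically (the weighted score equations have no closed form in this family).
Segmentation assigns each pixel to its maximum-posterior component.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np
import yaml
from scipy import optimize, signal
from scipy.ndimage import gaussian_filter1d
from scipy.special import logsumexp

from .distributions import TWO_PARAM_SHAPE, LogisticTypeDist

__all__ = [
    "MixtureParams",
    "EMConfig",
    "EMTrace",
    "DegenerateLikelihoodError",
    "ComponentCollapseError",
    "mixture_pdf",
    "mixture_logpdf",
    "log_likelihood",
    "responsibilities",
    "em_step",
    "fit_em",
    "initialize_params",
    "estimate_K",
    "classify_pixels",
]

SCALE_FLOOR = 1e-3
COLLAPSE_WEIGHT = 1e-8


class DegenerateLikelihoodError(ValueError):
    """All component densities vanished at some pixel."""


class ComponentCollapseError(ValueError):
    """A component's effective weight fell below the collapse threshold."""


@dataclass(frozen=True)
class MixtureParams:
    """Weights and component parameters of a K-component mixture."""

    components: tuple[LogisticTypeDist, ...]
    weights: tuple[float, ...]

    def __post_init__(self) -> None:
        comps = tuple(self.components)
        w = np.asarray(self.weights, dtype=float)
        object.__setattr__(self, "components", comps)
        object.__setattr__(self, "weights", tuple(w.tolist()))
        if len(comps) != w.size or len(comps) < 1:
            raise ValueError("components and weights must be non-empty and equal-length")
        if np.any(w <= 0) or np.any(w > 1):
            raise ValueError("weights must lie in (0, 1]")
        if abs(w.sum() - 1.0) > 1e-12:
            raise ValueError(f"weights must sum to 1, got {w.sum()!r}")

    @property
    def K(self) -> int:
        return len(self.components)

    @property
    def locations(self) -> np.ndarray:
        return np.array([c.location for c in self.components])

    @property
    def scales(self) -> np.ndarray:
        return np.array([c.scale for c in self.components])

    @property
    def shape(self) -> float:
        return self.components[0].shape

    def to_dict(self) -> dict:
        return {
            "K": self.K,
            "p": float(self.shape),
            "weights": [float(w) for w in self.weights],
            "locations": [float(c.location) for c in self.components],
            "scales": [float(c.scale) for c in self.components],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MixtureParams":
        p = float(d.get("p", TWO_PARAM_SHAPE))
        comps = tuple(
            LogisticTypeDist(float(m), float(s), p)
            for m, s in zip(d["locations"], d["scales"], strict=True)
        )
        mp = cls(comps, tuple(float(w) for w in d["weights"]))
        if "K" in d and int(d["K"]) != mp.K:
            raise ValueError("declared K does not match component count")
        return mp

    def save(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def load(cls, path) -> "MixtureParams":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


@dataclass(frozen=True)
class EMConfig:
    """EM control knobs.

    ``tol`` is the convergence threshold on the maximum absolute change of any
    parameter between iterations (the estimation error of 1e-3 is the
    conventional stopping rule for this model).  ``m_step`` selects between the
    default numerical weighted-MLE M-step and a damped score-equation
    fixed-point update of sigma^2 ("fixed_point"); the latter falls back to the
    MLE update for any component whose fixed-point step would decrease the
    observed-data log-likelihood, so both modes are ascent-preserving.
    """

    tol: float = 1e-3
    max_iter: int = 500
    init_strategy: Literal["quantile", "kmeans", "user"] = "quantile"
    seed: int = 0
    shape: float = TWO_PARAM_SHAPE
    m_step: Literal["mle", "fixed_point"] = "mle"
    user_params: MixtureParams | None = None

    def __post_init__(self) -> None:
        if not (self.tol > 0):
            raise ValueError("tol must be > 0")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        if self.init_strategy == "user" and self.user_params is None:
            raise ValueError("init_strategy 'user' requires user_params")


@dataclass
class EMTrace:
    """Per-iteration record of an EM run."""

    params_per_iter: list[MixtureParams] = field(default_factory=list)
    loglik_per_iter: list[float] = field(default_factory=list)
    converged: bool = False
    iterations: int = 0

    @property
    def final(self) -> MixtureParams:
        return self.params_per_iter[-1]


def _component_logpdfs(pixels: np.ndarray, params: MixtureParams) -> np.ndarray:
    """N x K matrix of log w_i + log f_i(y_s)."""
    logw = np.log(np.asarray(params.weights))
    return np.column_stack([c.logpdf(pixels) for c in params.components]) + logw


def mixture_logpdf(y, params: MixtureParams):
    y = np.atleast_1d(np.asarray(y, dtype=float))
    out = logsumexp(_component_logpdfs(y, params), axis=1)
    return out if out.size > 1 else float(out[0])


def mixture_pdf(y, params: MixtureParams):
    return np.exp(mixture_logpdf(y, params))


def log_likelihood(pixels, params: MixtureParams) -> float:
    """Observed-data log-likelihood sum_s log m(y_s)."""
    pixels = np.asarray(pixels, dtype=float).ravel()
    return float(np.sum(logsumexp(_component_logpdfs(pixels, params), axis=1)))


def responsibilities(pixels, params: MixtureParams) -> np.ndarray:
    """Row-stochastic N x K posterior membership matrix, computed in log space."""
    pixels = np.asarray(pixels, dtype=float).ravel()
    if pixels.size < 1:
        raise ValueError("at least one pixel required")
    lp = _component_logpdfs(pixels, params)
    norm = logsumexp(lp, axis=1)
    bad = ~np.isfinite(norm)
    if np.any(bad):
        raise DegenerateLikelihoodError(
            f"all component densities are zero at pixel index {int(np.argmax(bad))}"
        )
    return np.exp(lp - norm[:, None])


def _weighted_negloglik(theta, pixels, resp_i, shape):
    mu, log_sigma = theta
    if abs(log_sigma) > 500:  # keep exp() finite during line search
        return np.inf
    dist = LogisticTypeDist(mu, max(np.exp(log_sigma), SCALE_FLOOR), shape)
    return -float(resp_i @ dist.logpdf(pixels))


def _mle_update(pixels, resp_i, comp: LogisticTypeDist) -> LogisticTypeDist:
    """Maximize the responsibility-weighted log-likelihood of one component."""
    x0 = np.array([comp.location, np.log(comp.scale)])
    res = optimize.minimize(
        _weighted_negloglik,
        x0,
        args=(pixels, resp_i, comp.shape),
        method="Nelder-Mead",
        options={"xatol": 1e-5, "fatol": 1e-8, "maxiter": 200},
    )
    # Nelder-Mead's initial simplex contains x0, so res.fun <= f(x0): the
    # update can only improve the weighted likelihood (generalized EM).
    mu, log_sigma = res.x
    return LogisticTypeDist(float(mu), max(float(np.exp(log_sigma)), SCALE_FLOOR), comp.shape)


def _score_z(z: np.ndarray, p: float) -> np.ndarray:
    """d/dz of the log-kernel log(p+z^2) - z - 2 log(1+e^(-z))."""
    sz = 1.0 / (1.0 + np.exp(-np.clip(z, -700, 700)))
    return 2.0 * z / (p + z * z) + 1.0 - 2.0 * sz


def _fixed_point_update(pixels, resp_i, comp: LogisticTypeDist) -> LogisticTypeDist:
    """One damped score step: mu by 1-D solve, sigma^2 by a ratio update.

    The sigma score equation sum_s r_s (1 + z_s h'(z_s)) = 0 rearranges to the
    multiplicative fixed point sigma^2 <- sigma^2 * R with
    R = sum r [2 z s(z) - z - 2 z^2/(p+z^2)] / sum r, which equals 1 exactly at
    the stationary point.  A damping exponent of 0.5 keeps the step stable.
    """
    p, sigma = comp.shape, comp.scale
    res = optimize.minimize_scalar(
        lambda m: -float(resp_i @ LogisticTypeDist(m, sigma, p).logpdf(pixels)),
        bounds=(comp.location - 5 * sigma, comp.location + 5 * sigma),
        method="bounded",
    )
    mu = float(res.x)
    z = (pixels - mu) / sigma
    sz = 1.0 / (1.0 + np.exp(-np.clip(z, -700, 700)))
    num = resp_i @ (2.0 * z * sz - z - 2.0 * z * z / (p + z * z))
    ratio = max(float(num / resp_i.sum()), 1e-6)
    sigma_new = max(sigma * ratio**0.25, SCALE_FLOOR)
    return LogisticTypeDist(mu, sigma_new, p)


def em_step(pixels, params: MixtureParams, cfg: EMConfig | None = None) -> MixtureParams:
    """One E+M iteration; weights become mean responsibilities."""
    cfg = cfg or EMConfig()
    pixels = np.asarray(pixels, dtype=float).ravel()
    resp = responsibilities(pixels, params)
    weights = resp.mean(axis=0)
    for i, w in enumerate(weights):
        if w < COLLAPSE_WEIGHT:
            raise ComponentCollapseError(f"component {i} collapsed (weight {w:.3g})")
    weights = weights / weights.sum()

    new_comps = []
    for i, comp in enumerate(params.components):
        if cfg.m_step == "fixed_point":
            cand = _fixed_point_update(pixels, resp[:, i], comp)
            # guard the generalized-EM ascent property
            if resp[:, i] @ cand.logpdf(pixels) < resp[:, i] @ comp.logpdf(pixels):
                cand = _mle_update(pixels, resp[:, i], comp)
        else:
            cand = _mle_update(pixels, resp[:, i], comp)
        new_comps.append(cand)
    return MixtureParams(tuple(new_comps), tuple(weights.tolist()))


def _param_vector(params: MixtureParams) -> np.ndarray:
    return np.concatenate([params.weights, params.locations, params.scales])


def initialize_params(
    pixels,
    K: int,
    strategy: str = "quantile",
    seed: int = 0,
    shape: float = TWO_PARAM_SHAPE,
) -> MixtureParams:
    """Equal-weight initialization with quantile or k-means locations.

    Scales come from the within-group standard deviation divided by the
    family's standard-deviation-to-scale ratio, floored at 1e-3.
    """
    pixels = np.asarray(pixels, dtype=float).ravel()
    if K < 1:
        raise ValueError("K must be >= 1")
    if np.unique(pixels).size < K:
        raise ValueError(f"K={K} exceeds the number of distinct pixel values")

    if strategy == "quantile":
        locs = np.quantile(pixels, (np.arange(K) + 0.5) / K)
    elif strategy == "kmeans":
        from sklearn.cluster import KMeans

        km = KMeans(n_clusters=K, n_init=10, random_state=seed).fit(pixels[:, None])
        locs = np.sort(km.cluster_centers_.ravel())
    else:
        raise ValueError(f"unknown init strategy {strategy!r}")

    # sd(y) = scale * sqrt((p pi^2 + 7 pi^4/5)/(3p + pi^2))
    sd_ratio = np.sqrt(LogisticTypeDist(0.0, 1.0, shape).var)
    group = np.argmin(np.abs(pixels[:, None] - locs[None, :]), axis=1)
    scales = np.empty(K)
    for i in range(K):
        sd = pixels[group == i].std() if np.any(group == i) else 0.0
        scales[i] = max(sd / sd_ratio, SCALE_FLOOR)
    comps = tuple(LogisticTypeDist(float(m), float(s), shape) for m, s in zip(locs, scales))
    return MixtureParams(comps, tuple([1.0 / K] * K))


def fit_em(pixels, K: int, cfg: EMConfig | None = None) -> EMTrace:
    """Fit a K-component mixture by EM; returns the full iteration trace."""
    cfg = cfg or EMConfig()
    pixels = np.asarray(pixels, dtype=float).ravel()
    if pixels.size < 10 * K:
        raise ValueError(f"need at least {10 * K} pixels for K={K}")
    if K > 1 and np.unique(pixels).size == 1:
        raise ValueError("constant-intensity input cannot support K > 1")

    if cfg.init_strategy == "user":
        params = cfg.user_params
    else:
        params = initialize_params(pixels, K, cfg.init_strategy, cfg.seed, cfg.shape)

    trace = EMTrace()
    trace.params_per_iter.append(params)
    trace.loglik_per_iter.append(log_likelihood(pixels, params))
    for it in range(1, cfg.max_iter + 1):
        new_params = em_step(pixels, params, cfg)
        trace.params_per_iter.append(new_params)
        trace.loglik_per_iter.append(log_likelihood(pixels, new_params))
        delta = np.max(np.abs(_param_vector(new_params) - _param_vector(params)))
        params = new_params
        trace.iterations = it
        if delta < cfg.tol:
            trace.converged = True
            break
    return trace


@dataclass(frozen=True)
class KEstimateConfig:
    """Histogram-mode counting configuration.

    ``bandwidth`` is the Gaussian smoothing sigma in intensity units (None
    picks ~1/64 of the data range); ``min_prominence`` is the required peak
    prominence as a fraction of the tallest smoothed bin.
    """

    n_bins: int = 256
    bandwidth: float | None = None
    min_prominence: float = 0.05


def estimate_K(pixels, cfg: KEstimateConfig | None = None) -> int:
    """Estimate the segment count as the number of prominent histogram modes."""
    cfg = cfg or KEstimateConfig()
    pixels = np.asarray(pixels, dtype=float).ravel()
    if pixels.size < 100:
        raise ValueError("need at least 100 pixels to estimate K")
    lo, hi = float(pixels.min()), float(pixels.max())
    if hi <= lo:
        return 1
    counts, edges = np.histogram(pixels, bins=cfg.n_bins, range=(lo, hi))
    bin_width = edges[1] - edges[0]
    bw = cfg.bandwidth if cfg.bandwidth is not None else (hi - lo) / 64.0
    smooth = gaussian_filter1d(counts.astype(float), sigma=max(bw / bin_width, 0.5))
    # pad so modes at the range ends register as peaks
    padded = np.concatenate([[smooth.min() - 1], smooth, [smooth.min() - 1]])
    peaks, _ = signal.find_peaks(padded, prominence=cfg.min_prominence * smooth.max())
    return max(int(peaks.size), 1)


def classify_pixels(image, params: MixtureParams) -> np.ndarray:
    """Maximum-posterior labels in {0..K-1}; ties go to the lowest index."""
    arr = np.asarray(getattr(image, "pixels", image), dtype=float)
    resp = responsibilities(arr.ravel(), params)
    return np.argmax(resp, axis=1).reshape(arr.shape)
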