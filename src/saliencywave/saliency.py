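"""Per-scale saliency maps, entropy-based scale selection, and fusion.

Channel conspicuities are blended with energy weights and smoothed with
a Gaussian low-pass, giving one normalized saliency map per wavelet
scale.  Each map is scored by an evaluation function (information
entropy times center-weighted saliency mass, lower is better); the two
best-scoring maps are fused with their scores cross-exchanged as
weights and a multiplicative center-bias prior.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter

from .channels import FeatureChannelSet, decompose_channels
from .spectrum import (
    WaveletFilterPair,
    conspicuity_map,
    dct2_forward,
    max_feasible_depth,
    multiscale_magnitudes,
    split_magnitude_sign,
)

__all__ = [
    "SaliencyConfig",
    "ScaleSaliencyMap",
    "FinalSaliencyMap",
    "integrate_channels",
    "interference_matrix",
    "map_entropy",
    "evaluate_map",
    "center_bias_matrix",
    "fuse_best_two",
    "compute_saliency",
]


@dataclass(frozen=True)
class SaliencyConfig:
    """Free parameters of the saliency pipeline.

    ``working_size=None`` runs at native resolution (detection mode).
    ``center_bias_sigma_frac=None`` disables the center-bias prior.
    """

    working_size: tuple[int, int] | None = (128, 128)
    n_scales: int = 6
    wavelet: str = "haar"
    approx_gain: float = 0.0
    spectral_domain: str = "log"
    gaussian_sigma_frac: float = 0.08
    entropy_bins: int = 256
    center_bias_sigma_frac: float | None = 0.55
    epsilon: float = 1e-12

    def __post_init__(self) -> None:
        if self.n_scales < 2:
            raise ValueError("n_scales must be >= 2 (fusion needs two maps)")
        if self.entropy_bins < 1:
            raise ValueError("entropy_bins must be positive")
        if self.gaussian_sigma_frac < 0:
            raise ValueError("gaussian_sigma_frac must be >= 0")
        if self.approx_gain < 0:
            raise ValueError("approx_gain must be >= 0")
        if self.spectral_domain not in ("log", "linear"):
            raise ValueError("spectral_domain must be 'log' or 'linear'")
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")
        if self.working_size is not None:
            h, w = self.working_size
            if h < 1 or w < 1:
                raise ValueError("working_size must be positive")


@dataclass
class ScaleSaliencyMap:
    """A normalized saliency map for one decomposition scale."""

    S: np.ndarray
    scale_index: int
    score: float


@dataclass
class FinalSaliencyMap:
    """Fused, center-biased saliency map in [0, 1]."""

    values: np.ndarray
    selected_scales: tuple[int, int]
    scores: tuple[float, float]
    scale_maps: list[ScaleSaliencyMap] = field(default_factory=list)


def _minmax(arr: np.ndarray, epsilon: float = 1e-12) -> np.ndarray:
    lo = float(arr.min())
    hi = float(arr.max())
    if hi - lo <= epsilon:
        return np.zeros_like(arr)
    return (arr - lo) / (hi - lo + epsilon)


def integrate_channels(
    conspicuities,
    weights,
    sigma: float,
    epsilon: float = 1e-12,
) -> np.ndarray:
    """Gaussian-smoothed weighted sum of four channel conspicuities.

    The result is min-max normalized to [0, 1]; an all-zero blend stays
    zero.  ``sigma=0`` skips the smoothing (identity filter limit).
    """
    maps = [np.asarray(m, dtype=float) for m in conspicuities]
    if len(maps) != 4 or len(weights) != 4:
        raise ValueError("expected four conspicuity maps and four weights")
    shape = maps[0].shape
    for m in maps[1:]:
        if m.shape != shape:
            raise ValueError("conspicuity maps must share one shape")
    blend = sum(w * m for w, m in zip(weights, maps))
    if sigma > 0:
        blend = gaussian_filter(blend, sigma=sigma, mode="reflect", truncate=3.0)
    return _minmax(blend, epsilon)


def interference_matrix(shape: tuple[int, int]) -> np.ndarray:
    """Radial distance-from-center ramp: 0 at center, 1 at the corners."""
    h, w = shape
    if h < 1 or w < 1:
        raise ValueError("shape must be positive")
    rows = np.arange(h, dtype=float)[:, None] - (h - 1) / 2.0
    cols = np.arange(w, dtype=float)[None, :] - (w - 1) / 2.0
    dist = np.hypot(rows, cols)
    peak = dist.max()
    if peak == 0:
        return np.zeros((h, w))
    return dist / peak


def map_entropy(S: np.ndarray, bins: int = 256) -> float:
    """Shannon entropy (bits) of the map's intensity histogram."""
    S = np.asarray(S, dtype=float)
    hist, _ = np.histogram(S, bins=bins, range=(0.0, 1.0))
    p = hist[hist > 0] / S.size
    return float(-(p * np.log2(p)).sum())


def evaluate_map(S: np.ndarray, K: np.ndarray, bins: int = 256) -> float:
    """Evaluation score: entropy times center-weighted saliency mass.

    Lower scores mark cleaner, more centrally concentrated maps.
    """
    S = np.asarray(S, dtype=float)
    K = np.asarray(K, dtype=float)
    if S.shape != K.shape:
        raise ValueError(f"shape mismatch: {S.shape} vs {K.shape}")
    return map_entropy(S, bins) * float((S * K).sum())


def center_bias_matrix(
    shape: tuple[int, int], sigma_frac: float | None = 1.0 / 3.0
) -> np.ndarray:
    """Isotropic Gaussian prior, peak 1 at the image center.

    ``sigma_frac=None`` (or infinity) yields a flat all-ones matrix.
    """
    h, w = shape
    if h < 1 or w < 1:
        raise ValueError("shape must be positive")
    if sigma_frac is None or not np.isfinite(sigma_frac):
        return np.ones((h, w))
    if sigma_frac <= 0:
        raise ValueError("sigma_frac must be positive")
    sigma = sigma_frac * min(h, w)
    rows = np.arange(h, dtype=float)[:, None] - (h - 1) / 2.0
    cols = np.arange(w, dtype=float)[None, :] - (w - 1) / 2.0
    return np.exp(-(rows**2 + cols**2) / (2.0 * sigma**2))


def fuse_best_two(
    scale_maps: list[ScaleSaliencyMap],
    psi: np.ndarray,
    epsilon: float = 1e-12,
) -> FinalSaliencyMap:
    """Fuse the two lowest-scoring scale maps with exchanged weights.

    The fused map is ``psi * (H2*S1 + H1*S2)`` where S1 carries the
    smallest score H1, then min-max normalized.  Ties prefer the finer
    (smaller) scale index.
    """
    if len(scale_maps) < 2:
        raise ValueError("fusion needs at least two scale maps")
    ranked = sorted(scale_maps, key=lambda m: (m.score, m.scale_index))
    best, second = ranked[0], ranked[1]
    h1, h2 = best.score, second.score
    fused = psi * (h2 * best.S + h1 * second.S)
    if h1 == 0.0 and h2 == 0.0:
        # Degenerate: both maps scored perfect (e.g. everything zero);
        # fall back to the unweighted biased mean so a nonzero S1 survives.
        fused = psi * (best.S + second.S)
    return FinalSaliencyMap(
        values=_minmax(fused, epsilon),
        selected_scales=(best.scale_index, second.scale_index),
        scores=(h1, h2),
        scale_maps=list(scale_maps),
    )


def _resize(image: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    from skimage.transform import resize

    if image.shape[:2] == tuple(shape):
        return image
    out = resize(image, shape, order=1, mode="reflect", anti_aliasing=True)
    return np.clip(out, 0.0, 1.0)


def compute_saliency(
    image: np.ndarray,
    config: SaliencyConfig | None = None,
    keep_stack: bool = True,
) -> FinalSaliencyMap:
    """Full saliency pipeline from an RGB image to the fused map.

    Deterministic end to end: resize to the working resolution,
    decompose into feature channels, whiten each channel's DCT magnitude
    spectrum at every wavelet scale, integrate the channel conspicuities
    per scale, score each scale map, and fuse the best two.
    """
    if config is None:
        config = SaliencyConfig()
    image = np.asarray(image, dtype=float)
    if image.ndim == 2:
        image = np.repeat(image[:, :, None], 3, axis=2)
    if config.working_size is not None:
        image = _resize(image, tuple(config.working_size))

    channels: FeatureChannelSet = decompose_channels(image)
    shape = channels.I.shape

    n_scales = config.n_scales
    feasible = max_feasible_depth(shape)
    if n_scales > feasible:
        warnings.warn(
            f"n_scales reduced from {n_scales} to {feasible} for shape {shape}",
            RuntimeWarning,
            stacklevel=2,
        )
        n_scales = feasible
    if n_scales < 2:
        raise ValueError(f"image of shape {shape} too small for two scales")

    filters = WaveletFilterPair.from_name(config.wavelet)
    per_channel: list[tuple[np.ndarray, list[np.ndarray]]] = []
    for cmap in channels.maps():
        F = dct2_forward(cmap)
        pair = split_magnitude_sign(F)
        mags = multiscale_magnitudes(
            pair.A_M,
            n_scales,
            filters,
            config.approx_gain,
            domain=config.spectral_domain,
        )
        per_channel.append((pair.S_M, mags.scales))

    sigma = config.gaussian_sigma_frac * shape[1]
    K = interference_matrix(shape)
    weights = channels.weights()

    scale_maps: list[ScaleSaliencyMap] = []
    for n in range(n_scales):
        consps = [
            conspicuity_map(mags[n], S_M) for S_M, mags in per_channel
        ]
        S_n = integrate_channels(consps, weights, sigma, config.epsilon)
        score = evaluate_map(S_n, K, config.entropy_bins)
        scale_maps.append(ScaleSaliencyMap(S=S_n, scale_index=n + 1, score=score))

    psi = center_bias_matrix(shape, config.center_bias_sigma_frac)
    final = fuse_best_two(scale_maps, psi, config.epsilon)
    if not keep_stack:
        final.scale_maps = []
    return final
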