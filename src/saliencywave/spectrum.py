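"""DCT spectrum analysis and multiscale Mallat wavelet machinery.

Each feature channel is taken to the frequency domain with an
orthonormal 2-D DCT-II, factorized into a nonnegative magnitude matrix
and a sign matrix, and the magnitude matrix is run through a separable
Mallat filter bank.  Zeroing (or attenuating) the deepest approximation
subband before reconstruction flattens the spectral envelope to a
scale-dependent degree; the inverse DCT of the modulated spectrum is the
channel's conspicuity map at that scale.

The filter bank uses periodic extension, so any orthonormal filter pair
gives exact perfect reconstruction.  Non-power-of-two inputs are
symmetrically padded to a multiple of ``2**depth`` and cropped back
after synthesis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.fft import dctn, idctn

__all__ = [
    "dct2_forward",
    "dct2_inverse",
    "split_magnitude_sign",
    "SpectrumPair",
    "WaveletFilterPair",
    "WaveletPyramid",
    "MultiscaleMagnitudes",
    "mallat_decompose",
    "mallat_reconstruct",
    "multiscale_magnitudes",
    "conspicuity_map",
    "max_feasible_depth",
]


# ---------------------------------------------------------------------------
# DCT analysis

def dct2_forward(channel: np.ndarray) -> np.ndarray:
    """Orthonormal 2-D DCT-II of a real map."""
    channel = np.asarray(channel, dtype=float)
    if channel.size == 0:
        raise ValueError("cannot transform an empty map")
    if channel.ndim != 2:
        raise ValueError(f"expected a 2-D map, got ndim={channel.ndim}")
    return dctn(channel, type=2, norm="ortho")


def dct2_inverse(coeffs: np.ndarray) -> np.ndarray:
    """Inverse of :func:`dct2_forward` (orthonormal DCT-III)."""
    coeffs = np.asarray(coeffs, dtype=float)
    if coeffs.size == 0:
        raise ValueError("cannot transform an empty map")
    return idctn(coeffs, type=2, norm="ortho")


@dataclass(frozen=True)
class SpectrumPair:
    """Magnitude/sign factorization of a DCT coefficient matrix.

    ``A_M`` is elementwise nonnegative, ``S_M`` has entries in
    {-1, 0, +1}, and ``S_M * A_M`` reassembles the coefficients exactly.
    """

    A_M: np.ndarray
    S_M: np.ndarray


def split_magnitude_sign(F: np.ndarray) -> SpectrumPair:
    """Factor DCT coefficients into magnitude and sign matrices."""
    F = np.asarray(F, dtype=float)
    return SpectrumPair(A_M=np.abs(F), S_M=np.sign(F))


# ---------------------------------------------------------------------------
# Wavelet filter bank

# Orthonormal low-pass analysis taps; the high-pass taps follow from the
# quadrature-mirror relation g[n] = (-1)^n h[L-1-n].
_SQRT2 = math.sqrt(2.0)
_SQRT3 = math.sqrt(3.0)
_LOWPASS_TAPS: dict[str, tuple[float, ...]] = {
    "haar": (1.0 / _SQRT2, 1.0 / _SQRT2),
    "db2": (
        (1.0 + _SQRT3) / (4.0 * _SQRT2),
        (3.0 + _SQRT3) / (4.0 * _SQRT2),
        (3.0 - _SQRT3) / (4.0 * _SQRT2),
        (1.0 - _SQRT3) / (4.0 * _SQRT2),
    ),
}


@dataclass(frozen=True)
class WaveletFilterPair:
    """Orthonormal analysis filter pair (low-pass ``h``, high-pass ``g``)."""

    h: np.ndarray
    g: np.ndarray
    name: str = "custom"

    @classmethod
    def from_name(cls, name: str) -> "WaveletFilterPair":
        try:
            h = np.asarray(_LOWPASS_TAPS[name.lower()], dtype=float)
        except KeyError:
            known = ", ".join(sorted(_LOWPASS_TAPS))
            raise ValueError(f"unknown wavelet {name!r}; known: {known}") from None
        signs = np.where(np.arange(h.size) % 2 == 0, 1.0, -1.0)
        g = signs * h[::-1]
        return cls(h=h, g=g, name=name.lower())

    def __post_init__(self) -> None:
        h = np.asarray(self.h, dtype=float)
        g = np.asarray(self.g, dtype=float)
        if h.size != g.size or h.size < 2 or h.size % 2:
            raise ValueError("filter taps must come in equal even lengths >= 2")
        object.__setattr__(self, "h", h)
        object.__setattr__(self, "g", g)


def _analyze_axis(
    x: np.ndarray, filters: WaveletFilterPair, axis: int
) -> tuple[np.ndarray, np.ndarray]:
    # a[i] = sum_j h[j] x[(2i+j) mod n]; likewise d[i] with g.
    x = np.moveaxis(x, axis, 0)
    n = x.shape[0]
    half = n // 2
    base = 2 * np.arange(half)
    a = np.zeros((half,) + x.shape[1:])
    d = np.zeros_like(a)
    for j, (hj, gj) in enumerate(zip(filters.h, filters.g)):
        rows = (base + j) % n
        xv = x[rows]
        a += hj * xv
        d += gj * xv
    return np.moveaxis(a, 0, axis), np.moveaxis(d, 0, axis)


def _synthesize_axis(
    a: np.ndarray, d: np.ndarray, filters: WaveletFilterPair, axis: int
) -> np.ndarray:
    a = np.moveaxis(a, axis, 0)
    d = np.moveaxis(d, axis, 0)
    half = a.shape[0]
    n = 2 * half
    y = np.zeros((n,) + a.shape[1:])
    base = 2 * np.arange(half)
    for j, (hj, gj) in enumerate(zip(filters.h, filters.g)):
        rows = (base + j) % n  # distinct for fixed j, so += is safe
        y[rows] += hj * a + gj * d
    return np.moveaxis(y, 0, axis)


@dataclass
class WaveletPyramid:
    """Separable 2-D wavelet pyramid.

    ``details[k]`` holds the (Bds, Bsd, Bdd) subbands produced at level
    ``k+1``; ``approx`` is the deepest approximation subband Bss.
    ``orig_shape`` remembers the pre-padding shape so reconstruction can
    crop back.
    """

    approx: np.ndarray
    details: list[tuple[np.ndarray, np.ndarray, np.ndarray]]
    filters: WaveletFilterPair
    orig_shape: tuple[int, int]

    @property
    def depth(self) -> int:
        return len(self.details)


def max_feasible_depth(shape: tuple[int, int]) -> int:
    """Largest decomposition depth supported by a matrix of this shape."""
    m = min(shape)
    if m < 2:
        return 0
    return int(math.floor(math.log2(m)))


def _pad_to_multiple(matrix: np.ndarray, block: int) -> np.ndarray:
    h, w = matrix.shape
    ph = (-h) % block
    pw = (-w) % block
    if ph == 0 and pw == 0:
        return matrix
    return np.pad(matrix, ((0, ph), (0, pw)), mode="symmetric")


def mallat_decompose(
    matrix: np.ndarray, depth: int, filters: WaveletFilterPair | None = None
) -> WaveletPyramid:
    """Multi-level separable filter-bank analysis.

    At each level the current approximation is split into four subbands
    (Bss, Bds, Bsd, Bdd) by low/high-pass filtering and dyadic
    downsampling along both axes; the recursion continues on Bss.
    """
    matrix = np.asarray(matrix, dtype=float)
    if matrix.ndim != 2:
        raise ValueError("expected a 2-D matrix")
    if depth < 1:
        raise ValueError("depth must be >= 1")
    feasible = max_feasible_depth(matrix.shape)
    if depth > feasible:
        raise ValueError(
            f"depth {depth} too large for shape {matrix.shape}; "
            f"max feasible depth is {feasible}"
        )
    if filters is None:
        filters = WaveletFilterPair.from_name("haar")

    orig_shape = matrix.shape
    current = _pad_to_multiple(matrix, 2**depth)
    details: list[tuple[np.ndarray, np.ndarray, np.ndarray]] = []
    for _ in range(depth):
        # first axis: s/d split, then second axis
        s_rows, d_rows = _analyze_axis(current, filters, axis=0)
        bss, bsd = _analyze_axis(s_rows, filters, axis=1)
        bds, bdd = _analyze_axis(d_rows, filters, axis=1)
        details.append((bds, bsd, bdd))
        current = bss
    return WaveletPyramid(
        approx=current, details=details, filters=filters, orig_shape=orig_shape
    )


def mallat_reconstruct(pyramid: WaveletPyramid) -> np.ndarray:
    """Synthesis inverse of :func:`mallat_decompose`."""
    current = pyramid.approx
    for bds, bsd, bdd in reversed(pyramid.details):
        if not (current.shape == bds.shape == bsd.shape == bdd.shape):
            raise ValueError(
                "inconsistent subband shapes: "
                f"{current.shape}, {bds.shape}, {bsd.shape}, {bdd.shape}"
            )
        s_rows = _synthesize_axis(current, bsd, pyramid.filters, axis=1)
        d_rows = _synthesize_axis(bds, bdd, pyramid.filters, axis=1)
        current = _synthesize_axis(s_rows, d_rows, pyramid.filters, axis=0)
    h, w = pyramid.orig_shape
    return current[:h, :w]


# ---------------------------------------------------------------------------
# Multiscale magnitude modulation

@dataclass
class MultiscaleMagnitudes:
    """Reconstructed magnitude matrices, one per decomposition depth."""

    scales: list[np.ndarray] = field(default_factory=list)

    @property
    def n_scales(self) -> int:
        return len(self.scales)

    def __iter__(self):
        return iter(self.scales)

    def __getitem__(self, idx):
        return self.scales[idx]


# Offset guarding log(0); small against any magnitude of interest.
LOG_EPS = 1e-8


def multiscale_magnitudes(
    A_M: np.ndarray,
    n_scales: int,
    filters: WaveletFilterPair | None = None,
    approx_gain: float = 0.0,
    domain: str = "log",
) -> MultiscaleMagnitudes:
    """Envelope-flattened magnitude matrices at ``n_scales`` depths.

    For scale ``N`` the magnitude matrix is decomposed to depth ``N``,
    the depth-``N`` approximation subband is multiplied by
    ``approx_gain``, and the matrix is reconstructed.  Deeper scales
    suppress a coarser, lower-energy approximation, i.e. flatten the
    envelope more mildly.

    With ``domain="log"`` (the default used by the saliency pipeline)
    the filter bank runs on ``log(A_M + eps)`` and the reconstruction is
    exponentiated back, so full suppression (``approx_gain=0``) divides
    each magnitude by its scale-``N`` smooth envelope — true spectral
    whitening, which equalizes repeated (iso-feature) energy.  With
    ``domain="linear"`` the filter bank runs on the raw magnitudes and
    suppression subtracts the envelope instead; this mode is linear in
    ``A_M`` but flattens far more weakly.  In either domain
    ``approx_gain=1`` reproduces ``A_M`` exactly (perfect
    reconstruction).
    """
    A_M = np.asarray(A_M, dtype=float)
    if n_scales < 1:
        raise ValueError("n_scales must be >= 1")
    if domain not in ("log", "linear"):
        raise ValueError(f"domain must be 'log' or 'linear', got {domain!r}")
    feasible = max_feasible_depth(A_M.shape)
    if n_scales > feasible:
        raise ValueError(
            f"n_scales {n_scales} exceeds max feasible depth {feasible} "
            f"for shape {A_M.shape}"
        )
    if filters is None:
        filters = WaveletFilterPair.from_name("haar")

    matrix = np.log(A_M + LOG_EPS) if domain == "log" else A_M
    out = MultiscaleMagnitudes()
    for depth in range(1, n_scales + 1):
        pyr = mallat_decompose(matrix, depth, filters)
        pyr.approx = pyr.approx * approx_gain
        rec = mallat_reconstruct(pyr)
        if domain == "log":
            rec = np.exp(rec) - LOG_EPS
        out.scales.append(rec)
    return out


def conspicuity_map(A_prime: np.ndarray, S_M: np.ndarray) -> np.ndarray:
    """Spatial conspicuity: |IDCT(sign-matrix * modulated magnitude)|."""
    A_prime = np.asarray(A_prime, dtype=float)
    S_M = np.asarray(S_M, dtype=float)
    if A_prime.shape != S_M.shape:
        raise ValueError(
            f"shape mismatch: magnitude {A_prime.shape} vs sign {S_M.shape}"
        )
    return np.abs(dct2_inverse(S_M * A_prime))
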