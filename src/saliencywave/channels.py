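"""Biologically motivated feature channels.

An RGB image is decomposed into one intensity channel and three
general-tuned color channels (red, green, blue), each paired with an
energy-based weight that models lateral inhibition: channels carrying a
lot of total energy are down-weighted so that rare features dominate the
saliency map.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class FeatureChannelSet:
    """The four general-tuned feature maps and their weights.

    All maps share one shape and are nonnegative (the color channels are
    clipped at zero).  Weights are dimensionless scalars >= 0.
    """

    I: np.ndarray
    R: np.ndarray
    G: np.ndarray
    B: np.ndarray
    omega_I: float
    omega_R: float
    omega_G: float
    omega_B: float

    def maps(self) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        return self.I, self.R, self.G, self.B

    def weights(self) -> tuple[float, float, float, float]:
        return self.omega_I, self.omega_R, self.omega_G, self.omega_B


def channel_weight(channel: np.ndarray) -> float:
    """Energy-normalized weight of a feature channel.

    Returns ``max(channel) / sum(channel)`` when the channel carries any
    energy, and ``max(channel)`` (i.e. 0 for the all-zero map) otherwise.
    The sum runs over the whole map regardless of resolution.

    Parameters
    ----------
    channel : ndarray
        Nonnegative 2-D feature map.
    """
    channel = np.asarray(channel, dtype=float)
    if channel.size == 0:
        raise ValueError("channel weight of an empty map is undefined")
    total = float(channel.sum())
    peak = float(channel.max())
    if total != 0.0:
        return peak / total
    return peak


def decompose_channels(image: np.ndarray) -> FeatureChannelSet:
    """Split an RGB image into intensity + general-tuned color channels.

    Given bands ``r, g, b`` (floats in [0, 1]):

    - ``I = (r + g + b) / 3``
    - ``R = r - (g + b) / 2``
    - ``G = g - (r + b) / 2``
    - ``B = b - (r + g) / 2``

    Negative values in R, G, B are set to zero.  Each channel's weight
    is computed with :func:`channel_weight`.

    Parameters
    ----------
    image : ndarray, shape (H, W, 3)
        Nonnegative RGB raster.

    Raises
    ------
    ValueError
        If the input does not have exactly three bands.
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError(
            f"expected an H x W x 3 image, got shape {image.shape}"
        )
    if np.any(image < 0):
        raise ValueError("image intensities must be nonnegative")

    r = image[:, :, 0]
    g = image[:, :, 1]
    b = image[:, :, 2]

    I = (r + g + b) / 3.0
    R = np.clip(r - (g + b) / 2.0, 0.0, None)
    G = np.clip(g - (r + b) / 2.0, 0.0, None)
    B = np.clip(b - (r + g) / 2.0, 0.0, None)

    return FeatureChannelSet(
        I=I,
        R=R,
        G=G,
        B=B,
        omega_I=channel_weight(I),
        omega_R=channel_weight(R),
        omega_G=channel_weight(G),
        omega_B=channel_weight(B),
    )
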