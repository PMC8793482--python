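import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def one_over_f_noise(rng, n=128):
    """Natural-image-like 2-D noise with a 1/f amplitude spectrum."""
    spec = np.fft.fft2(rng.normal(size=(n, n)))
    fy = np.fft.fftfreq(n)[:, None]
    fx = np.fft.fftfreq(n)[None, :]
    f = np.hypot(fy, fx)
    f[0, 0] = 1.0
    img = np.real(np.fft.ifft2(spec / f))
    return (img - img.min()) / np.ptp(img)


@pytest.fixture
def natural_like_image(rng):
    """128x128 RGB image with 1/f statistics in each band."""
    bands = [one_over_f_noise(rng) for _ in range(3)]
    return np.stack(bands, axis=-1)


def argmax_in_box(values, box):
    r, c = np.unravel_index(np.argmax(values), values.shape)
    top, left, height, width = box
    return top <= r < top + height and left <= c < left + width
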