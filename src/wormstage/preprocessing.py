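"""Image conditioning shared by both feature paths.

The handcrafted (M2) path runs, in order: histogram equalization to enhance
contrast, Gaussian low-pass filtering to suppress sensor noise, and a
frequency-domain high-pass filter to remove the smooth worm-tissue signal
and surrounding background — fluorescent protein spots live in the
high-frequency part of the spectrum, tissue and background in the low.
The deep (M1) path consumes an average-pooled (block-mean) downsampled
image; at the instrument's native 6000 x 4000 resolution a pool factor of 10
yields the 600 x 400 network input.

All operations are deterministic and single-channel.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import exposure


@dataclass(frozen=True)
class FilterConfig:
    """Tunable length-scales of the conditioning chain.

    ``lowpass_sigma`` is the Gaussian blur sigma in pixels (default 2.0 —
    after histogram equalization the background noise dominates the spot
    band, and a sigma comparable to the smallest spot scale is needed to
    pull spot peaks clear of the noise floor); ``highpass_cutoff`` is the
    radial cutoff as a fraction of the Nyquist frequency; ``pool_factor``
    is the block size of the average-pool downsampling for the CNN path.
    """

    lowpass_sigma: float = 2.0
    highpass_cutoff: float = 0.05
    pool_factor: int = 4

    def __post_init__(self) -> None:
        if self.lowpass_sigma <= 0:
            raise ValueError("lowpass_sigma must be > 0")
        if not 0 < self.highpass_cutoff < 1:
            raise ValueError("highpass_cutoff must be in (0, 1)")
        if self.pool_factor < 1:
            raise ValueError("pool_factor must be >= 1")


def equalize_histogram(image: np.ndarray) -> np.ndarray:
    """Full-image histogram equalization (256 bins), preserving intensity
    order. A constant image has no histogram to spread and is returned
    unchanged with a warning."""
    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise ValueError("expected a single-channel (2-D) image")
    if np.ptp(image) == 0:
        warnings.warn("constant image: histogram equalization is a no-op", stacklevel=2)
        return image.copy()
    return exposure.equalize_hist(image, nbins=256)


def denoise_lowpass(image: np.ndarray, config: FilterConfig) -> np.ndarray:
    """Linear shift-invariant Gaussian low-pass filter; reduces the variance
    of white noise while preserving the mean."""
    return ndimage.gaussian_filter(
        np.asarray(image, dtype=float), config.lowpass_sigma, mode="reflect"
    )


def _highpass_mask(shape: tuple[int, int], cutoff: float) -> np.ndarray:
    """Radial high-pass transfer function with a raised-cosine edge.

    The radial coordinate is normalized so that the Nyquist frequency is 1.
    The mask is 0 below ``cutoff/2``, 1 above ``3*cutoff/2``, and follows a
    half-cosine ramp in between (the smooth edge suppresses ringing that an
    ideal brick-wall mask would cause).
    """
    h, w = shape
    fy = np.fft.fftfreq(h)[:, None] / 0.5
    fx = np.fft.fftfreq(w)[None, :] / 0.5
    rho = np.sqrt(fy**2 + fx**2)
    lo, hi = 0.5 * cutoff, 1.5 * cutoff
    mask = np.ones(shape)
    mask[rho <= lo] = 0.0
    ramp = (rho > lo) & (rho < hi)
    mask[ramp] = 0.5 * (1 - np.cos(np.pi * (rho[ramp] - lo) / (hi - lo)))
    return mask


def highpass_frequency_filter(image: np.ndarray, config: FilterConfig) -> np.ndarray:
    """Remove low-frequency content (tissue, background shading) by masking
    the 2-D FFT below the cutoff and inverse-transforming.

    The DC component is always removed, so the output is (numerically)
    zero-mean; bright compact spots survive as positive bumps.
    """
    image = np.asarray(image, dtype=float)
    spectrum = np.fft.fft2(image)
    filtered = np.fft.ifft2(spectrum * _highpass_mask(image.shape, config.highpass_cutoff))
    return np.real(filtered)


def downsample_average_pool(image: np.ndarray, pool_factor: int) -> np.ndarray:
    """Block-mean downsampling: each output pixel is the mean of its
    ``pool_factor x pool_factor`` block; trailing rows/columns that do not
    fill a block are truncated."""
    image = np.asarray(image, dtype=float)
    if pool_factor < 1:
        raise ValueError("pool_factor must be >= 1")
    h, w = image.shape
    if pool_factor > h or pool_factor > w:
        raise ValueError(f"pool_factor {pool_factor} exceeds image dims {h}x{w}")
    if pool_factor == 1:
        return image.copy()
    h2, w2 = h // pool_factor, w // pool_factor
    trimmed = image[: h2 * pool_factor, : w2 * pool_factor]
    return trimmed.reshape(h2, pool_factor, w2, pool_factor).mean(axis=(1, 3))


def preprocess_for_detection(image: np.ndarray, config: FilterConfig) -> np.ndarray:
    """Full M2-path conditioning: equalize -> low-pass -> high-pass.

    Returns a float image, zero-mean, with spots as positive bumps; feed it
    to :func:`wormstage.spot_detector.detect_spots`, which handles the
    8-bit rescaling the threshold sweep expects.
    """
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # constant images fall through cleanly
        equalized = equalize_histogram(image)
    smoothed = denoise_lowpass(equalized, config)
    return highpass_frequency_filter(smoothed, config)
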