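"""Retina-emulating stimulus pipeline.

The model's visual input is a stream of 17x17 grayscale patches that have been
passed through a centre-surround (difference-of-Gaussians) filter, randomly
rotated, mean-subtracted and scaled to the [-1, 1] range, and finally split
into half-rectified ON-centre and OFF-centre channels.  The concatenated
ON/OFF vector (length 2 * 17 * 17 = 578) sets the rates of the Poisson spike
trains that drive the network's feedforward synapses.

Because the natural-image corpus used originally is not deposited anywhere,
the module also ships a synthetic naturalistic-image generator producing
spatially correlated images with an approximately 1/f amplitude spectrum,
which is the statistical signature of natural scenes that the development
of oriented receptive fields depends on.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

PATCH_SIZE = 17
N_PIXELS = PATCH_SIZE * PATCH_SIZE          # 289
N_CHANNELS = 2 * N_PIXELS                   # 578 (ON then OFF)

# side of the square subregion that still contains a 17x17 window under any
# rotation: ceil(17 * sqrt(2)) plus a 2-pixel interpolation margin
_ROT_MARGIN = 27


@dataclass
class StimulusPatch:
    """A preprocessed patch plus its ON/OFF channel vector.

    ``patch`` is the normalized 17x17 array in [-1, 1]; ``on_off`` is the
    length-578 non-negative channel vector, ON channels first.  ``source_meta``
    records provenance (image id, location, rotation angle).
    """

    patch: np.ndarray
    on_off: np.ndarray
    source_meta: dict = field(default_factory=dict)


def _unit_gaussian_kernel(sigma: float, radius: int) -> np.ndarray:
    ax = np.arange(-radius, radius + 1, dtype=float)
    xx, yy = np.meshgrid(ax, ax)
    k = np.exp(-(xx ** 2 + yy ** 2) / (2.0 * sigma ** 2))
    return k / k.sum()


def dog_kernel(sigma_center: float = 1.0, sigma_surround: float = 2.0) -> np.ndarray:
    """Difference-of-Gaussians kernel, each Gaussian normalized to unit sum.

    Truncated at +/- 4 * sigma_surround.  Because both Gaussians integrate to
    one, the kernel itself integrates to zero: a uniform field produces no
    response, mirroring retinal centre-surround cells.
    """
    if not (0 < sigma_center < sigma_surround):
        raise ValueError("require 0 < sigma_center < sigma_surround")
    radius = int(np.ceil(4.0 * sigma_surround))
    return (_unit_gaussian_kernel(sigma_center, radius)
            - _unit_gaussian_kernel(sigma_surround, radius))


def dog_filter(image: np.ndarray, sigma_center: float = 1.0,
               sigma_surround: float = 2.0) -> np.ndarray:
    """Centre-surround filter an image (s.d. 1 and 2 pixels by default)."""
    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise ValueError(f"expected a 2-D grayscale image, got ndim={image.ndim}")
    kernel = dog_kernel(sigma_center, sigma_surround)
    return ndimage.convolve(image, kernel, mode="nearest")


def extract_patch(image: np.ndarray, rng: np.random.Generator,
                  angle_deg: float | None = None) -> np.ndarray:
    """Extract a randomly located, randomly rotated 17x17 patch.

    The location is uniform over all positions where a rotated window fits.
    Rotation uses bilinear interpolation of a square subregion around the
    patch centre; ``angle_deg`` overrides the random angle (used by tests).

    A 17x17 image is accepted as the degenerate case (identity crop, rotation
    forced to zero).
    """
    image = np.asarray(image, dtype=float)
    h, w = image.shape
    if h == PATCH_SIZE and w == PATCH_SIZE:
        return image.copy()
    if h < _ROT_MARGIN or w < _ROT_MARGIN:
        raise ValueError(
            f"image must be at least {_ROT_MARGIN}x{_ROT_MARGIN} "
            f"(or exactly {PATCH_SIZE}x{PATCH_SIZE}); got {h}x{w}")
    if angle_deg is None:
        angle_deg = float(rng.uniform(0.0, 360.0))
    half = _ROT_MARGIN // 2
    r = int(rng.integers(half, h - half))
    c = int(rng.integers(half, w - half))
    sub = image[r - half: r + half + 1, c - half: c + half + 1]
    if angle_deg != 0.0:
        sub = ndimage.rotate(sub, angle_deg, reshape=False, order=1,
                             mode="nearest")
    lo = half - PATCH_SIZE // 2
    return sub[lo: lo + PATCH_SIZE, lo: lo + PATCH_SIZE].copy()


def normalize_patch(patch: np.ndarray) -> np.ndarray:
    """Mean-subtract and scale to max |value| = 1.

    A degenerate (constant) patch maps to all zeros, i.e. null input.
    """
    patch = np.asarray(patch, dtype=float)
    if not np.all(np.isfinite(patch)):
        raise ValueError("patch contains non-finite values")
    out = patch - patch.mean()
    peak = np.abs(out).max()
    if peak == 0.0:
        return out
    return out / peak


def split_on_off(patch: np.ndarray) -> np.ndarray:
    """Split a signed patch into the concatenated [ON; OFF] channel vector.

    ON channels carry the half-rectified positive part, OFF channels the
    sign-flipped negative part, so ON - OFF reconstructs the patch exactly.
    """
    flat = np.asarray(patch, dtype=float).ravel()
    return np.concatenate([np.maximum(flat, 0.0), np.maximum(-flat, 0.0)])


def on_off_to_patch(on_off: np.ndarray,
                    size: int = PATCH_SIZE) -> np.ndarray:
    """Inverse of :func:`split_on_off` (ON half minus OFF half)."""
    on_off = np.asarray(on_off, dtype=float)
    n = size * size
    return (on_off[:n] - on_off[n:]).reshape(size, size)


def shuffle_pixels(patch: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Uniformly permute a patch's pixels (the spatial-structure control).

    Preserves the multiset of intensities exactly while destroying all
    spatial correlation.
    """
    patch = np.asarray(patch, dtype=float)
    flat = patch.ravel().copy()
    rng.shuffle(flat)
    return flat.reshape(patch.shape)


def generate_synthetic_image(size: int = 128, spectral_exponent: float = 1.0,
                             rng: np.random.Generator | None = None) -> np.ndarray:
    """Generate a spatially correlated image with a power-law spectrum.

    The radially averaged amplitude spectrum falls off as 1/f**exponent;
    exponent 1 approximates natural-scene statistics, exponent 0 is white
    noise.  Output is zero-mean with unit standard deviation.
    """
    if size < 64:
        raise ValueError("size must be >= 64")
    if rng is None:
        rng = np.random.default_rng()
    white = rng.standard_normal((size, size))
    spectrum = np.fft.fft2(white)
    fy = np.fft.fftfreq(size)[:, None]
    fx = np.fft.fftfreq(size)[None, :]
    f = np.hypot(fy, fx)
    f[0, 0] = 1.0  # DC handled separately
    amp = f ** (-float(spectral_exponent))
    amp[0, 0] = 0.0
    img = np.fft.ifft2(spectrum * amp).real
    img -= img.mean()
    sd = img.std()
    if sd > 0:
        img /= sd
    return img


def rates_from_stimulus(on_off: np.ndarray, rate_scale: float) -> np.ndarray:
    """Map the ON/OFF intensity vector to Poisson rates (Hz).

    ``rate_scale`` is the intensity-to-rate conversion in Hz per unit
    intensity; rates are simply ``rate_scale * on_off``.
    """
    if rate_scale < 0:
        raise ValueError("rate_scale must be non-negative")
    on_off = np.asarray(on_off, dtype=float)
    if np.any(on_off < 0):
        raise ValueError("on_off values must be non-negative")
    return rate_scale * on_off


def make_patch(image: np.ndarray, rng: np.random.Generator,
               shuffle: bool = False, meta: dict | None = None) -> StimulusPatch:
    """Full pipeline from a (already DoG-filtered) image to a StimulusPatch."""
    p = normalize_patch(extract_patch(image, rng))
    if shuffle:
        p = shuffle_pixels(p, rng)
    return StimulusPatch(patch=p, on_off=split_on_off(p),
                         source_meta=meta or {})


class PatchStream:
    """Endless stream of preprocessed patches from synthetic images.

    Images are generated lazily (``patches_per_image`` patches are drawn from
    each DoG-filtered synthetic image before a new one is made), which mimics
    sampling subregions with replacement from an image corpus.
    """

    def __init__(self, rng: np.random.Generator, image_size: int = 128,
                 spectral_exponent: float = 1.0, patches_per_image: int = 50,
                 shuffle: bool = False):
        self.rng = rng
        self.image_size = image_size
        self.spectral_exponent = spectral_exponent
        self.patches_per_image = patches_per_image
        self.shuffle = shuffle
        self._filtered = None
        self._left = 0
        self._image_id = -1

    def _next_image(self) -> None:
        img = generate_synthetic_image(self.image_size, self.spectral_exponent,
                                       self.rng)
        self._filtered = dog_filter(img)
        self._left = self.patches_per_image
        self._image_id += 1

    def next_patch(self) -> np.ndarray:
        """Return the next normalized (possibly pixel-shuffled) 17x17 patch."""
        if self._left <= 0:
            self._next_image()
        self._left -= 1
        p = normalize_patch(extract_patch(self._filtered, self.rng))
        if self.shuffle:
            p = shuffle_pixels(p, self.rng)
        return p

    def next_on_off(self) -> np.ndarray:
        return split_on_off(self.next_patch())

    def batch_on_off(self, n: int) -> np.ndarray:
        """n x 578 array of consecutive ON/OFF vectors."""
        out = np.empty((n, N_CHANNELS))
        for i in range(n):
            out[i] = self.next_on_off()
        return out
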