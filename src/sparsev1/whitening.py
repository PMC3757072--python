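"""Retina-style whitening of images and stimuli.

Whitening approximates the decorrelating transfer function of the retina/LGN:
natural images have a ~1/f amplitude spectrum, so multiplying each spatial
frequency by ``f`` flattens the spectrum, while a steep low-pass roll-off
``exp(-(f/f0)^4)`` suppresses the noisy highest frequencies.  The combined
frequency-domain gain is

    w(f) = f * exp(-(f / f0)^4),   f in cycles/image,

applied on the DFT grid of a square image.  The gain at DC is zero, so
whitened images (and whitened stimuli composited on a gray background) carry
no mean luminance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: reference cutoff for a 512-pixel image; rescaled proportionally for other
#: grid sides so the filter shape is resolution-invariant.
F0_REFERENCE = 200.0
SIDE_REFERENCE = 512


def default_f0(image_side: int) -> float:
    """Cutoff frequency (cycles/image) scaled from the 512-px convention."""
    return F0_REFERENCE * image_side / SIDE_REFERENCE


@dataclass(frozen=True)
class WhiteningFilter:
    """Frequency-domain whitening gain over a square image grid.

    Attributes
    ----------
    f0 : float
        Low-pass cutoff in cycles per image.
    kernel : ndarray
        Gain on the (unshifted) DFT grid, shape ``(side, side)``.
    """

    f0: float
    kernel: np.ndarray = field(repr=False)

    @property
    def side(self) -> int:
        return self.kernel.shape[0]

    def __call__(self, image: np.ndarray) -> np.ndarray:
        return whiten(self, image)


def build_whitening_filter(image_side: int, f0: float | None = None) -> WhiteningFilter:
    """Construct the radially symmetric whitening gain ``f * exp(-(f/f0)^4)``.

    Parameters
    ----------
    image_side : int
        Side of the square image grid in pixels (>= 4).
    f0 : float, optional
        Cutoff in cycles/image; defaults to the 200 * side/512 convention.
    """
    if image_side < 4:
        raise ValueError(f"image_side must be >= 4, got {image_side}")
    if f0 is None:
        f0 = default_f0(image_side)
    if f0 <= 0:
        raise ValueError(f"f0 must be positive, got {f0}")
    # frequency coordinates in cycles/image on the unshifted DFT grid
    fx = np.fft.fftfreq(image_side) * image_side
    f = np.hypot(fx[:, None], fx[None, :])
    kernel = f * np.exp(-((f / f0) ** 4))
    return WhiteningFilter(f0=float(f0), kernel=kernel)


def whiten(filt: WhiteningFilter, image: np.ndarray) -> np.ndarray:
    """Apply the whitening gain in the frequency domain.

    Linear in its input; a constant image maps to zero (DC gain is 0).
    """
    image = np.asarray(image, dtype=float)
    if image.shape != filt.kernel.shape:
        raise ValueError(
            f"image shape {image.shape} does not match filter grid "
            f"{filt.kernel.shape}"
        )
    spectrum = np.fft.fft2(image) * filt.kernel
    return np.real(np.fft.ifft2(spectrum))
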