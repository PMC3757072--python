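"""Synthetic inputs: naturalistic image ensembles, Gabor fixture
dictionaries, and ground-truth sparse generative samples.

The package ships no image data; everything the pipeline consumes is
generated here.  Dead-leaves ensembles (occluding disks with power-law
radii) reproduce the scale-invariant, edge-dominated second-order statistics
of natural scenes well enough for dictionary learning to produce localized,
oriented, band-pass elements; 1/f-spectrum noise is a lighter-weight
alternative with the correct power spectrum but no edges.  The Gabor fixture
dictionary stands in for a learned dictionary so the electrophysiology
protocols run in seconds with known ground truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dictionary import Dictionary

__all__ = [
    "ImageEnsembleSpec",
    "generate_images",
    "gabor_dictionary",
    "sample_sparse_generative",
]


@dataclass(frozen=True)
class ImageEnsembleSpec:
    """Recipe for a synthetic naturalistic image ensemble.

    ``model`` is ``dead_leaves`` (occlusion) or ``pink_noise`` (spectral).
    ``exponent`` is the disk-radius power-law exponent (dead leaves; 3 gives
    scale invariance) or the power-spectrum exponent (pink noise; amplitude
    ~ 1/f^(exponent/2)).
    """

    model: str = "dead_leaves"
    n_images: int = 10
    image_side: int = 128
    seed: int = 0
    exponent: float = 3.0
    r_min: float = 2.0
    r_max: float | None = None  # defaults to image_side / 4

    def __post_init__(self) -> None:
        if self.n_images < 1:
            raise ValueError("n_images must be >= 1")
        if self.model not in ("dead_leaves", "pink_noise"):
            raise ValueError(f"unknown image model {self.model!r}")


def generate_images(spec: ImageEnsembleSpec) -> list[np.ndarray]:
    """Generate a seeded, reproducible ensemble of grayscale images."""
    rng = np.random.default_rng(spec.seed)
    if spec.model == "dead_leaves":
        return [_dead_leaves(spec, rng) for _ in range(spec.n_images)]
    return [_pink_noise(spec, rng) for _ in range(spec.n_images)]


def _dead_leaves(spec: ImageEnsembleSpec, rng: np.random.Generator) -> np.ndarray:
    """Composite opaque disks front-to-back until the canvas is covered.

    Radii follow a power law p(r) ~ r^-exponent on [r_min, r_max];
    intensities are uniform on [0, 1].  Painting back-to-front while only
    filling still-empty pixels is equivalent to front-to-back occlusion.
    """
    n = spec.image_side
    r_max = spec.r_max if spec.r_max is not None else n / 4.0
    img = np.full((n, n), np.nan)
    rows = np.arange(n)[:, None]
    cols = np.arange(n)[None, :]
    n_empty = n * n
    a = 1.0 - spec.exponent  # CDF inversion exponent
    while n_empty > 0:
        u = rng.random()
        if abs(a) < 1e-12:
            r = spec.r_min * (r_max / spec.r_min) ** u
        else:
            r = (spec.r_min**a + u * (r_max**a - spec.r_min**a)) ** (1.0 / a)
        cr, cc = rng.random(2) * n
        shade = rng.random()
        disk = (rows - cr) ** 2 + (cols - cc) ** 2 <= r * r
        paint = disk & np.isnan(img)
        if paint.any():
            img[paint] = shade
            n_empty -= int(paint.sum())
    return img


def _pink_noise(spec: ImageEnsembleSpec, rng: np.random.Generator) -> np.ndarray:
    """Gaussian noise shaped to a 1/f^(exponent/2) amplitude spectrum."""
    n = spec.image_side
    white = rng.standard_normal((n, n))
    fx = np.fft.fftfreq(n) * n
    f = np.hypot(fx[:, None], fx[None, :])
    amp = np.zeros_like(f)
    nz = f > 0
    amp[nz] = f[nz] ** (-spec.exponent / 2.0)
    shaped = np.real(np.fft.ifft2(np.fft.fft2(white) * amp))
    shaped -= shaped.mean()
    sd = shaped.std()
    return shaped / sd if sd > 0 else shaped


# --------------------------------------------------------------------- gabors
def gabor_patch(
    patch_side: int,
    center: tuple[float, float],
    orientation: float,
    spatial_freq: float,
    phase: float,
    sigma_along: float = 2.0,
    sigma_across: float = 1.5,
) -> np.ndarray:
    """Unit-energy Gabor using the package's stimulus conventions.

    The carrier phase argument matches the grating renderer
    (``sf * (dr*sin(th) + dc*cos(th)) + phase``) so a grating at the
    generating parameters is the optimal linear stimulus.
    """
    if sigma_along <= 0 or sigma_across <= 0:
        raise ValueError("Gabor envelope sigmas must be positive")
    th = math.radians(orientation)
    dr = np.arange(patch_side, dtype=float)[:, None] - center[0]
    dc = np.arange(patch_side, dtype=float)[None, :] - center[1]
    across = dr * math.sin(th) + dc * math.cos(th)  # modulation axis
    along = -dr * math.cos(th) + dc * math.sin(th)  # stripe axis
    envelope = np.exp(
        -0.5 * ((along / sigma_along) ** 2 + (across / sigma_across) ** 2)
    )
    g = envelope * np.cos(spatial_freq * across + phase)
    norm = np.linalg.norm(g)
    if norm == 0:
        raise ValueError("degenerate Gabor (zero energy)")
    return g / norm


def gabor_dictionary(
    patch_side: int = 16,
    centers: int | list[tuple[float, float]] = 5,
    orientations: int | list[float] = 8,
    phases: list[float] = (0.0, math.pi / 2),
    spatial_freqs: list[float] = (1.0,),
    sigma_along: float = 2.0,
    sigma_across: float = 1.5,
) -> Dictionary:
    """Parametric Gabor fixture dictionary on a grid, mirrored.

    ``centers`` may be a count ``k`` (a centered k × k lattice) or explicit
    (row, col) positions; ``orientations`` a count (evenly spaced on
    [0, 180)) or explicit degrees.  Ground-truth centers and orientations
    are recorded in ``meta``.
    """
    if isinstance(centers, int):
        # k x k lattice placed symmetrically inside the patch
        pos = np.linspace(0, patch_side - 1, centers + 2)[1:-1]
        centers = [(float(r), float(c)) for r in pos for c in pos]
    if isinstance(orientations, int):
        orientations = list(np.arange(orientations) * 180.0 / orientations)
    if not centers or not orientations or not list(phases) or not list(spatial_freqs):
        raise ValueError("fixture grid must be non-empty")
    elements, rows = [], []
    for (cr, cc) in centers:
        for ori in orientations:
            for sf in spatial_freqs:
                for ph in phases:
                    elements.append(
                        gabor_patch(
                            patch_side, (cr, cc), ori, sf, ph,
                            sigma_along, sigma_across,
                        )
                    )
                    rows.append((cr, cc, ori, sf, ph))
    elements = np.stack(elements)
    m = elements.shape[0]
    base = pd.DataFrame(
        rows,
        columns=["center_row", "center_col", "true_orientation",
                 "true_spatial_freq", "true_phase"],
    )
    base["polarity"] = 1.0
    neg = base.copy()
    neg["polarity"] = -1.0
    meta = pd.concat([base, neg], ignore_index=True)
    return Dictionary(elements=elements, mirrored=True, meta=meta)


def sample_sparse_generative(
    dictionary: Dictionary,
    k: int,
    amp_sd: float = 1.0,
    noise_sd: float = 0.01,
    n: int = 100,
    seed: int | None = 0,
):
    """Draw patches ``x = Phi a* + eps`` with known k-sparse codes.

    Active entries are |N(0, amp_sd)| (nonnegative convention) at ``k``
    uniformly chosen learned elements; ``eps`` is i.i.d. N(0, noise_sd).
    Returns ``(patches (n, P, P), codes (n, M_learned))``.
    """
    if k > dictionary.n_learned:
        raise ValueError("k exceeds the number of learned elements")
    rng = np.random.default_rng(seed)
    m = dictionary.n_learned
    p = dictionary.patch_side
    phi = dictionary.elements.reshape(m, -1).T
    codes = np.zeros((n, m))
    for i in range(n):
        idx = rng.choice(m, size=k, replace=False)
        codes[i, idx] = np.abs(rng.normal(0.0, amp_sd, size=k))
    patches = codes @ phi.T
    patches += rng.normal(0.0, noise_sd, size=patches.shape)
    return patches.reshape(n, p, p), codes
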