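"""Stimulus rendering for virtual electrophysiology.

All protocols probe the model with classical stimuli — bars, circular
sinusoidal grating patches, annular (surround) gratings, plaids — rendered
on the patch grid, whitened with the same analytic filter used during
training, and composited on a gray background with the same mean as the
grating (so the whitened stimulus carries no DC step).

Conventions
-----------
* Patches are indexed ``(row, col)``, origin top-left, 0-based; stimulus
  centers and CRF centers share this frame.
* Orientation is in degrees in [0, 180), measured counterclockwise from
  horizontal; the sinusoid's spatial phase argument is
  ``sf * (dr*sin(theta) + dc*cos(theta)) + phase`` with ``sf`` in
  radians/pixel.
* Contrast is the peak-to-trough range of the intensity values inside the
  aperture (the bar value sits ``contrast`` above/below the background).
* Apertures are hard-edged (no cosine taper), sampled at pixel centers.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .whitening import WhiteningFilter, whiten

__all__ = ["StimulusSpec", "FrameSequence", "render", "prepare", "drift"]

log = logging.getLogger(__name__)

BACKGROUND = 0.5
DEFAULT_CONTRAST = 0.3  # stimulus contrast used unless a protocol notes otherwise


@dataclass(frozen=True)
class StimulusSpec:
    """Geometric description of one stimulus.

    ``size`` is the disc diameter (gratings), bar length (bars), or the
    outer constraint for annuli; ``width`` is the bar width or the annulus
    thickness; ``inner_radius``/``gap`` apply to annuli only (modulation
    occupies radii ``[inner_radius + gap, inner_radius + gap + width]``).
    Plaids carry a second grating in ``mask``.
    """

    kind: str = "grating_disc"  # bar | grating_disc | grating_annulus | plaid | uniform
    center: tuple[float, float] = (7.5, 7.5)
    size: float = 8.0
    width: float = 2.0
    orientation: float = 0.0
    spatial_freq: float = 1.0
    phase: float = 0.0
    contrast: float = DEFAULT_CONTRAST
    inner_radius: float = 0.0
    gap: float = 0.0
    polarity: int = 1  # bar polarity: +1 light, -1 dark
    mask: "StimulusSpec | None" = None

    def __post_init__(self) -> None:
        if self.contrast < 0:
            raise ValueError("contrast must be >= 0")
        if self.size < 0:
            raise ValueError("size must be >= 0")
        if not 0 <= self.orientation < 180:
            object.__setattr__(self, "orientation", self.orientation % 180.0)

    def replace(self, **kw) -> "StimulusSpec":
        return replace(self, **kw)


@dataclass
class FrameSequence:
    """Frames of a drifting stimulus at progressive phases."""

    frames: np.ndarray  # (n_frames, P, P)
    phase_step: float  # radians/frame
    cycle_frames: int  # frames per temporal cycle

    def __len__(self) -> int:
        return self.frames.shape[0]


def _grid(patch_side: int, center: tuple[float, float]):
    r = np.arange(patch_side, dtype=float)[:, None] - center[0]
    c = np.arange(patch_side, dtype=float)[None, :] - center[1]
    return r, c


def _sinusoid(spec: StimulusSpec, dr: np.ndarray, dc: np.ndarray) -> np.ndarray:
    th = math.radians(spec.orientation)
    arg = spec.spatial_freq * (dr * math.sin(th) + dc * math.cos(th)) + spec.phase
    return np.cos(arg)


def _grating_field(spec: StimulusSpec, dr, dc, aperture: np.ndarray) -> np.ndarray:
    """Sinusoid scaled so max-min over the aperture equals the contrast,
    centered on the background level; zero outside the aperture."""
    out = np.zeros_like(dr * dc, dtype=float)
    if spec.contrast == 0 or not aperture.any():
        return out
    if spec.spatial_freq == 0:
        # degenerate grating = uniform luminance patch (light, like a bar)
        out[aperture] = spec.contrast
        return out
    raw = _sinusoid(spec, dr, dc)
    vals = raw[aperture]
    rng = vals.max() - vals.min()
    if rng <= 0:
        return out
    mid = (vals.max() + vals.min()) / 2.0
    out[aperture] = spec.contrast * (raw[aperture] - mid) / rng
    return out


def render(spec: StimulusSpec, patch_side: int) -> np.ndarray:
    """Render one stimulus on a ``patch_side`` × ``patch_side`` grid.

    The image equals the background everywhere outside the aperture; inside,
    the intensity range equals ``spec.contrast`` exactly (continuous values).
    """
    dr, dc = _grid(patch_side, spec.center)
    rad = np.hypot(dr, dc)
    img = np.full((patch_side, patch_side), BACKGROUND)

    if spec.kind == "uniform" or spec.contrast == 0:
        return img

    if spec.kind == "grating_disc":
        aperture = rad <= spec.size / 2.0
        _warn_if_clipped(aperture, rad, spec, patch_side)
        img += _grating_field(spec, dr, dc, aperture)
    elif spec.kind == "grating_annulus":
        r_in = spec.inner_radius + spec.gap
        aperture = (rad >= r_in) & (rad <= r_in + spec.width)
        img += _grating_field(spec, dr, dc, aperture)
    elif spec.kind == "bar":
        th = math.radians(spec.orientation)
        along = -dr * math.cos(th) + dc * math.sin(th)  # stripe direction
        across = dr * math.sin(th) + dc * math.cos(th)  # modulation axis
        aperture = (np.abs(along) <= spec.size / 2.0) & (
            np.abs(across) <= spec.width / 2.0
        )
        img[aperture] += spec.polarity * spec.contrast
    elif spec.kind == "plaid":
        if spec.mask is None:
            raise ValueError("plaid spec requires a mask component")
        test = render(spec.replace(kind="grating_disc", mask=None), patch_side)
        mask = render(spec.mask, patch_side)
        img = test + mask - BACKGROUND
    else:
        raise ValueError(f"unknown stimulus kind {spec.kind!r}")
    return img


_clip_warned: set = set()


def _warn_if_clipped(aperture, rad, spec, patch_side) -> None:
    r0, c0 = spec.center
    if (
        r0 - spec.size / 2 < -0.5
        or c0 - spec.size / 2 < -0.5
        or r0 + spec.size / 2 > patch_side - 0.5
        or c0 + spec.size / 2 > patch_side - 0.5
    ):
        key = (spec.center, round(spec.size, 3), patch_side)
        if key not in _clip_warned:  # warn once per geometry, not per frame
            _clip_warned.add(key)
            log.warning(
                "aperture (size %.1f at %s) extends beyond the %d-px patch; "
                "clipped",
                spec.size,
                spec.center,
                patch_side,
            )


def prepare(spec: StimulusSpec, filt: WhiteningFilter) -> np.ndarray:
    """Render, whiten, and composite a stimulus into a model-ready patch.

    Whitening removes the DC component, so the gray background maps to zero
    and the result is linear in contrast above DC.
    """
    return whiten(filt, render(spec, filt.side))


def drift(
    spec: StimulusSpec,
    temporal_freq: float = 3.0,
    frame_rate: float = 30.0,
    n_cycles: float = 1.0,
    patch_side: int | None = None,
    whitener: WhiteningFilter | None = None,
) -> FrameSequence:
    """Discretize a drifting grating as static frames at progressive phases.

    The per-frame phase increment is ``2*pi*temporal_freq/frame_rate``
    (3 Hz at 30 frames/s -> 10 frames per cycle).  A zero temporal frequency
    yields a constant sequence of one cycle's worth of frames.  When a
    ``whitener`` is supplied the frames are model-ready (whitened) patches.
    """
    if temporal_freq < 0 or frame_rate <= 0:
        raise ValueError("temporal_freq must be >= 0 and frame_rate > 0")
    if temporal_freq > 0 and frame_rate <= 2 * temporal_freq:
        raise ValueError(
            f"frame rate {frame_rate} violates Nyquist for {temporal_freq} Hz"
        )
    if temporal_freq == 0:
        cycle_frames = int(round(frame_rate))
        phase_step = 0.0
    else:
        cycle_frames = int(round(frame_rate / temporal_freq))
        phase_step = 2 * math.pi * temporal_freq / frame_rate
    n_frames = int(round(cycle_frames * n_cycles))
    if patch_side is None:
        if whitener is None:
            raise ValueError("provide patch_side or a whitener")
        patch_side = whitener.side

    def one(phase_offset: float) -> np.ndarray:
        s = _advance_phase(spec, phase_offset)
        if whitener is not None:
            return prepare(s, whitener)
        return render(s, patch_side)

    frames = np.stack([one(k * phase_step) for k in range(n_frames)])
    return FrameSequence(frames=frames, phase_step=phase_step, cycle_frames=cycle_frames)


def _advance_phase(spec: StimulusSpec, dphi: float) -> StimulusSpec:
    """Advance the phase of a stimulus and (phase-locked) of its mask."""
    new = spec.replace(phase=spec.phase + dphi)
    if spec.mask is not None:
        new = new.replace(mask=spec.mask.replace(phase=spec.mask.phase + dphi))
    return new
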