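"""Dictionaries of model receptive fields: learning, mirroring, selection.

A dictionary is a set of unit-energy spatial elements over a square patch,
interpreted as the classical receptive fields (CRFs) of the model neurons.
Elements are learned from whitened image patches by alternating sparse
inference (an ℓ1-penalized least-squares solve per patch) with a gradient
step on the reconstruction error, the classic recipe for sparse coding of
natural scenes.  For a rate (nonnegative) code the learned block is mirrored
with its negation, doubling the effective population so signed coefficients
become pairs of opponent units.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.decomposition import sparse_encode

from .whitening import WhiteningFilter, build_whitening_filter, whiten

__all__ = [
    "Dictionary",
    "sample_patches",
    "learn_dictionary",
    "mirror",
    "select_localized",
]


@dataclass
class Dictionary:
    """A set of unit-energy patch elements, optionally mirrored.

    Attributes
    ----------
    elements : ndarray, shape (M_learned, P, P)
        The learned (unmirrored) elements.
    mirrored : bool
        Whether the effective dictionary is ``[Phi, -Phi]``.
    meta : DataFrame
        Per-effective-unit metadata: CRF center (row, col), polarity, and
        optimal grating parameters once an experiment fills them in.
    """

    elements: np.ndarray
    mirrored: bool = False
    meta: pd.DataFrame | None = None
    _matrix: np.ndarray | None = field(default=None, repr=False, compare=False)
    _gram: np.ndarray | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.elements = np.asarray(self.elements, dtype=float)
        if self.elements.ndim != 3 or self.elements.shape[1] != self.elements.shape[2]:
            raise ValueError("elements must have shape (M, P, P)")
        if not np.isfinite(self.elements).all():
            raise ValueError("dictionary elements contain non-finite values")
        if self.meta is None:
            self.meta = default_meta(self.elements, self.mirrored)

    # ------------------------------------------------------------------ shape
    @property
    def n_learned(self) -> int:
        return self.elements.shape[0]

    @property
    def patch_side(self) -> int:
        return self.elements.shape[1]

    @property
    def effective_count(self) -> int:
        return 2 * self.n_learned if self.mirrored else self.n_learned

    @property
    def matrix(self) -> np.ndarray:
        """Column matrix (n_pixels, effective_count); mirrored block appended."""
        if self._matrix is None:
            phi = self.elements.reshape(self.n_learned, -1).T
            self._matrix = np.hstack([phi, -phi]) if self.mirrored else phi
        return self._matrix

    @property
    def gram(self) -> np.ndarray:
        """Cached Gram matrix Phi^T Phi of the effective dictionary."""
        if self._gram is None:
            self._gram = self.matrix.T @ self.matrix
        return self._gram

    def invalidate_cache(self) -> None:
        """Explicitly drop cached matrix/Gram (after mutating elements)."""
        self._matrix = None
        self._gram = None

    # ------------------------------------------------------------------ ops
    def mirror(self) -> "Dictionary":
        return mirror(self)

    def select_localized(self, energy_fraction: float = 0.9, window: int | None = None):
        return select_localized(self, energy_fraction, window)

    # ------------------------------------------------------------------ io
    def save_npz(self, path) -> None:
        np.savez(
            path,
            elements=self.elements,
            mirrored=np.array(self.mirrored),
            meta_columns=np.array(list(self.meta.columns), dtype=object),
            meta_values=self.meta.to_numpy(dtype=float),
        )

    @classmethod
    def load_npz(cls, path) -> "Dictionary":
        with np.load(path, allow_pickle=True) as data:
            meta = pd.DataFrame(
                data["meta_values"], columns=[str(c) for c in data["meta_columns"]]
            )
            return cls(
                elements=data["elements"],
                mirrored=bool(data["mirrored"]),
                meta=meta,
            )

    def save_hdf5(self, path) -> None:
        import h5py

        with h5py.File(path, "w") as f:
            f.create_dataset("elements", data=self.elements)
            f.attrs["mirrored"] = self.mirrored
            grp = f.create_group("meta")
            for col in self.meta.columns:
                grp.create_dataset(col, data=self.meta[col].to_numpy(dtype=float))

    @classmethod
    def load_hdf5(cls, path) -> "Dictionary":
        import h5py

        with h5py.File(path, "r") as f:
            meta = pd.DataFrame({k: v[...] for k, v in f["meta"].items()})
            return cls(
                elements=f["elements"][...],
                mirrored=bool(f.attrs["mirrored"]),
                meta=meta,
            )


def default_meta(elements: np.ndarray, mirrored: bool) -> pd.DataFrame:
    """CRF centers from the maximum-|amplitude| pixel of each element."""
    m = elements.shape[0]
    flat = np.abs(elements.reshape(m, -1))
    idx = flat.argmax(axis=1)
    rows, cols = np.unravel_index(idx, elements.shape[1:])
    meta = pd.DataFrame(
        {
            "center_row": rows.astype(float),
            "center_col": cols.astype(float),
            "polarity": np.ones(m),
        }
    )
    if mirrored:
        neg = meta.copy()
        neg["polarity"] = -1.0
        meta = pd.concat([meta, neg], ignore_index=True)
    return meta


def sample_patches(
    images,
    patch_side: int,
    n: int,
    seed: int | np.random.Generator | None = None,
    subtract_mean: bool = True,
) -> np.ndarray:
    """Draw ``n`` patches at uniformly random positions from a set of images.

    Returns an array of shape (n, patch_side, patch_side); per-patch mean is
    subtracted unless disabled.  Reproducible given ``seed``.
    """
    rng = np.random.default_rng(seed)
    images = [np.asarray(im, dtype=float) for im in images]
    for im in images:
        if im.shape[0] < patch_side or im.shape[1] < patch_side:
            raise ValueError(
                f"image {im.shape} smaller than patch side {patch_side}"
            )
    out = np.empty((n, patch_side, patch_side))
    for i in range(n):
        im = images[rng.integers(len(images))]
        r = rng.integers(im.shape[0] - patch_side + 1)
        c = rng.integers(im.shape[1] - patch_side + 1)
        out[i] = im[r : r + patch_side, c : c + patch_side]
    if subtract_mean and n:
        out -= out.mean(axis=(1, 2), keepdims=True)
    return out


def _encode_batch(phi: np.ndarray, patches: np.ndarray, lam: float) -> np.ndarray:
    """Signed ℓ1 inference (coordinate descent) for the learning loop.

    Minimizes ``1/2||x - Phi a||^2 + lam * ||a||_1`` per patch; returns codes
    of shape (n_patches, M).  (``sparse_encode`` applies its own 1/n_features
    scaling internally, so ``alpha=lam`` realizes this energy exactly.)
    """
    return sparse_encode(
        patches.reshape(patches.shape[0], -1),
        phi.T,
        algorithm="lasso_cd",
        alpha=lam,
        max_iter=2000,
    )


def learn_dictionary(
    patches: np.ndarray,
    m: int,
    lam: float = 0.1,
    epochs: int = 20,
    lr: float = 1.0,
    lr_decay: float = 0.5,
    lr_decay_every: int = 10,
    batch_size: int = 100,
    seed: int | None = 0,
    inner_passes: int = 3,
) -> Dictionary:
    """Learn a sparse-coding dictionary by alternating ℓ1 inference with a
    gain-adapted gradient step on the reconstruction error.

    Per minibatch: codes ``A`` solve the ℓ1-penalized least-squares problem
    (coordinate descent), then each element takes the gradient step

        phi_j += lr * g_j * (X - Phi A) a_j^T,    g_j = 1 / sum_i a_j(i)^2,

    applied element-by-element for ``inner_passes`` sweeps.  The per-element
    gain ``g_j`` equalizes the update across elements with unequal
    coefficient energy (heavily used elements take proportionally smaller
    steps), which keeps usage balanced; unused elements are re-seeded from
    the worst-reconstructed patch of the batch, and every element is
    renormalized to unit energy.  Elements are initialized from random
    training patches.  The mean per-patch energy is logged per epoch as
    ``training_loss`` (attached to the returned Dictionary).

    Raises
    ------
    FloatingPointError
        If the training loss diverges to a non-finite value.
    """
    if m < 1:
        raise ValueError("m must be >= 1")
    patches = np.asarray(patches, dtype=float)
    if patches.ndim != 3 or patches.shape[0] == 0:
        raise ValueError("patches must be a non-empty (n, P, P) array")
    n, p, _ = patches.shape
    rng = np.random.default_rng(seed)
    X = patches.reshape(n, -1).T  # (pixels, n)
    init = rng.choice(n, size=m, replace=m > n)
    phi = X[:, init] + 1e-6 * rng.standard_normal((p * p, m))
    norms = np.linalg.norm(phi, axis=0)
    norms[norms == 0] = 1.0
    phi = phi / norms
    losses = []
    for epoch in range(epochs):
        step = lr * (lr_decay ** (epoch // lr_decay_every))
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, batch_size):
            idx = order[start : start + batch_size]
            Xb = X[:, idx]
            A = _encode_batch(phi, Xb.T.reshape(len(idx), p, p), lam).T  # (m, B)
            resid = Xb - phi @ A
            epoch_loss += 0.5 * float(np.sum(resid**2)) + lam * float(
                np.sum(np.abs(A))
            )
            AAt = A @ A.T
            B = Xb @ A.T
            for _ in range(inner_passes):
                for j in range(m):
                    gain = AAt[j, j]
                    if gain < 1e-12:
                        continue
                    phi[:, j] += (step / gain) * (B[:, j] - phi @ AAt[:, j])
                    nj = np.linalg.norm(phi[:, j])
                    if nj > 0:
                        phi[:, j] /= nj
            dead = np.diag(AAt) < 1e-12
            if dead.any():
                worst = np.argsort(-np.sum(resid**2, axis=0))
                for slot, j in enumerate(np.where(dead)[0]):
                    col = Xb[:, worst[slot % len(idx)]]
                    nc = np.linalg.norm(col)
                    if nc > 0:
                        phi[:, j] = col / nc
        mean_loss = epoch_loss / n
        if not np.isfinite(mean_loss):
            raise FloatingPointError(
                f"dictionary learning diverged at epoch {epoch} "
                f"(loss={mean_loss})"
            )
        losses.append(mean_loss)
    d = Dictionary(elements=phi.T.reshape(m, p, p))
    d.training_loss = np.asarray(losses)
    return d


def mirror(dictionary: Dictionary) -> Dictionary:
    """Extend the dictionary with the negation of every element."""
    if dictionary.mirrored:
        raise ValueError("dictionary is already mirrored")
    return Dictionary(
        elements=dictionary.elements.copy(),
        mirrored=True,
        meta=default_meta(dictionary.elements, mirrored=True),
    )


def select_localized(
    dictionary: Dictionary,
    energy_fraction: float = 0.9,
    window: int | None = None,
) -> np.ndarray:
    """Indices of effective units whose squared-amplitude mass inside the
    central ``window`` × ``window`` box exceeds ``energy_fraction``.

    Deterministic and idempotent; with a mirrored dictionary both members of
    a well-localized pair are returned.
    """
    p = dictionary.patch_side
    if window is None:
        window = int(round(p * 0.75))
    if window > p:
        raise ValueError(f"window {window} exceeds patch side {p}")
    lo = (p - window) // 2
    hi = lo + window
    el = dictionary.elements
    total = np.sum(el**2, axis=(1, 2))
    inner = np.sum(el[:, lo:hi, lo:hi] ** 2, axis=(1, 2))
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(total > 0, inner / np.where(total > 0, total, 1.0), 0.0)
    learned_sel = np.where(frac >= energy_fraction)[0]
    if dictionary.mirrored:
        return np.concatenate([learned_sel, learned_sel + dictionary.n_learned])
    return learned_sel


def element_orientation_tuning(
    element: np.ndarray,
    orientations=None,
    spatial_freqs=(0.5, 1.0, 1.5, 2.0, 2.5, 3.0),
    n_phases: int = 8,
):
    """Linear orientation tuning of one dictionary element.

    Probes the element with full-field gratings: at each orientation the
    response is the maximum inner product over phase at the element's
    optimal spatial frequency (the SF maximizing the response at the best
    orientation).  This is the filter-level (no network) characterization
    used to classify learned elements as oriented vs blob-like.
    Returns a ``metrics.TuningCurve``.
    """
    from .metrics import TuningCurve
    from .stimuli import StimulusSpec, render

    el = np.asarray(element, dtype=float)
    p = el.shape[0]
    if orientations is None:
        orientations = np.arange(0.0, 180.0, 5.0)
    phases = np.arange(n_phases) * 2 * np.pi / n_phases
    center = ((p - 1) / 2.0, (p - 1) / 2.0)
    resp = np.empty((len(orientations), len(spatial_freqs)))
    x = el.ravel()
    for i, ori in enumerate(orientations):
        for j, sf in enumerate(spatial_freqs):
            best = -np.inf
            for ph in phases:
                g = render(
                    StimulusSpec(
                        center=center, size=4 * p, orientation=float(ori),
                        spatial_freq=sf, phase=float(ph), contrast=1.0,
                    ),
                    p,
                )
                best = max(best, float((g - g.mean()).ravel() @ x))
            resp[i, j] = best
    sf_idx = np.unravel_index(np.argmax(resp), resp.shape)[1]
    return TuningCurve(
        "orientation",
        np.asarray(orientations, dtype=float),
        resp[:, sf_idx],
        statistic="linear",
        condition={"spatial_freq": spatial_freqs[sf_idx]},
    )


# re-export whitening surface at the dictionary-module level (it is part of
# the CRF-building pipeline)
__all__ += [
    "WhiteningFilter",
    "build_whitening_filter",
    "whiten",
    "element_orientation_tuning",
]
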