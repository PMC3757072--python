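"""Top-level modelling interface.

:class:`SparseCoding` is the model object: patch data plus the
hyperparameters of the sparse-coding objective.  ``fit()`` learns the
dictionary and returns a :class:`SparseCodingResults` carrying the mirrored
dictionary, the training-loss trace, and a ``summary()`` table;
``results.encode`` runs the LCA dynamical system on new inputs and
``results.virtual_physiology()`` opens an electrophysiology session on the
fitted population.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import dictionary as dict_mod
from .dictionary import Dictionary, learn_dictionary, sample_patches
from .experiments import VirtualPhysiology
from .lca import LCAParams, lca_encode_static
from .whitening import build_whitening_filter, whiten

__all__ = ["SparseCoding", "SparseCodingResults"]


class SparseCoding:
    """Sparse-coding model of a patch ensemble.

    Parameters
    ----------
    patches : ndarray, shape (n, P, P)
        Training patches (whitened images sampled into patches).
    n_elements : int
        Number of learned dictionary elements (before mirroring).
    lam_train : float
        ℓ1 weight used during dictionary learning.
    """

    def __init__(self, patches: np.ndarray, n_elements: int, lam_train: float = 0.1):
        self.patches = np.asarray(patches, dtype=float)
        if self.patches.ndim != 3:
            raise ValueError("patches must have shape (n, P, P)")
        self.n_elements = int(n_elements)
        self.lam_train = float(lam_train)

    @classmethod
    def from_images(
        cls,
        images,
        patch_side: int = 16,
        n_patches: int = 5000,
        n_elements: int = 512,
        lam_train: float = 0.1,
        whiten_images: bool = True,
        seed: int | None = 0,
    ) -> "SparseCoding":
        """Build the model from full images: whiten, then sample patches."""
        images = [np.asarray(im, dtype=float) for im in images]
        if whiten_images:
            out = []
            for im in images:
                filt = build_whitening_filter(im.shape[0])
                z = whiten(filt, im)
                sd = z.std()
                # unit-variance convention so lam_train is data-scale free
                out.append(z / sd if sd > 0 else z)
            images = out
        patches = sample_patches(images, patch_side, n_patches, seed=seed)
        return cls(patches, n_elements=n_elements, lam_train=lam_train)

    def fit(
        self,
        epochs: int = 20,
        lr: float = 0.1,
        seed: int | None = 0,
        params: LCAParams | None = None,
        **learn_kwargs,
    ) -> "SparseCodingResults":
        learned = learn_dictionary(
            self.patches,
            m=self.n_elements,
            lam=self.lam_train,
            epochs=epochs,
            lr=lr,
            seed=seed,
            **learn_kwargs,
        )
        loss = learned.training_loss
        mirrored = learned.mirror()
        return SparseCodingResults(
            model=self,
            dictionary=mirrored,
            training_loss=loss,
            params=params or LCAParams(),
        )


class SparseCodingResults:
    """Fitted sparse-coding population.

    Attributes
    ----------
    dictionary : Dictionary
        The mirrored dictionary (learned elements and their negations).
    training_loss : ndarray
        Mean per-patch energy per learning epoch.
    params : LCAParams
        The global dynamical-system parameters used for inference.
    """

    def __init__(self, model, dictionary: Dictionary, training_loss, params):
        self.model = model
        self.dictionary = dictionary
        self.training_loss = np.asarray(training_loss, dtype=float)
        self.params = params

    @classmethod
    def from_dictionary(
        cls, dictionary: Dictionary, params: LCAParams | None = None
    ) -> "SparseCodingResults":
        """Wrap an existing (e.g. fixture) dictionary as a fitted result."""
        if not dictionary.mirrored:
            dictionary = dictionary.mirror()
        return cls(
            model=None,
            dictionary=dictionary,
            training_loss=np.array([]),
            params=params or LCAParams(),
        )

    def encode(self, x: np.ndarray, **kwargs):
        """Run the LCA dynamical system to steady state on one patch."""
        return lca_encode_static(self.dictionary, x, self.params, **kwargs)

    def select_localized(self, energy_fraction: float = 0.9, window: int | None = None):
        return self.dictionary.select_localized(energy_fraction, window)

    def virtual_physiology(self, **kwargs) -> VirtualPhysiology:
        return VirtualPhysiology(self.dictionary, params=self.params, **kwargs)

    def summary(self) -> str:
        """Plain-text summary of the fitted population."""
        d = self.dictionary
        lines = [
            "Sparse coding population (LCA dynamical system)",
            "=" * 48,
            f"patch side:           {d.patch_side} px",
            f"learned elements:     {d.n_learned}",
            f"effective elements:   {d.effective_count} (mirrored)",
            f"overcompleteness:     {d.effective_count / d.patch_side**2:.2f}x",
            f"lambda (inference):   {self.params.lam:g}",
            f"tau / dt:             {self.params.tau:g} ms / {self.params.dt:.3g} ms",
            f"steps per frame:      {self.params.steps_per_frame}",
            f"static steps:         {self.params.static_steps}",
        ]
        if self.training_loss.size:
            lines += [
                f"training epochs:      {self.training_loss.size}",
                f"final training loss:  {self.training_loss[-1]:.4f} "
                f"(from {self.training_loss[0]:.4f})",
            ]
        n_loc = len(self.select_localized())
        lines.append(f"well-localized units: {n_loc}")
        return "\n".join(lines)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"<SparseCodingResults: {self.dictionary.effective_count} effective "
            f"units, lam={self.params.lam:g}>"
        )
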