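"""Locally Competitive Algorithm (LCA): sparse coding as a dynamical system.

A population of units with membrane potentials ``u`` and rates
``a = T_lam(u)`` evolves under

    tau * du/dt = -u + Phi^T x - (Phi^T Phi - I) a,

where ``Phi`` is the dictionary matrix (one unit-norm receptive field per
column) and ``T_lam`` is the soft-thresholding function.  The thresholded
steady state minimizes the sparse-coding energy

    E(a) = 1/2 ||x - Phi a||^2 + lam * sum_i |a_i|.

With the nonnegative convention (mirrored dictionary containing each element
and its negation), rates are interpretable as firing rates and the recurrent
interaction between units i and j is inhibitory when <phi_i, phi_j> > 0 and
excitatory when it is negative.

The integrator is a first-order Euler scheme.  Static stimuli are run for a
fixed number of steps (optionally stopping early once the state is
numerically stationary); movies are integrated continuously across frames
with no state reset, a fixed number of Euler steps per frame.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "LCAParams",
    "LCAState",
    "DriveDecomposition",
    "soft_threshold",
    "lca_encode_static",
    "lca_encode_batch",
    "lca_encode_movie",
    "energy",
    "decompose_drives",
]


@dataclass(frozen=True)
class LCAParams:
    """Global parameter set of the dynamical system, fixed across protocols.

    Parameters
    ----------
    lam : float
        Sparsity tradeoff λ (> 0): threshold of the rate nonlinearity and
        weight of the ℓ1 penalty.
    tau : float
        Membrane time constant in ms (physiological range 10–100 ms).
    dt : float
        Euler integration step in ms; must satisfy ``0 < dt < tau``.
    steps_per_frame : int
        Euler steps per movie frame (25 steps ≈ a 1/30 s frame).
    static_steps : int
        Steps used for static-stimulus convergence runs.
    strict : bool
        If True, ``tau/2 <= dt < tau`` raises instead of warning.
    """

    lam: float = 0.1
    tau: float = 10.0
    dt: float = 10.0 / 7.5
    steps_per_frame: int = 25
    static_steps: int = 1000
    strict: bool = False

    def __post_init__(self) -> None:
        if self.lam <= 0:
            raise ValueError(f"lam must be > 0, got {self.lam}")
        if self.dt <= 0:
            raise ValueError(f"dt must be > 0, got {self.dt}")
        if self.dt >= self.tau:
            raise ValueError(
                f"dt={self.dt} >= tau={self.tau}: Euler integration unstable"
            )
        if self.dt >= self.tau / 2:
            msg = f"dt={self.dt} is within a factor 2 of tau={self.tau}"
            if self.strict:
                raise ValueError(msg)
            warnings.warn(msg, stacklevel=2)
        if self.steps_per_frame < 1:
            raise ValueError("steps_per_frame must be >= 1")
        if self.static_steps < self.steps_per_frame:
            raise ValueError("static_steps must be >= steps_per_frame")

    def replace(self, **kwargs) -> "LCAParams":
        from dataclasses import replace

        return replace(self, **kwargs)


@dataclass
class LCAState:
    """Network state: membrane potentials ``u`` and rates ``a = T_lam(u)``."""

    u: np.ndarray
    a: np.ndarray
    n_steps: int = 0


@dataclass
class DriveDecomposition:
    """Steady-state input decomposition for one target unit.

    ``feedforward + excitation - inhibition`` equals the steady-state
    membrane potential of the target (inhibition is reported as a
    nonnegative magnitude).  ``contributors`` lists the significant
    competitors as ``(unit index, signed contribution)``.
    """

    feedforward: float
    excitation: float
    inhibition: float
    contributors: list[tuple[int, float]] = field(default_factory=list)


def soft_threshold(u: np.ndarray | float, lam: float, nonneg: bool = True):
    """Soft-thresholding nonlinearity mapping potentials to rates.

    Signed mode: ``sign(u) * max(|u| - lam, 0)``; nonnegative mode:
    ``max(u - lam, 0)``.
    """
    if lam < 0:
        raise ValueError(f"lam must be >= 0, got {lam}")
    u = np.asarray(u, dtype=float)
    if nonneg:
        return np.maximum(u - lam, 0.0)
    return np.sign(u) * np.maximum(np.abs(u) - lam, 0.0)


def _as_column_input(dictionary, x: np.ndarray) -> np.ndarray:
    """Flatten a patch (or stack of patches) to feedforward drive columns."""
    phi = dictionary.matrix  # (n_pixels, n_effective)
    x = np.asarray(x, dtype=float)
    if x.size != phi.shape[0] and x.shape[-1] * x.shape[-2] != phi.shape[0]:
        raise ValueError(
            f"input with {x.size} values does not match dictionary patch "
            f"geometry ({phi.shape[0]} pixels)"
        )
    return x.reshape(-1)


def lca_encode_static(
    dictionary,
    x: np.ndarray,
    params: LCAParams,
    *,
    tol: float | None = None,
    record: bool = False,
):
    """Integrate the LCA to (approximate) steady state on one static input.

    Parameters
    ----------
    dictionary : Dictionary
        Provides ``matrix`` (pixels × effective elements) and cached ``gram``.
    x : ndarray
        Whitened input patch, ``(P, P)`` or flat.
    params : LCAParams
    tol : float, optional
        If given, stop once ``max|Δu|`` in a step falls below ``tol`` (the
        step cap stays ``params.static_steps``).
    record : bool
        If True, also return the rate trajectory, one row per Euler step.

    Returns
    -------
    LCAState, or (LCAState, ndarray) when ``record`` is True.
    """
    xf = _as_column_input(dictionary, x)
    b = dictionary.matrix.T @ xf
    gram = dictionary.gram
    nonneg = dictionary.mirrored
    rate = params.dt / params.tau
    u = np.zeros_like(b)
    a = soft_threshold(u, params.lam, nonneg)
    traj = np.empty((params.static_steps, b.size)) if record else None
    n = 0
    for step in range(params.static_steps):
        du = rate * (b - u - gram @ a + a)
        u = u + du
        a = soft_threshold(u, params.lam, nonneg)
        if record:
            traj[step] = a
        n = step + 1
        if tol is not None and np.max(np.abs(du)) < tol:
            break
    state = LCAState(u=u, a=a, n_steps=n)
    if record:
        return state, traj[:n]
    return state


def lca_encode_batch(
    dictionary,
    X: np.ndarray,
    params: LCAParams,
    *,
    tol: float | None = None,
    dtype=None,
) -> np.ndarray:
    """Static LCA over a batch of stimuli (columns), vectorized.

    ``X`` has shape (n_pixels, n_stimuli).  Converged columns are frozen once
    their ``max|Δu|`` falls below ``tol``.  Returns the rate matrix
    (n_effective, n_stimuli); numerically equivalent to running
    :func:`lca_encode_static` per column (``dtype=np.float32`` trades ~1e-5
    rate accuracy for speed in large protocol sweeps).
    """
    phi = dictionary.matrix
    if X.shape[0] != phi.shape[0]:
        raise ValueError("stimulus pixel count does not match dictionary")
    b = phi.T @ X
    gram = dictionary.gram
    if dtype is not None:
        b = b.astype(dtype)
        gram = gram.astype(dtype)
    nonneg = dictionary.mirrored
    rate = params.dt / params.tau
    u = np.zeros_like(b)
    active = np.arange(b.shape[1])
    ub = u
    bb = b
    for _ in range(params.static_steps):
        a = soft_threshold(ub, params.lam, nonneg)
        du = rate * (bb - ub - gram @ a + a)
        ub = ub + du
        if tol is not None:
            live = np.max(np.abs(du), axis=0) >= tol
            if not live.all():
                u[:, active] = ub
                active = active[live]
                if active.size == 0:
                    break
                ub = ub[:, live]
                bb = bb[:, live]
    if active.size:
        u[:, active] = ub
    return soft_threshold(u, params.lam, nonneg)


def lca_encode_movie(
    dictionary,
    frames: Sequence[np.ndarray] | np.ndarray,
    params: LCAParams,
    *,
    state: LCAState | None = None,
) -> np.ndarray:
    """Integrate the LCA through a frame sequence, state persisting across
    frame boundaries.

    Each frame drives ``params.steps_per_frame`` Euler steps.  Returns the
    rate trajectory, shape ``(n_frames * steps_per_frame, n_effective)``.
    Frames may be a 3-d array (frame, row, col) or a list of patches.
    """
    frames = list(frames)
    if len(frames) == 0:
        raise ValueError("frame sequence is empty")
    phi = dictionary.matrix
    gram = dictionary.gram
    nonneg = dictionary.mirrored
    rate = params.dt / params.tau
    u = np.zeros(phi.shape[1]) if state is None else state.u.copy()
    traj = np.empty((len(frames) * params.steps_per_frame, phi.shape[1]))
    k = 0
    for frame in frames:
        b = phi.T @ _as_column_input(dictionary, frame)
        for _ in range(params.steps_per_frame):
            a = soft_threshold(u, params.lam, nonneg)
            u = u + rate * (b - u - gram @ a + a)
            traj[k] = soft_threshold(u, params.lam, nonneg)
            k += 1
    return traj


def lca_encode_movie_batch(
    dictionary,
    frame_stack: np.ndarray,
    params: LCAParams,
) -> np.ndarray:
    """Movie LCA over many conditions at once.

    ``frame_stack`` has shape (n_conditions, n_frames, P, P) (or pixels
    flattened).  Each condition starts from the zero state.  Returns rates of
    shape (n_conditions, n_frames * steps_per_frame, n_effective).
    """
    phi = dictionary.matrix
    gram = dictionary.gram
    nonneg = dictionary.mirrored
    rate = params.dt / params.tau
    nc, nf = frame_stack.shape[:2]
    Xf = frame_stack.reshape(nc, nf, -1)
    if Xf.shape[2] != phi.shape[0]:
        raise ValueError("frame pixel count does not match dictionary")
    # precompute feedforward drives: (n_frames, n_eff, n_cond)
    B = np.einsum("pm,cfp->fmc", phi, Xf)
    u = np.zeros((phi.shape[1], nc))
    steps = params.steps_per_frame
    traj = np.empty((nc, nf * steps, phi.shape[1]))
    k = 0
    for f in range(nf):
        b = B[f]
        for _ in range(steps):
            a = soft_threshold(u, params.lam, nonneg)
            u = u + rate * (b - u - gram @ a + a)
            traj[:, k, :] = soft_threshold(u, params.lam, nonneg).T
            k += 1
    return traj


def energy(dictionary, x: np.ndarray, a: np.ndarray, lam: float) -> float:
    """Sparse-coding energy ``1/2 ||x - Phi a||^2 + lam * sum|a|``."""
    xf = _as_column_input(dictionary, x)
    a = np.asarray(a, dtype=float)
    if a.size != dictionary.matrix.shape[1]:
        raise ValueError("rate vector length does not match dictionary")
    resid = xf - dictionary.matrix @ a
    return 0.5 * float(resid @ resid) + lam * float(np.sum(np.abs(a)))


def decompose_drives(
    dictionary,
    x: np.ndarray,
    state: LCAState,
    target: int,
    significance: float = 1e-3,
) -> DriveDecomposition:
    """Split the steady-state input to one unit into feedforward drive,
    recurrent excitation and recurrent inhibition.

    At a fixed point, ``u_t = <phi_t, x> + sum_{j != t} -<phi_t, phi_j> a_j``;
    positive terms are excitatory, negative inhibitory (so a competitor with
    overlapping CRF, ``<phi_t, phi_j> > 0``, inhibits).  The sums run over
    every active competitor; ``significance`` only filters the contributor
    list reported for display.
    """
    n_eff = dictionary.matrix.shape[1]
    if not 0 <= target < n_eff:
        raise IndexError(f"target {target} out of range for {n_eff} units")
    xf = _as_column_input(dictionary, x)
    ff = float(dictionary.matrix[:, target] @ xf)
    overlaps = dictionary.gram[target]
    contrib = -overlaps * state.a
    contrib[target] = 0.0
    active = state.a > 0
    active[target] = False
    exc = float(np.sum(contrib[active & (contrib > 0)]))
    inh = float(-np.sum(contrib[active & (contrib < 0)]))
    listed = np.where((state.a > significance) & (np.arange(n_eff) != target))[0]
    contributors = [(int(j), float(contrib[j])) for j in listed]
    return DriveDecomposition(
        feedforward=ff, excitation=exc, inhibition=inh, contributors=contributors
    )
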