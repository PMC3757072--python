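"""Unit tests for the LCA dynamical system."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.linear_model import Lasso

import sparsev1 as sv
from sparsev1.lca import lca_encode_movie
from tests.conftest import random_mirrored_dictionary


def lasso_oracle(dictionary, x, lam):
    """Independent convex-solver minimizer of the sparse-coding energy."""
    n = dictionary.matrix.shape[0]
    solver = Lasso(
        alpha=lam / n,
        positive=dictionary.mirrored,
        fit_intercept=False,
        max_iter=200000,
        tol=1e-14,
    )
    solver.fit(dictionary.matrix, np.asarray(x, float).ravel())
    return solver.coef_


class TestSoftThreshold:
    @pytest.mark.parametrize(
        "u, lam, nonneg, expected",
        [
            (0.5, 0.1, False, 0.4),
            (-0.5, 0.1, False, -0.4),
            (-0.3, 0.1, True, 0.0),
            (0.05, 0.1, False, 0.0),
            (0.0, 0.0, False, 0.0),
        ],
    )
    def test_piecewise_definition(self, u, lam, nonneg, expected):
        assert sv.soft_threshold(u, lam, nonneg=nonneg) == pytest.approx(expected)

    def test_negative_lam_rejected(self):
        with pytest.raises(ValueError):
            sv.soft_threshold(1.0, -0.1)

    @given(
        u=st.floats(-100, 100, allow_nan=False),
        lam=st.floats(0, 10, allow_nan=False),
    )
    @settings(max_examples=200, deadline=None)
    def test_shrinkage_properties(self, u, lam):
        a = float(sv.soft_threshold(u, lam, nonneg=False))
        assert abs(a) <= abs(u) + 1e-12
        if a != 0:
            assert np.sign(a) == np.sign(u)
            assert abs(a) == pytest.approx(abs(u) - lam, abs=1e-9)
        an = float(sv.soft_threshold(u, lam, nonneg=True))
        assert an >= 0.0


class TestStaticEncoding:
    def test_orthonormal_closed_form(self, rng):
        q, _ = np.linalg.qr(rng.standard_normal((16, 16)))
        d = sv.Dictionary(elements=q.T.reshape(16, 4, 4))
        x = rng.standard_normal((4, 4))
        state = sv.lca_encode_static(d, x, sv.LCAParams(dt=1.0))
        expected = sv.soft_threshold(q.T @ x.ravel(), 0.1, nonneg=False)
        assert np.abs(state.a - expected).max() < 1e-8

    def test_zero_input_zero_rates(self, rng):
        d = random_mirrored_dictionary(rng)
        state = sv.lca_encode_static(d, np.zeros((d.patch_side,) * 2), sv.LCAParams())
        assert np.all(state.a == 0)
        assert np.all(state.u == 0)

    def test_matches_lasso_oracle(self, rng, tight_params):
        for _ in range(10):
            d = random_mirrored_dictionary(rng)
            x = rng.standard_normal((d.patch_side,) * 2)
            state = sv.lca_encode_static(d, x, tight_params, tol=1e-12)
            oracle = lasso_oracle(d, x, tight_params.lam)
            assert np.abs(state.a - oracle).max() < 1e-4

    def test_shape_mismatch_rejected(self, rng):
        d = random_mirrored_dictionary(rng, patch_side=3)
        with pytest.raises(ValueError):
            sv.lca_encode_static(d, np.zeros((5, 5)), sv.LCAParams())

    def test_thresholding_identity_at_final_state(self, rng):
        d = random_mirrored_dictionary(rng)
        x = rng.standard_normal((d.patch_side,) * 2)
        state = sv.lca_encode_static(d, x, sv.LCAParams())
        assert np.allclose(state.a, sv.soft_threshold(state.u, 0.1, nonneg=True))

    def test_batch_matches_single(self, rng):
        from sparsev1.lca import lca_encode_batch

        d = random_mirrored_dictionary(rng, patch_side=3, n_learned=8)
        X = rng.standard_normal((9, 5))
        p = sv.LCAParams()
        A = lca_encode_batch(d, X, p)
        for j in range(5):
            single = sv.lca_encode_static(d, X[:, j], p)
            assert np.abs(A[:, j] - single.a).max() < 1e-12


class TestEnergy:
    def test_zero_code_gives_half_squared_norm(self, rng):
        d = random_mirrored_dictionary(rng)
        x = rng.standard_normal((d.patch_side,) * 2)
        e = sv.energy(d, x, np.zeros(d.effective_count), 0.1)
        assert e == pytest.approx(0.5 * np.sum(x**2))

    def test_steady_state_beats_zero_code(self, rng, tight_params):
        for _ in range(5):
            d = random_mirrored_dictionary(rng)
            x = rng.standard_normal((d.patch_side,) * 2)
            state = sv.lca_encode_static(d, x, tight_params, tol=1e-12)
            e_star = sv.energy(d, x, state.a, tight_params.lam)
            e_zero = sv.energy(d, x, np.zeros_like(state.a), tight_params.lam)
            assert e_star <= e_zero + 1e-12

    def test_tiny_instance_brute_force_grid(self):
        # 2-pixel patch (1x... use 2x2 with two elements); exhaustive grid
        # minimization is the independent oracle for the energy surface.
        els = np.array([[[1.0, 0.0], [0.0, 0.0]], [[0.0, 1.0], [0.0, 0.0]]])
        d = sv.Dictionary(elements=els)
        x = np.array([[0.7, -0.2], [0.0, 0.0]])
        lam = 0.1
        grid = np.linspace(-1.0, 1.0, 401)
        best = min(
            (sv.energy(d, x, np.array([a1, a2]), lam), a1, a2)
            for a1 in grid
            for a2 in grid
        )
        # closed form for an orthonormal pair: soft threshold per coefficient
        a_star = sv.soft_threshold(np.array([0.7, -0.2]), lam, nonneg=False)
        assert best[1] == pytest.approx(a_star[0], abs=0.005)
        assert best[2] == pytest.approx(a_star[1], abs=0.005)
        assert sv.energy(d, x, a_star, lam) <= best[0] + 1e-9

    def test_energy_descent_along_trajectory(self, rng):
        # dt = tau/10: energy evaluated at a(t) must be non-increasing
        p = sv.LCAParams(dt=1.0, tau=10.0, static_steps=2000)
        for _ in range(5):
            d = random_mirrored_dictionary(rng)
            x = rng.standard_normal((d.patch_side,) * 2)
            _, traj = sv.lca_encode_static(d, x, p, record=True)
            energies = np.array([sv.energy(d, x, a, p.lam) for a in traj[::10]])
            assert np.all(np.diff(energies) <= 1e-8)


class TestMirroredPairs:
    def test_exclusivity_at_convergence(self, rng, tight_params):
        for _ in range(5):
            d = random_mirrored_dictionary(rng)
            x = rng.standard_normal((d.patch_side,) * 2)
            state = sv.lca_encode_static(d, x, tight_params, tol=1e-12)
            m = d.n_learned
            both = np.minimum(state.a[:m], state.a[m:])
            assert both.max() <= 1e-6


class TestMovieEncoding:
    def test_constant_movie_converges_to_static(self, rng):
        d = random_mirrored_dictionary(rng, patch_side=3, n_learned=6)
        x = rng.standard_normal((3, 3))
        p = sv.LCAParams(static_steps=1000)
        traj = lca_encode_movie(d, [x] * 40, p)  # 40 frames x 25 steps
        static = sv.lca_encode_static(d, x, p)
        assert np.abs(traj[-1] - static.a).max() < 1e-6

    def test_single_frame_equals_static_integrator(self, rng):
        d = random_mirrored_dictionary(rng, patch_side=3, n_learned=6)
        x = rng.standard_normal((3, 3))
        p = sv.LCAParams(steps_per_frame=25, static_steps=25)
        traj = lca_encode_movie(d, [x], p)
        static = sv.lca_encode_static(d, x, p)
        assert np.abs(traj[-1] - static.a).max() == 0.0

    def test_zero_frames_zero_rates(self, rng):
        d = random_mirrored_dictionary(rng, patch_side=3, n_learned=6)
        traj = lca_encode_movie(d, [np.zeros((3, 3))] * 3, sv.LCAParams())
        assert np.all(traj == 0)

    def test_empty_movie_rejected(self, rng):
        d = random_mirrored_dictionary(rng, patch_side=3, n_learned=6)
        with pytest.raises(ValueError):
            lca_encode_movie(d, [], sv.LCAParams())

    def test_movie_batch_matches_loop(self, rng):
        from sparsev1.lca import lca_encode_movie_batch

        d = random_mirrored_dictionary(rng, patch_side=3, n_learned=6)
        frames = rng.standard_normal((2, 4, 3, 3))
        p = sv.LCAParams()
        batch = lca_encode_movie_batch(d, frames, p)
        for c in range(2):
            loop = lca_encode_movie(d, list(frames[c]), p)
            assert np.abs(batch[c] - loop).max() < 1e-12


class TestDriveDecomposition:
    def _converged(self, d, x):
        return sv.lca_encode_static(
            d, x, sv.LCAParams(dt=2.5, static_steps=200000), tol=1e-13
        )

    def test_components_sum_to_steady_state_potential(self, rng):
        d = random_mirrored_dictionary(rng, patch_side=4, n_learned=10)
        x = rng.standard_normal((4, 4))
        state = self._converged(d, x)
        target = int(np.argmax(state.a))
        dec = sv.decompose_drives(d, x, state, target)
        total = dec.feedforward + dec.excitation - dec.inhibition
        assert total == pytest.approx(state.u[target], abs=1e-6)

    def test_overlapping_active_competitor_is_inhibitory(self):
        # two overlapping same-sign elements: <phi_i, phi_j> > 0 -> the
        # active competitor contributes inhibition to the target
        e1 = np.zeros((2, 2)); e1[0, 0] = 1.0
        e2 = np.full((2, 2), 0.5)
        els = np.stack([e1, e2 / np.linalg.norm(e2)])
        d = sv.Dictionary(elements=els).mirror()
        x = np.full((2, 2), 1.0)
        state = self._converged(d, x)
        assert state.a[1] > 0
        dec = sv.decompose_drives(d, x, state, target=0)
        inhibitory = [c for _, c in dec.contributors if c < 0]
        assert dec.inhibition > 0
        assert len(inhibitory) >= 1

    def test_solo_active_target_sees_only_feedforward(self, rng):
        d = random_mirrored_dictionary(rng, patch_side=3, n_learned=5)
        # drive with a single element's own shape, scaled small enough that
        # only that unit activates
        x = 0.3 * d.elements[0]
        state = self._converged(d, x)
        active = np.where(state.a > 0)[0]
        if len(active) == 1:
            dec = sv.decompose_drives(d, x, state, int(active[0]))
            assert dec.excitation == 0.0
            assert dec.inhibition == 0.0
            assert dec.feedforward == pytest.approx(state.u[active[0]], abs=1e-6)

    def test_target_out_of_range(self, rng):
        d = random_mirrored_dictionary(rng, patch_side=3, n_learned=5)
        x = np.zeros((3, 3))
        state = sv.lca_encode_static(d, x, sv.LCAParams())
        with pytest.raises(IndexError):
            sv.decompose_drives(d, x, state, target=10**4)


class TestParams:
    def test_unstable_step_rejected(self):
        with pytest.raises(ValueError):
            sv.LCAParams(dt=10.0, tau=10.0)

    def test_marginal_step_warns(self):
        with pytest.warns(UserWarning):
            sv.LCAParams(dt=6.0, tau=10.0)

    def test_marginal_step_strict_raises(self):
        with pytest.raises(ValueError):
            sv.LCAParams(dt=6.0, tau=10.0, strict=True)

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"lam": 0.0},
            {"lam": -1.0},
            {"steps_per_frame": 0},
            {"static_steps": 10, "steps_per_frame": 25},
        ],
    )
    def test_invalid_params_rejected(self, kwargs):
        with pytest.raises(ValueError):
            sv.LCAParams(**kwargs)
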