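"""Virtual electrophysiology protocols on small known-ground-truth fixtures."""

import numpy as np
import pytest

import sparsev1 as sv
from sparsev1.experiments import SEARCH_GRID, VirtualPhysiology


@pytest.fixture(scope="module")
def solo_phys():
    """A single Gabor (plus its mirror): no competitors at its own location."""
    d = sv.gabor_dictionary(
        patch_side=16, centers=[(7.5, 7.5)], orientations=[0.0],
        phases=(0.0,), spatial_freqs=(1.5,),
    )
    return VirtualPhysiology(d)


@pytest.fixture(scope="module")
def small_phys():
    """One center, four orientations, two phases: 8 learned / 16 effective."""
    d = sv.gabor_dictionary(
        patch_side=16, centers=[(7.5, 7.5)], orientations=4,
        phases=(0.0, np.pi / 2), spatial_freqs=(1.5,),
    )
    return VirtualPhysiology(d)


class TestOptimalSearch:
    def test_recovers_generating_orientation(self, small_phys):
        meta = small_phys.dictionary.meta
        for unit in (0, 4):  # 0 deg and 90 deg fixture units (phase 0)
            opt = small_phys.find_optimal_grating(unit)
            true_ori = meta.iloc[unit].true_orientation
            dist = abs(opt.orientation - true_ori)
            assert min(dist, 180 - dist) <= 5.0
            assert opt.responsive

    def test_parameters_lie_on_the_search_grid(self, small_phys):
        opt = small_phys.find_optimal_grating(0)
        g = SEARCH_GRID
        assert opt.size in g["size"]
        assert opt.orientation in g["orientation"]
        assert opt.spatial_freq in g["spatial_freq"]
        assert any(np.isclose(opt.phase, g["phase"]))

    def test_optimum_beats_other_grid_points(self, small_phys):
        opt = small_phys.find_optimal_grating(0)
        others = [
            opt.spec(0.3, orientation=45.0),
            opt.spec(0.3, size=2.0),
            opt.spec(0.3, spatial_freq=0.5),
        ]
        r = small_phys.static_responses(others, 0)
        assert np.all(opt.response >= r - 1e-9)

    def test_result_is_cached(self, small_phys):
        a = small_phys.find_optimal_grating(0)
        b = small_phys.find_optimal_grating(0)
        assert a is b

    def test_unresponsive_unit_flagged(self, solo_phys):
        phys = VirtualPhysiology(solo_phys.dictionary)
        opt = phys.find_optimal_grating(0, contrast=0.0)
        assert not opt.responsive


class TestEndStopping:
    def test_collinear_competitors_produce_end_stopping(self, collinear_fixture):
        phys = VirtualPhysiology(collinear_fixture)
        meta = collinear_fixture.meta
        unit = int(
            meta[
                (meta.center_row == 7.5) & (meta.center_col == 7.5)
                & (meta.true_orientation == 0.0) & (meta.true_phase == 0.0)
                & (meta.polarity == 1.0)
            ].index[0]
        )
        curve = phys.end_stopping(unit)
        assert curve.responses[-1] < curve.peak_response

    def test_no_competitors_no_end_stopping(self, solo_phys):
        curve = solo_phys.end_stopping(0)
        # without recurrent inhibition there is no substantial end-stopping:
        # the long-bar response stays at the peak level up to the sub-percent
        # feedforward ripple the whitening filter itself introduces
        assert curve.responses[-1] >= 0.95 * curve.peak_response
        assert np.all(np.diff(curve.responses) >= -0.01 * curve.peak_response)

    def test_zero_contrast_bar_silent(self, solo_phys):
        curve = solo_phys.end_stopping(0, contrast=0.0)
        assert np.all(curve.responses == 0)


class TestDriftingProtocols:
    def test_zero_contrast_f1_is_zero(self, small_phys):
        curves = small_phys.size_tuning(0, contrasts=(0.0,))
        assert np.all(curves[0.0].responses == 0)

    def test_contrast_ordering_at_optimal_size(self, small_phys):
        curves = small_phys.size_tuning(0, contrasts=(0.05, 0.5))
        assert curves[0.5].peak_response >= curves[0.05].peak_response

    def test_orientation_tuning_peaks_at_preferred(self, small_phys):
        curves = small_phys.orientation_tuning(0, contrasts=(0.3,))
        curve = curves[0.3]
        true_ori = small_phys.dictionary.meta.iloc[0].true_orientation
        dist = abs(curve.peak_abscissa % 180.0 - true_ori)
        assert min(dist, 180 - dist) <= 5.0

    def test_orientation_curve_has_180_degree_period(self, small_phys):
        curve = small_phys.orientation_tuning(0, contrasts=(0.3,))[0.3]
        assert curve.abscissa[0] == 0.0 and curve.abscissa[-1] == 180.0
        assert curve.responses[0] == pytest.approx(curve.responses[-1], abs=1e-9)

    def test_contrast_response_monotone_without_surround(self, small_phys):
        curve = small_phys.contrast_response(0, surround_kind="none")
        assert curve.responses[0] == 0.0
        assert np.all(np.diff(curve.responses) >= -1e-9)


class TestSurround:
    def test_zero_surround_contrast_equals_center_alone(self, small_phys):
        opt = small_phys.find_optimal_grating(0)
        _, sur = small_phys.surround_orientation_tuning(0, surround_contrast=0.0)
        center_resp = small_phys.drifting_responses(
            [opt.spec(0.3)], 0, statistic="mean"
        )[0]
        assert np.allclose(sur.responses, center_resp, atol=1e-9)

    def test_offpatch_annulus_equals_center_alone(self, small_phys):
        opt = small_phys.find_optimal_grating(0)
        _, sur = small_phys.surround_orientation_tuning(0, gap=40.0)
        center_resp = small_phys.drifting_responses(
            [opt.spec(0.3)], 0, statistic="mean"
        )[0]
        assert np.allclose(sur.responses, center_resp, atol=1e-9)

    def test_iso_suppresses_more_than_ortho(self, collinear_fixture):
        phys = VirtualPhysiology(collinear_fixture)
        meta = collinear_fixture.meta
        unit = int(
            meta[
                (meta.center_row == 7.5) & (meta.center_col == 7.5)
                & (meta.true_orientation == 0.0) & (meta.true_phase == 0.0)
                & (meta.polarity == 1.0)
            ].index[0]
        )
        opt = phys.find_optimal_grating(unit)
        _, sur = phys.surround_orientation_tuning(unit)
        iso = sur.responses[np.argmin(np.abs(sur.abscissa - opt.orientation))]
        d_ortho = np.abs((sur.abscissa - opt.orientation - 90.0 + 90) % 180 - 90)
        ortho = sur.responses[int(np.argmin(d_ortho))]
        assert iso < ortho


class TestCrossOrientation:
    def test_zero_mask_contrast_identical_to_test_alone(self, small_phys):
        curve = small_phys.cross_orientation(0, mask_contrast=0.0)
        test_alone = small_phys.drifting_responses(
            [small_phys.find_optimal_grating(0).spec(0.3)], 0, statistic="f1"
        )[0]
        assert np.allclose(curve.responses, test_alone, atol=1e-12)

    def test_ortho_mask_suppresses(self, collinear_fixture):
        # the fixture contains ortho-tuned competitors around the target
        phys = VirtualPhysiology(collinear_fixture)
        meta = collinear_fixture.meta
        unit = int(
            meta[
                (meta.center_row == 7.5) & (meta.center_col == 7.5)
                & (meta.true_orientation == 0.0) & (meta.true_phase == 0.0)
                & (meta.polarity == 1.0)
            ].index[0]
        )
        test_r, plaid_r = phys.plaid_vs_test(unit, 0.3)
        assert plaid_r < test_r

    def test_center_stimulus_cache_shared_across_protocols(self, small_phys):
        opt = small_phys.find_optimal_grating(0)
        spec = opt.spec(0.3)
        a = small_phys.drifting_responses([spec], 0, statistic="f1")
        b = small_phys.drifting_responses([spec], 0, statistic="f1")
        assert np.array_equal(a, b)
        key_hits = [k for k in small_phys._frame_cache if k[0] == spec]
        assert len(key_hits) == 1


class TestRunPopulation:
    def test_empty_unit_list(self, small_phys):
        table = small_phys.run_population([])
        assert len(table) == 0

    def test_row_contents_and_determinism(self, small_phys, tmp_path):
        t1 = small_phys.run_population([0])
        # a fresh session must reproduce the identical row
        phys2 = VirtualPhysiology(small_phys.dictionary)
        t2 = phys2.run_population([0])
        for col in ("crf_size", "si_high", "delta_si", "expansion_ratio"):
            assert t1[col].iloc[0] == pytest.approx(t2[col].iloc[0], abs=1e-9)

    def test_checkpoint_resume(self, small_phys, tmp_path):
        t1 = small_phys.run_population([0], checkpoint_dir=tmp_path)
        assert (tmp_path / "unit_0.json").exists()
        t2 = small_phys.run_population([0], checkpoint_dir=tmp_path)
        assert t1["si_high"].iloc[0] == t2["si_high"].iloc[0]
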