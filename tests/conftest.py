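import warnings

import numpy as np
import pytest
from hypothesis import settings

import sparsev1 as sv

warnings.filterwarnings("ignore", message="dt=.*factor 2")

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


def random_mirrored_dictionary(rng, patch_side=None, n_learned=None):
    """A small random unit-norm mirrored dictionary (<=16 px, <=32 eff)."""
    p = int(rng.integers(2, 5)) if patch_side is None else patch_side
    m = int(rng.integers(3, 17)) if n_learned is None else n_learned
    els = rng.standard_normal((m, p, p))
    els /= np.linalg.norm(els.reshape(m, -1), axis=1)[:, None, None]
    return sv.Dictionary(elements=els).mirror()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def tight_params():
    """Converge-to-steady-state settings for oracle comparisons."""
    return sv.LCAParams(dt=2.5, static_steps=100000)


@pytest.fixture(scope="session")
def collinear_fixture():
    """Three collinear horizontal Gabors (plus orthogonal foils): the
    minimal population in which end-stopping and iso-surround competition
    can arise."""
    centers = [(7.5, 3.5), (7.5, 7.5), (7.5, 11.5)]
    return sv.gabor_dictionary(
        patch_side=16, centers=centers, orientations=[0.0, 90.0],
        phases=(0.0, np.pi / 2), spatial_freqs=(1.5,),
    )


@pytest.fixture(scope="session")
def battery_fixture():
    """The desk-scale fixture population: 3x3 center lattice x 8
    orientations x 2 phases (288 effective units)."""
    return sv.gabor_dictionary(patch_side=16, centers=3, orientations=8)


@pytest.fixture(scope="session")
def battery(battery_fixture):
    """Full virtual-electrophysiology battery over 10 recorded fixture
    units (shared across tests; a few minutes of compute)."""
    meta = battery_fixture.meta
    sel = meta[
        (meta.polarity == 1.0)
        & (meta.true_phase == 0.0)
        & (meta.true_orientation.isin([0.0, 45.0, 90.0, 135.0]))
    ]
    sel = sel[
        ((sel.center_row == 7.5) & (sel.center_col == 7.5))
        | ((sel.center_row == 7.5) & (sel.center_col == 3.75))
        | ((sel.center_row == 3.75) & (sel.center_col == 7.5))
    ]
    units = list(sel.index)[:10]
    phys = sv.VirtualPhysiology(battery_fixture)
    table = phys.run_population(units)
    return {"phys": phys, "units": units, "table": table}
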