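import numpy as np
import pytest

from fmriqc.io import Dataset3D, Dataset4D, Mask3D
from fmriqc.synthetic import SimSpec, make_phantom_anat, make_toy_atlas, simulate_epi


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_spec():
    """A fast no-artifact phantom spec for unit tests."""
    return SimSpec(dims=(20, 20, 16), n_volumes=40, rng_seed=7)


@pytest.fixture
def small_phantom(small_spec):
    anat, mask = make_phantom_anat(small_spec)
    epi, truth = simulate_epi(small_spec, anat, mask)
    return {"spec": small_spec, "anat": anat, "mask": mask,
            "epi": epi, "truth": truth}


@pytest.fixture
def small_atlas(small_phantom):
    return make_toy_atlas(small_phantom["mask"], 4,
                          rng_seed=small_phantom["spec"].rng_seed)


def make_4d(values, voxel=(2.0, 2.0, 2.0), tr=2.0, run_lengths=None):
    values = np.asarray(values, dtype=float)
    aff = np.diag(list(voxel) + [1.0])
    return Dataset4D(values, voxel, tr, aff, run_lengths=run_lengths or [])


def make_3d(values, voxel=(2.0, 2.0, 2.0)):
    values = np.asarray(values, dtype=float)
    aff = np.diag(list(voxel) + [1.0])
    return Dataset3D(values, voxel, aff)


def make_mask(values, voxel=(2.0, 2.0, 2.0)):
    aff = np.diag(list(voxel) + [1.0])
    return Mask3D(np.asarray(values).astype(int), voxel, aff)
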