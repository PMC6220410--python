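import numpy as np
import pytest

from gtvnet.phantom import PhantomParams, desk_params, generate_patient
from gtvnet.preprocess import SamplePair


@pytest.fixture(scope="session")
def desk_case():
    """One deterministic desk-scale patient with tumors and confounders."""
    params = desk_params("A")
    params.seed = 7
    return generate_patient(params, "P01", center_id="A")


@pytest.fixture(scope="session")
def desk_case_b():
    params = desk_params("B")
    params.seed = 13
    return generate_patient(params, "P02", center_id="B")


@pytest.fixture()
def rng():
    return np.random.default_rng(123)


@pytest.fixture()
def toy_sample(rng):
    """A 32x32 two-channel sample with a square lesion."""
    ct = rng.random((32, 32))
    pet = rng.random((32, 32))
    mask = np.zeros((32, 32), dtype=np.uint8)
    mask[10:18, 12:20] = 1
    return SamplePair(ct_slice=ct, pet_slice=pet, gold_mask=mask,
                      pixel_spacing_mm=(2.0, 2.0), slice_thickness_mm=4.0,
                      patient_id="T", slice_index=0, is_positive=True)
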