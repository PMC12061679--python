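import numpy as np
import pytest

import ventiqct as vq


@pytest.fixture(scope="session")
def default_phantom():
    """One reference phantom shared across tests: 15% fSAD, 10% emphysema,
    6 mm peak deformation, two hot spots."""
    spec = vq.PhantomSpec(seed=1)
    insp, exp, lobes, truth = vq.make_ct_pair(spec)
    return spec, insp, exp, lobes, truth


@pytest.fixture(scope="session")
def default_spect(default_phantom):
    spec, insp, exp, lobes, truth = default_phantom
    spect = vq.make_spect(spec, truth, lobes)
    return spect, truth


@pytest.fixture(scope="session")
def registered_field(default_phantom):
    """Deformable registration result on the reference phantom."""
    spec, insp, exp, lobes, truth = default_phantom
    return vq.deformable_register_sstvd(exp, insp, lobes)


@pytest.fixture(scope="session")
def pipeline_report():
    """Full pipeline run on the default study conditions."""
    return vq.run_pipeline(vq.PhantomSpec(seed=1))


@pytest.fixture(scope="session")
def cohort_tables():
    return vq.load_tables()


def aligned_tracer(spec, exp, lobes, truth, spect):
    """Align a phantom SPECT volume to the TLC grid using the ground truth."""
    back = vq.AffineTransform(np.eye(3), truth.spect_offset_mm)
    on_exp = vq.resample_affine(spect, exp, back)
    return vq.apply_displacement(on_exp, truth.true_displacement)
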