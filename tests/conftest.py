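import numpy as np
import pytest

from petmtv import (
    LesionSpec,
    PhantomSpec,
    ScanMeta,
    SuvImage,
    make_cohort,
    make_phantom,
)


def make_image(values, spacing=(4.0, 4.0, 2.0), phase="early", subject_id="T01"):
    """Wrap a raw array as a SuvImage with placeholder scan metadata."""
    meta = ScanMeta(
        subject_id=subject_id,
        phase=phase,
        uptake_time_min=60.0,
        injected_activity_Bq=2.0e8,
        body_weight_g=60000.0,
    )
    return SuvImage(values=np.asarray(values, dtype=float), spacing=spacing, meta=meta)


@pytest.fixture
def image_factory():
    return make_image


@pytest.fixture(scope="session")
def clean_phantom():
    """Noise-free, blur-free sphere: every method recovers truth exactly."""
    spec = PhantomSpec(noise_sd=0.0, psf_fwhm_mm=0.0, rng_seed=5)
    lesion = LesionSpec(
        center_mm=(60.0, 120.0, 64.0), radii_mm=(12.0, 12.0, 12.0), suv_early=8.0
    )
    return make_phantom(spec, lesion, subject_id="CLEAN")


@pytest.fixture(scope="session")
def realistic_phantom():
    """Default scanner model: 8.4 mm FWHM blur + SUV noise."""
    spec = PhantomSpec(rng_seed=5)
    lesion = LesionSpec(
        center_mm=(60.0, 120.0, 64.0), radii_mm=(14.0, 12.0, 16.0), suv_early=9.0
    )
    return make_phantom(spec, lesion, subject_id="REAL")


@pytest.fixture(scope="session")
def cohort50():
    """The 50-lesion dual-time-point study cohort used by cohort-level tests."""
    return make_cohort(50, base_seed=11)
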