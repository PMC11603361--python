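import numpy as np
import pytest

from ntatlas.synthetic_data import (
    CohortSimParams,
    PhantomSpec,
    build_synthetic_atlas,
    make_subject_phantom,
    simulate_cohort,
)
from ntatlas.tractography import TrackingParams


@pytest.fixture(scope="session")
def template_phantom():
    return make_subject_phantom(PhantomSpec(), identity=True, subject_id="template")


@pytest.fixture(scope="session")
def small_atlas():
    """5-subject synthetic atlas used throughout the patient-fit tests."""
    return build_synthetic_atlas(
        PhantomSpec(rng_seed=7), n_subjects=5,
        params=TrackingParams(samples_per_seed_voxel=25, rng_seed=7),
    )


@pytest.fixture(scope="session")
def paper_like_cohort(small_atlas):
    """60-patient cohort under the default (logistic) outcome model."""
    return simulate_cohort(CohortSimParams(n_patients=60, rng_seed=11), small_atlas)


@pytest.fixture(scope="session")
def threshold_cohort(small_atlas):
    """500-patient cohort whose QoL flips at a hard 127.4 mm^3 volume threshold."""
    return simulate_cohort(
        CohortSimParams(n_patients=500, volume_threshold_mm3=127.4, rng_seed=5),
        small_atlas,
    )


@pytest.fixture(scope="session")
def null_cohort(small_atlas):
    """500-patient cohort with all outcome effects switched off."""
    params = CohortSimParams(
        n_patients=500, rng_seed=13,
        qol_worse_intercept=np.log(0.15 / 0.85),
        qol_worse_beta_logvol=0.0, qol_worse_beta_ntc=0.0,
        ae_beta_logvol=0.0, ae_beta_ntc=0.0,
    )
    return simulate_cohort(params, small_atlas)
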