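"""Shared fixtures: synthetic cohorts and fitted models built once per session."""

from __future__ import annotations

import numpy as np
import pytest

import plantarmap as pm


@pytest.fixture(scope="session")
def cohort55():
    """A 55-subject aligned synthetic cohort (the default study conditions)."""
    spec = pm.CohortSpec(n_subjects=55, seed=101)
    return pm.generate_cohort(spec, mode="aligned")


@pytest.fixture(scope="session")
def model55(cohort55):
    """Pixel-wise model fitted on the 55-subject cohort.

    The domain is the silhouette of the cohort mean image, standing in for
    the groupwise template (the aligned-mode cohort is already in a common
    frame, so the mean image is the template up to registration jitter).
    """
    mean_img = pm.PressureImage(
        np.mean([im.data for im in cohort55.images], axis=0), (3.0, 3.0), side="left"
    )
    domain = pm.compute_silhouette(mean_img)
    return pm.fit_pixelwise_model(
        cohort55.images, cohort55.demographics_records, domain, template=mean_img
    )


@pytest.fixture(scope="session")
def foot_image():
    """One noise-free synthetic foot image."""
    spec = pm.CohortSpec(n_subjects=2, seed=5, noise_sd_kpa=0.0)
    z = pm.Demographics(age=45, sex=0, weight=75, height=172, shoe_size=41)
    return pm.generate_foot_image(spec.phenotype, z, spec, seed=0)


@pytest.fixture(scope="session")
def noisy_foot_image():
    spec = pm.CohortSpec(n_subjects=2, seed=5)
    z = pm.Demographics(age=45, sex=0, weight=75, height=172, shoe_size=41)
    return pm.generate_foot_image(spec.phenotype, z, spec, seed=3)


def make_video(data: np.ndarray, spacing=(3.0, 3.0), frequency=500.0, side="left"):
    return pm.PressureVideo(
        data=data, spacing=spacing, frequency=frequency, side=side
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
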