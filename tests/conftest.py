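"""Shared fixtures: small synthetic cohorts reused across the suite."""

from __future__ import annotations

import warnings

import numpy as np
import pytest

import normfactor as nf


@pytest.fixture(scope="session")
def small_bundle() -> nf.CohortBundle:
    """~500-voxel cohort with 2+2 planted factors; fast enough for units."""
    spec = nf.CohortSpec(
        n_controls=60,
        n_patients=40,
        grid_shape=(10, 10, 10),
        mask_fraction=0.5,
        k_pos=2,
        k_neg=2,
        noise_sd=0.2,
        seed=3,
    )
    return nf.generate_cohort(spec)


@pytest.fixture(scope="session")
def small_parts(small_bundle) -> tuple[nf.SignedParts, nf.NormativeFit]:
    """Signed deviation matrices of the small cohort's patients."""
    fit = nf.fit_normative(
        small_bundle.control_matrix, small_bundle.covariates("control"), seed=1
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        dev = nf.score_deviations(
            fit, small_bundle.patient_matrix, small_bundle.covariates("patient")
        )
    return nf.split_signed(dev), fit


@pytest.fixture(scope="session")
def planted_lowrank():
    """Exactly low-rank nonnegative D = W0 @ H0, 50 x 300, k = 2."""
    rng = np.random.default_rng(11)
    W0 = rng.gamma(4.0, 0.5, size=(50, 2))
    H0 = np.clip(rng.normal(0.0, 1.0, size=(2, 300)), 0.0, None)
    H0[0, :5] += 1.0  # guarantee no all-zero rows
    H0[1, 5:10] += 1.0
    return W0, H0, W0 @ H0
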