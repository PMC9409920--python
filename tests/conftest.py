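"""Shared fixtures: small phantom cohorts and derived tables.

Everything is generated programmatically and seeded; session scope keeps the
expensive cohort extractions shared across test modules.
"""

from __future__ import annotations

import numpy as np
import pytest

import dtcwt_radiomics as dr


@pytest.fixture(scope="session")
def small_cohort():
    """A 3+3 phantom cohort at the smallest supported grid."""
    cfg = dr.PhantomConfig(
        n_class_pos=3, n_class_neg=3, image_size=64, tumor_radius_range=(8, 12), seed=42
    )
    return dr.generate_cohort(cfg)


@pytest.fixture(scope="session")
def preprocessed_study(small_cohort):
    return dr.preprocess_study(small_cohort[0])


@pytest.fixture(scope="session")
def small_table(small_cohort):
    return dr.extract_cohort_features(small_cohort)


@pytest.fixture(scope="session")
def null_pvalue_pool():
    """p-values pooled over 20 seeded null-phantom cohorts (264 each).

    Shared by the selection-calibration tests: under zero class effects every
    feature's two-sample t-test p-value should be (marginally) uniform.
    """
    pvals = []
    counts = []
    for seed in range(20):
        cfg = dr.PhantomConfig(
            image_size=64,
            tumor_radius_range=(8, 14),
            rim_contrast_delta=0.0,
            texture_amplitude=0.0,
            seed=1000 + seed,
        )
        table = dr.extract_cohort_features(dr.generate_cohort(cfg))
        sel = dr.select_features(table, alpha=0.001)
        pvals.append(sel.stats["p"].to_numpy())
        counts.append(len(sel.selected))
    return np.concatenate(pvals), counts


@pytest.fixture()
def rng():
    return np.random.default_rng(7)
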