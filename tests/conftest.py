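"""Shared fixtures: synthetic cohorts and trained SOMs at two scales.

``small_*`` fixtures (600 genes × 60 samples, 10×10 grid) keep unit tests
fast; the ``reference_*`` fixtures use the package's default cohort
(2,000 genes × 120 samples, 20×20 grid) for recovery and calibration checks.
"""

import numpy as np
import pandas as pd
import pytest

from somportraits import (
    ExpressionMatrix,
    SOMConfig,
    SyntheticConfig,
    generate_cohort,
    preprocess,
    train_som,
)
from somportraits.synthetic import ContaminationSpec, ModuleSpec


def small_config(seed: int = 11, noise_sd: float = 0.3) -> SyntheticConfig:
    return SyntheticConfig(
        n_genes=600,
        n_samples=60,
        modules=(
            ModuleSpec("main-1", 40, {"S1": 1.0, "S4": -1.0}),
            ModuleSpec("main-2", 40, {"S1": -1.0, "S4": 1.0}),
            ModuleSpec("intermediate-A", 30, {"S2": 1.0}),
            ModuleSpec("intermediate-B", 30, {"S3": 1.0}),
        ),
        # contaminated samples in the two strong main classes, as in the
        # motivating outlier scenario
        contamination=ContaminationSpec(n_genes=25, sample_indices=(2, 45), effect=1.5),
        noise_sd=noise_sd,
        seed=seed,
    )


def noiseless_config(seed: int = 21) -> SyntheticConfig:
    """Small noise-free cohort: planted structure is exactly recoverable."""
    return SyntheticConfig(
        n_genes=400,
        n_samples=40,
        modules=(
            ModuleSpec("main-1", 40, {"S1": 1.0, "S4": -1.0}),
            ModuleSpec("main-2", 40, {"S1": -1.0, "S4": 1.0}),
            ModuleSpec("intermediate-A", 30, {"S2": 1.0}),
            ModuleSpec("intermediate-B", 30, {"S3": 1.0}),
        ),
        contamination=None,
        noise_sd=0.0,
        seed=seed,
    )


@pytest.fixture(scope="session")
def small_cohort():
    cfg = small_config()
    matrix, truth = generate_cohort(cfg)
    return cfg, matrix, truth


@pytest.fixture(scope="session")
def small_model(small_cohort):
    _, matrix, _ = small_cohort
    logfc = preprocess(matrix)
    return train_som(logfc, SOMConfig(rows=10, cols=10, seed=3))


@pytest.fixture(scope="session")
def reference_cohort():
    cfg = SyntheticConfig(seed=5)
    matrix, truth = generate_cohort(cfg)
    return cfg, matrix, truth


@pytest.fixture(scope="session")
def reference_model(reference_cohort):
    _, matrix, _ = reference_cohort
    logfc = preprocess(matrix)
    return train_som(logfc, SOMConfig(rows=20, cols=20, seed=5))


@pytest.fixture(scope="session")
def clean_reference_model():
    """Reference-scale cohort without the contamination signature, as after
    outlier correction; used for class-number assessment."""
    cfg = SyntheticConfig(seed=5, contamination=None)
    matrix, _ = generate_cohort(cfg)
    return train_som(preprocess(matrix), SOMConfig(rows=20, cols=20, seed=5))


@pytest.fixture()
def tiny_matrix():
    data = pd.DataFrame(
        [[1.0, 4.0], [2.0, 5.0], [3.0, 6.0]],
        index=["g1", "g2", "g3"],
        columns=["s1", "s2"],
    )
    return ExpressionMatrix(data)
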