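import numpy as np
import pandas as pd
import pytest

from rsmeta.dataset import code_design_matrix
from rsmeta.synthetic import (
    CovariateSpec,
    GeneratorConfig,
    IntRange,
    generate_detection_dataset,
    generate_effect_size_dataset,
)


@pytest.fixture(scope="session")
def toy_binary_frame():
    """6 effects in 2 samples with one binary covariate (oracle toys)."""
    return pd.DataFrame(
        {
            "effect_id": [f"e{i}" for i in range(6)],
            "study_id": "st0",
            "sample_id": ["A"] * 3 + ["B"] * 3,
            "detected": [1, 0, 1, 0, 0, 1],
            "x": ["a", "b", "a", "b", "a", "b"],
        }
    )


@pytest.fixture(scope="session")
def toy_binary_coded(toy_binary_frame):
    return code_design_matrix(toy_binary_frame, {"x": ["a", "b"]}, response="detected")


def detection_config(seed=0, **kw):
    """Two independent binary covariates on the effect level; known β, τ²."""
    defaults = dict(
        n_samples=60,
        effects_per_sample=IntRange(10, 10),
        covariate_spec=[
            CovariateSpec("x1", ["a", "b"], [0.5, 0.5], "effect"),
            CovariateSpec("x2", ["a", "b"], [0.5, 0.5], "effect"),
        ],
        beta={"x1:b": 0.8, "x2:b": -0.5},
        tau2_sample=1.0,
        intercept=0.0,
        multi_study_fraction=0.0,
        seed=seed,
    )
    defaults.update(kw)
    return GeneratorConfig(**defaults)


@pytest.fixture(scope="session")
def small_detection_dataset():
    return generate_detection_dataset(detection_config(seed=42))


@pytest.fixture(scope="session")
def small_magnitude_dataset():
    cfg = GeneratorConfig(
        n_samples=60,
        effects_per_sample=IntRange(3, 8),
        covariate_spec=[CovariateSpec("g", ["a", "b"], [0.5, 0.5], "effect")],
        es_gamma={"g:b": 0.12},
        es_mu=0.30,
        es_tau2_level3=0.029,
        es_tau2_level2=0.019,
        participant_n=IntRange(57, 410),
        multi_study_fraction=0.0,
        seed=7,
    )
    return generate_effect_size_dataset(cfg)
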