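import numpy as np
import pandas as pd
import pytest

from tgfbsig.datatypes import ExpressionMatrix
from tgfbsig.simulate import (
    CellLineSimConfig,
    CohortSimConfig,
    default_cohort_signature,
    generate_cellline_experiment,
    generate_cohort,
)


@pytest.fixture
def tiny_matrix() -> ExpressionMatrix:
    """3 genes x 4 samples, linear scale, hand-pickable values."""
    data = pd.DataFrame(
        {
            "s1": [6.0, 0.5, 1.5],
            "s2": [2.0, 4.0, 0.4],
            "s3": [1.0, 2.0, 3.0],
            "s4": [8.0, 1.0, 2.0],
        },
        index=pd.Index(["GeneA", "GeneB", "GeneC"], name="gene"),
    )
    return ExpressionMatrix(data, scale_tag="linear")


@pytest.fixture(scope="session")
def noiseless_cellline():
    config = CellLineSimConfig(n_genes=400, n_up=40, n_down=25, n_tnf=15,
                               n_synergy=15, noise_sd=0.0, seed=11)
    return generate_cellline_experiment(config)


@pytest.fixture(scope="session")
def cohort_beta1():
    """Simulated 200-sample cohort with a strong latent driver (beta=1)."""
    config = CohortSimConfig(n_samples=200, beta=1.0, noise_sd=0.5, seed=5)
    expr, clin, truth = generate_cohort(config)
    return expr, clin, truth, default_cohort_signature()
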