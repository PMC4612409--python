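import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def template():
    from amplimeth.synthetic import default_template

    return default_template()


@pytest.fixture
def small_matrix():
    """6-sample, 4-gene matrix with one clean increasing and one decreasing
    trend gene, one flat gene and one noisy null."""
    from amplimeth.trends import ExpressionMatrix

    samples = ["N1", "N2", "AD1", "AD2", "CRC1", "CRC2"]
    values = pd.DataFrame(
        {
            "N1": [4.0, 10.0, 5.0, 6.1],
            "N2": [4.2, 9.8, 5.0, 5.9],
            "AD1": [6.0, 8.0, 5.0, 6.2],
            "AD2": [6.2, 7.8, 5.0, 5.8],
            "CRC1": [8.0, 6.0, 5.0, 6.0],
            "CRC2": [8.2, 5.8, 5.0, 6.0],
        },
        index=["up_gene", "down_gene", "flat_gene", "null_gene"],
    )
    ann = pd.DataFrame(
        {"stage": ["normal", "normal", "adenoma", "adenoma", "CRC", "CRC"],
         "context": "biopsy"},
        index=samples,
    )
    return ExpressionMatrix(values, ann)
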