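import numpy as np
import pandas as pd
import pytest

from camwound.expression_matrix import ExpressionMatrix, SampleDesign


@pytest.fixture
def small_matrix():
    """4 probes x 4 samples with two clean sample groups of opposite sign."""
    rng = np.random.default_rng(11)
    base = rng.uniform(50, 150, 40)
    up = base * 4
    data = pd.DataFrame(
        {
            "s1": base + rng.normal(0, 1, 40),
            "s2": base + rng.normal(0, 1, 40),
            "s3": up + rng.normal(0, 1, 40),
            "s4": up + rng.normal(0, 1, 40),
        },
        index=[f"p{i}" for i in range(40)],
    )
    # give the second group an opposite pattern on half the probes
    data.iloc[:20, 2:] = (base[:20] / 4)[:, None] + rng.normal(0, 1, (20, 2))
    return ExpressionMatrix(data.clip(lower=0.1))


@pytest.fixture
def paired_design():
    return SampleDesign(
        pd.DataFrame(
            {
                "sample_id": ["w1", "w2", "w3", "c1", "c2", "c3"],
                "group": ["wound"] * 3 + ["control"] * 3,
                "egg_id": ["e1", "e2", "e3", "e1", "e2", "e3"],
            }
        )
    )
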