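import numpy as np
import pandas as pd
import pytest

from cnvtrn.io_formats import ExpressionMatrix, validate_annotation


@pytest.fixture
def rng():
    return np.random.default_rng(20260924)


@pytest.fixture
def tiny_annotation():
    """Five genes on two chromosomes; G0 and G3 are TFs."""
    return validate_annotation(
        pd.DataFrame(
            {
                "chrom": ["chr1", "chr1", "chr1", "chr2", "chr2"],
                "start": [0, 20000, 40000, 0, 20000],
                "end": [10000, 30000, 50000, 10000, 30000],
                "gene_id": ["G0", "G1", "G2", "G3", "G4"],
                "is_tf": [True, False, False, True, False],
            }
        )
    )


@pytest.fixture
def small_expression(rng):
    values = rng.normal(size=(6, 20))
    return ExpressionMatrix(
        [f"G{i}" for i in range(6)], [f"S{j}" for j in range(20)], values
    )
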