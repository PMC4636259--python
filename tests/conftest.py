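import numpy as np
import pandas as pd
import pytest

from methoutlier.datamodel import (
    ExpressionMatrix,
    MethylationMatrix,
    SampleAnnotation,
)


@pytest.fixture
def small_annotation() -> SampleAnnotation:
    return SampleAnnotation(
        pd.DataFrame(
            {
                "sample_id": ["T1", "T2", "T3", "N1", "N2", "N3", "N4"],
                "patient_id": ["p1", "p2", "p3", "p4", "p5", "p6", "p7"],
                "group": ["tumor"] * 3 + ["normal"] * 4,
                "specimen": ["tissue"] * 7,
                "hpv_copy_number": [600, 0.4, 0, 0, 0, 0, 0],
            }
        )
    )


@pytest.fixture
def small_meth(small_annotation) -> MethylationMatrix:
    rng = np.random.default_rng(7)
    vals = rng.uniform(0, 0.06, size=(3, 7))
    vals[0, 2] = 0.5  # one hypermethylated tumor outlier in geneA
    return MethylationMatrix(
        pd.DataFrame(
            vals,
            index=["geneA", "geneB", "geneC"],
            columns=small_annotation.sample_ids,
        ),
        level="gene",
    )


@pytest.fixture
def small_expr(small_annotation) -> ExpressionMatrix:
    rng = np.random.default_rng(8)
    vals = rng.normal(8.0, 1.0, size=(3, 7))
    return ExpressionMatrix(
        pd.DataFrame(
            vals,
            index=["geneA", "geneB", "geneC"],
            columns=small_annotation.sample_ids,
        )
    )
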