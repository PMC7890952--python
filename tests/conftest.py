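import numpy as np
import pandas as pd
import pytest

from cernanet.fixtures import FixtureSpec, generate
from cernanet.io_harmonize import (
    AnnotationTable,
    ExpressionMatrix,
    InteractionTable,
)


@pytest.fixture
def small_expr():
    return ExpressionMatrix(
        pd.DataFrame(
            [[1.0, 2.0], [3.0, 4.0], [5.0, 6.0]],
            index=pd.Index(["A", "B", "C"], name="gene"),
            columns=["s1", "s2"],
        )
    )


@pytest.fixture
def small_interactions():
    return InteractionTable.from_pairs(
        [("m1", "A"), ("m1", "B"), ("m2", "B"), ("m2", "C"), ("m3", "C")]
    )


@pytest.fixture
def small_annotation():
    return AnnotationTable(
        pd.DataFrame(
            {"biotype": ["protein_coding", "protein_coding", "lincRNA"]},
            index=pd.Index(["A", "B", "C"], name="gene"),
        )
    )


@pytest.fixture(scope="session")
def tiny_fixture():
    """A small end-to-end dataset (kept well below the default spec size)."""
    return generate(
        FixtureSpec(
            n_samples=30,
            n_mirnas=30,
            n_coding=20,
            n_noncoding=6,
            n_planted_triads=5,
            seed=7,
        )
    )


@pytest.fixture
def rng():
    return np.random.default_rng(0)
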