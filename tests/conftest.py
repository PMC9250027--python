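import numpy as np
import pandas as pd
import pytest

from cysttea.io_formats import AnnotationTable, IntensityTable
from cysttea.reference_library import ReferenceLibrary


@pytest.fixture
def small_table() -> IntensityTable:
    """Ten proteins, two samples, one missing cell and one zero."""
    frame = pd.DataFrame(
        {
            "W4": [10.0, 20.0, 0.0, 40.0, 50.0, 60.0, 70.0, 80.0, 90.0, np.nan],
            "W7": [1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0, 8.0, 9.0, 10.0],
        },
        index=pd.Index([f"p{i}" for i in range(10)], name="protein"),
    )
    return IntensityTable(frame)


@pytest.fixture
def ramp_table() -> IntensityTable:
    """100 proteins with intensities 1..100 in one sample."""
    frame = pd.DataFrame(
        {"W7": np.arange(1.0, 101.0)},
        index=pd.Index([f"p{i:03d}" for i in range(1, 101)], name="protein"),
    )
    return IntensityTable(frame)


@pytest.fixture
def liver_annotations() -> AnnotationTable:
    rows = pd.DataFrame(
        [
            ("g1", "liver", "strong", "25-75%"),
            ("g2", "liver", "weak", "25-75%"),
            ("g3", "liver", "strong", ">75%"),
            ("g4", "kidney", "strong", "25-75%"),
        ],
        columns=["gene", "tissue", "level", "fraction"],
    )
    return AnnotationTable(rows)


@pytest.fixture
def toy_library() -> ReferenceLibrary:
    return ReferenceLibrary(
        name="toy",
        tissues={
            "alpha": frozenset({"p1", "p2", "p3"}),
            "beta": frozenset({"p2", "p3", "p4"}),
            "gamma": frozenset({"p5"}),
        },
        provenance={"method": "ihc_annotation", "parameters": {}},
    )
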