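import numpy as np
import pandas as pd
import pytest

from commassembly import AbundanceTable, TaxonomyMap, parse_newick


@pytest.fixture
def tiny_table():
    """3 taxa x 3 samples with easy hand-checkable counts."""
    df = pd.DataFrame(
        {"S1": [3, 1, 0], "S2": [1, 1, 2], "S3": [0, 0, 5]},
        index=["A", "B", "C"],
    )
    return AbundanceTable(df)


@pytest.fixture
def three_tip_tree():
    return parse_newick("(A:1,(B:0.5,C:0.5):0.5);")


@pytest.fixture
def taxonomy():
    return TaxonomyMap(
        {
            "A": ("Bacteria", "Firmicutes", "Bacilli", "Lactobacillales",
                  "Streptococcaceae", "Lactococcus", ""),
            "B": ("Bacteria", "Cyanobacteria", "", "Chloroplast", "", "", ""),
            "C": ("Bacteria", "Proteobacteria", "", "", "Mitochondria", "", ""),
        }
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)
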