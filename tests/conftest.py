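import pandas as pd
import pytest

import divshift as ds


@pytest.fixture
def toy_taxonomy() -> ds.TaxonomyTable:
    """Two genera in one family plus two singleton families; 4 of 7 sampled."""
    frame = pd.DataFrame(
        {
            "species": ["a1", "a2", "a3", "b1", "b2", "c1", "d1"],
            "genus": ["A", "A", "A", "B", "B", "C", "D"],
            "tribe": [pd.NA] * 7,
            "family": ["FA", "FA", "FA", "FA", "FA", "FC", "FD"],
            "clade": ["X"] * 7,
            "sampled": [True, False, False, True, True, True, False],
        }
    )
    return ds.TaxonomyTable(frame)


@pytest.fixture
def toy_tree() -> ds.PhyloTree:
    """Molecular tree holding exactly the sampled species of toy_taxonomy."""
    return ds.parse_newick("((a1,(b1,b2)),c1);")
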