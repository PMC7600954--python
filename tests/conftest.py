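import numpy as np
import pytest

from ratecon.alignment import Alignment
from ratecon.models import SubstitutionModel
from ratecon.synthetic import simulate_dataset
from ratecon.trees import TimeTree


@pytest.fixture(scope="session")
def small_dataset():
    """16-taxon strict-clock data set used by several recovery tests."""
    truth, aln = simulate_dataset(n_tips=16, n_sites=1500, ucld_stdev=0.0,
                                  seed=42)
    return truth, aln


@pytest.fixture()
def toy_tree():
    """((A:1,B:1):1,C:2); with unit branch rates."""
    tree = TimeTree.from_newick("((A:1,B:1):1,C:2);")
    rates = np.ones(tree.n_nodes)
    rates[tree.root] = np.nan
    tree.rates = rates
    return tree


@pytest.fixture()
def toy_alignment():
    return Alignment.from_strings(
        ["A", "B", "C", "D"],
        ["ACGTAC", "ACGTAG", "ACTTAG", "GCTAAG"])


@pytest.fixture()
def jc_model():
    return SubstitutionModel.jc()
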