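import numpy as np
import pytest

import phylorecode as pr


@pytest.fixture
def aa_alphabet():
    return pr.amino_acid_alphabet()


@pytest.fixture
def tiny_alignment(aa_alphabet):
    return pr.Alignment(["t1", "t2"], np.array([list("AC"), list("AC")]),
                        aa_alphabet)


@pytest.fixture
def quartet_tree():
    return pr.Tree.from_newick("((A:0.3,B:0.5):0.2,(C:0.1,D:0.9):0.4);")


@pytest.fixture
def quartet_alignment(aa_alphabet):
    return pr.Alignment(["A", "B", "C", "D"],
                        np.array([list("ARN"), list("RRN"),
                                  list("ARD"), list("A-N")]), aa_alphabet)


@pytest.fixture
def study_model():
    """Small CAT-LG-style generating model, fixed seed."""
    return pr.default_study_model(n_categories=3, rng_seed=7)


@pytest.fixture
def sim_alignment(study_model):
    tree = pr.zone_tree(pr.ZoneTreeSpec(n_taxa=4))
    return pr.simulate_alignment(tree, study_model, 300, rng_seed=5)
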