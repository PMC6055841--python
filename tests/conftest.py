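import numpy as np
import pytest

import divtime as dt


@pytest.fixture(scope="session")
def balanced_quartet() -> dt.TimeTree:
    """Balanced 4-taxon tree: two cherries under the root (age 1)."""
    return dt.TimeTree.from_newick("((A:0.5,B:0.5):0.5,(C:0.6,D:0.6):0.4);")


@pytest.fixture(scope="session")
def quartet_model() -> dt.SubstModel:
    return dt.SubstModel(kappa=2.5, base_freqs=(0.3, 0.2, 0.2, 0.3),
                         gamma_alpha=0.8)


@pytest.fixture(scope="session")
def quartet_data(quartet_model):
    """Simulated quartet with known branch lengths plus a fitted quadratic
    likelihood summary (shared across likelihood tests)."""
    tree = dt.simulate_time_tree(4, 1.0, seed=1)
    rates = np.full(len(tree.branch_nodes()), 0.3)
    b_true = rates * tree.branch_durations()[tree.branch_nodes()]
    aln = dt.simulate_alignment(tree, rates, quartet_model, 5000, seed=3)
    approx = dt.fit_branch_approx(aln, tree, quartet_model)
    return {"tree": tree, "aln": aln, "b_true": b_true, "approx": approx}


@pytest.fixture(scope="session")
def fixture_52():
    """Synthetic 52-calibration table with its host tree."""
    return dt.calibration_fixture_52()
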