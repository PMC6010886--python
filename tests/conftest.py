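"""Shared fixtures: small hand-built trees and simulated datasets."""

import numpy as np
import pytest

import treerates as tr


@pytest.fixture
def newick_file(tmp_path):
    """Write Newick text to a temp file and return its path."""

    def _write(text, name="trees.nwk"):
        path = tmp_path / name
        path.write_text(text)
        return str(path)

    return _write


@pytest.fixture
def three_tip_tree(newick_file):
    return tr.read_newick(newick_file("((A:1,B:1):1,C:2);"))[0]


@pytest.fixture
def four_tip_bt():
    """N=4, ages (3, 2, 1): the Yule workhorse with closed-form MLE 2/9."""
    return tr.BranchingTimes(n=4, ages=np.array([3.0, 2.0, 1.0]))


@pytest.fixture
def simulated_pair():
    """A deterministic pair of birth-death trees of unequal depth."""
    rng = np.random.default_rng(2024)
    bts = [
        tr.simulate_crown_bd_times(
            tr.SimConfig(lam=0.052, mu=0.013, depth=d, min_tips=5), rng=rng
        )
        for d in (100.0, 141.14)
    ]
    return tr.MultiTreeData(bts)
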