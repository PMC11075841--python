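import numpy as np
import pytest

from idr_evosig import PhyloTree, ScoredAlignment, sample_tree
from idr_evosig.config import PipelineConfig


@pytest.fixture
def cherry():
    return PhyloTree.from_newick("(A:1,B:1);")


@pytest.fixture
def three_tip():
    return PhyloTree.from_newick("((A:1,B:1):1,C:2);")


@pytest.fixture
def tree33():
    """33-tip pure-birth tree rescaled to a genus-level phylogram depth."""
    return sample_tree(33, 42).scaled_to_depth(0.5)


@pytest.fixture
def permissive_config():
    """Thresholds suitable for small synthetic fixtures."""
    return PipelineConfig(
        min_nongap_length=5,
        diversity_criteria={"min_segments": 3, "min_clades": 0},
        rng_seed=7,
    )


@pytest.fixture
def toy_gap_alignment():
    return ScoredAlignment("toy", ["s1", "s2", "s3"], ["AC--GT", "ACTTGT", "A---GT"])


def random_tree(rng, n_tips=8):
    return sample_tree(n_tips, int(rng.integers(2**31 - 1)))
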