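import numpy as np
import pytest

from sparsecomp import Phylogeny, simulate_birth_death_tree


def random_tree(seed: int, n_tips: int = 20, death: float = 0.0) -> Phylogeny:
    """Seeded random tree for property tests."""
    return simulate_birth_death_tree(n_tips, birth=1.0, death_nu=death, seed=seed)


@pytest.fixture
def cherry_tree():
    from sparsecomp import read_newick

    return read_newick("((A:1,B:1):1,C:2);")


@pytest.fixture
def four_tip_tree():
    from sparsecomp import read_newick

    return read_newick("((A:1,B:1):1,(C:1,D:1):1);")


def brute_force_brownian(tree) -> np.ndarray:
    """Independent path-sum oracle: sum branch lengths below each pair's MRCA.

    Walks both root-to-tip paths node by node and adds up the lengths of
    the branches they share; no reuse of the package's covariance code.
    """
    lengths = tree.effective_lengths()
    tips = tree.tips()

    def root_path(v):
        path = [v]
        while (p := tree.parent(path[-1])) is not None:
            path.append(p)
        return list(reversed(path))

    n = len(tips)
    V = np.zeros((n, n))
    for i in range(n):
        pi = root_path(tips[i])
        for j in range(n):
            pj = root_path(tips[j])
            shared = 0.0
            for a, b in zip(pi[1:], pj[1:]):  # skip the root, which has no branch
                if a != b:
                    break
                shared += lengths[a]
            V[i, j] = shared
    return V
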