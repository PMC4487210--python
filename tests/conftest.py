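import numpy as np
import pytest

from paleophylo.matrix import Character, DataMatrix
from paleophylo.trees import Tree


@pytest.fixture
def quartet_tree() -> Tree:
    return Tree.from_newick("((A:1,B:1):1,(C:1,D:1):1);")


@pytest.fixture
def binary_quartet_matrix() -> DataMatrix:
    chars = [Character(str(j), tuple("01")) for j in range(4)]
    cells = [
        [{"0"}, {"0"}, {"1"}, {"0"}],
        [{"0"}, {"0"}, {"1"}, {"1"}],
        [{"1"}, {"1"}, {"0"}, {"0"}],
        [{"1"}, {"1"}, {"0"}, {"1"}],
    ]
    return DataMatrix(list("ABCD"), chars, cells)


def random_matrix(
    rng: np.random.Generator,
    n_taxa: int,
    n_chars: int,
    state_counts=(2, 3, 4),
    missing: float = 0.0,
    poly: float = 0.0,
) -> DataMatrix:
    """Random categorical matrix with optional missing/polymorphic cells."""
    taxa = [f"t{i}" for i in range(n_taxa)]
    chars = []
    cells = [[] for _ in taxa]
    for j in range(n_chars):
        k = int(rng.choice(state_counts))
        symbols = tuple(str(s) for s in range(k))
        chars.append(Character(f"c{j}", symbols))
        for i in range(n_taxa):
            u = rng.random()
            if u < missing:
                cells[i].append(None)
            elif u < missing + poly and k > 1:
                size = int(rng.integers(2, k + 1))
                cells[i].append(set(rng.choice(symbols, size, replace=False)))
            else:
                cells[i].append({str(int(rng.integers(k)))})
    return DataMatrix(taxa, chars, cells)


def random_binary_tree(
    rng: np.random.Generator, labels: list[str], mean_len: float = 0.3
) -> Tree:
    from paleophylo.inference import _random_binary_tree

    return _random_binary_tree(labels, rng, mean_len)
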