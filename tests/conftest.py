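import numpy as np
import pytest

from zeascan.alignments import HaplotypeMatrix, PopulationMap, SequenceAlignment


@pytest.fixture
def worked_matrix() -> HaplotypeMatrix:
    """Four haplotypes, three polarized sites: 000 / 100 / 110 / 111."""
    derived = np.array(
        [
            [0, 1, 1, 1],
            [0, 0, 1, 1],
            [0, 0, 0, 1],
        ],
        dtype=np.int8,
    )
    return HaplotypeMatrix(4, np.array([1.0, 2.0, 3.0]), derived)


def render_matrix(matrix: HaplotypeMatrix, length: int,
                  ancestral: str = "A", derived: str = "C",
                  prefix: str = "h") -> SequenceAlignment:
    """Render a binary matrix into an alignment on {ancestral, derived}."""
    assert length >= matrix.num_sites
    seqs = []
    for row in range(matrix.n):
        chars = [ancestral] * length
        for site in range(matrix.num_sites):
            if matrix.derived[site, row]:
                chars[site] = derived
        seqs.append("".join(chars))
    ids = [f"{prefix}{i + 1}" for i in range(matrix.n)]
    return SequenceAlignment(ids, seqs)


@pytest.fixture
def two_pop_map() -> PopulationMap:
    return PopulationMap(
        {
            "h1": "temperate",
            "h2": "temperate",
            "h3": "tropical",
            "h4": "tropical",
            "og": "outgroup",
        },
        frozenset({"og"}),
    )


def matrix_pairwise_mean(matrix: HaplotypeMatrix) -> float:
    """Brute-force mean pairwise difference count (test oracle)."""
    n = matrix.n
    total = 0
    for i in range(n - 1):
        for j in range(i + 1, n):
            total += int(np.sum(matrix.derived[:, i] != matrix.derived[:, j]))
    return total / (n * (n - 1) / 2)
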