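import numpy as np
import pandas as pd
import pytest

from sweepscan.genotypes import GeneticMap, GenotypeMatrix, SubpopAssignment

_CODE = {"A": 0, "H": 1, "B": 2, "-": -1}


def make_matrix(rows: list[str], samples=None, snps=None) -> GenotypeMatrix:
    """Build a GenotypeMatrix from call strings, one per sample.

    ``make_matrix(["AHB-", "AABB"])`` gives 2 samples x 4 SNPs with calls
    coded A/H/B/- as in the TSV dialect.
    """
    n_samples = len(rows)
    n_snps = len(rows[0]) if rows else 0
    calls = np.array([[_CODE[c] for c in row] for row in rows], dtype=np.int8)
    samples = samples or [f"s{i + 1}" for i in range(n_samples)]
    snps = snps or [f"m{j + 1}" for j in range(n_snps)]
    return GenotypeMatrix(samples, snps, calls.reshape(n_samples, n_snps))


def make_map(snps, lgs, cms) -> GeneticMap:
    return GeneticMap(pd.DataFrame({"snp_id": snps, "lg": lgs, "cm": cms}))


@pytest.fixture
def two_pop_assignment():
    def _make(n1: int, n2: int, n_excluded: int = 0) -> SubpopAssignment:
        labels = {}
        for i in range(n1):
            labels[f"s{i + 1}"] = "pop1"
        for i in range(n2):
            labels[f"s{n1 + i + 1}"] = "pop2"
        for i in range(n_excluded):
            labels[f"s{n1 + n2 + i + 1}"] = "excluded"
        return SubpopAssignment(labels)

    return _make


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)
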