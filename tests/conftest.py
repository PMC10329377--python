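"""Shared fixtures: small synthetic datasets and count-table builders."""

import numpy as np
import pandas as pd
import pytest

from trdkit import GenotypeTable, MatingCountTable, make_fixture
from trdkit.mating_model import CELLS, MATINGS


@pytest.fixture(scope="session")
def null_genome():
    """Small all-null genome: 2 chromosomes x 50 SNPs, 60 x 25 half-sibs."""
    return make_fixture("null_genome", seed=11)


@pytest.fixture(scope="session")
def skewed_sire():
    """Constructed dataset where one sire fully explains the distortion."""
    return make_fixture("single_skewed_sire")


@pytest.fixture()
def tiny_gt():
    """4 samples x 3 markers with phase and missingness, built by hand."""
    markers = pd.DataFrame({
        "chrom": ["chr1", "chr1", "chr2"],
        "marker_id": ["m1", "m2", "m3"],
        "pos_bp": [100, 200, 150],
    })
    codes = np.array([[0, 1, 2, -1],
                      [1, 1, 0, 2],
                      [2, 0, 1, 1]], dtype=np.int16)
    hap_a = np.array([[0, 0, 1, -1],
                      [1, 0, 0, 1],
                      [1, 0, 1, 0]], dtype=np.int8)
    hap_b = np.array([[0, 1, 1, -1],
                      [0, 1, 0, 1],
                      [1, 0, 0, 1]], dtype=np.int8)
    phased = np.array([[True, True, True, False],
                       [True, False, True, True],
                       [True, True, False, True]])
    return GenotypeTable(["a", "b", "c", "d"], markers, codes,
                         hap_a, hap_b, phased)


def random_count_table(rng: np.random.Generator,
                       n_max: int = 200) -> MatingCountTable:
    """A random plausible mating-count table for engine cross-checks."""
    cells = {}
    for m in MATINGS:
        n = int(rng.integers(0, n_max))
        if n == 0:
            continue
        probs = rng.dirichlet(np.ones(len(CELLS[m])))
        draws = rng.multinomial(n, probs)
        for o, k in zip(CELLS[m], draws):
            cells[(m, o)] = int(k)
    return MatingCountTable.from_cells(cells)
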