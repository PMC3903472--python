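import numpy as np
import pandas as pd
import pytest

from oncoclade.matrix import AberrationKey, BinaryCharacterMatrix


def make_matrix(entries, taxa=None) -> BinaryCharacterMatrix:
    """Binary character matrix from a 0/1 array with placeholder characters."""
    entries = np.asarray(entries, dtype=np.int8)
    n, m = entries.shape
    if taxa is None:
        taxa = [chr(65 + i) for i in range(n)]
    chars = [AberrationKey("chr1", j * 100, j * 100 + 50, "gain", label=f"c{j}")
             for j in range(m)]
    return BinaryCharacterMatrix(list(taxa), chars, entries)


def random_matrix(rng: np.random.Generator, n_taxa: int, n_chars: int) -> BinaryCharacterMatrix:
    """Random 0/1 matrix with no all-absent characters."""
    while True:
        e = rng.integers(0, 2, size=(n_taxa, n_chars))
        if (e.sum(axis=0) > 0).all():
            return make_matrix(e)


@pytest.fixture
def table1():
    from oncoclade.stats import load_table1
    return load_table1()


@pytest.fixture
def small_cohort():
    from oncoclade.synthetic import CohortConfig, generate_cohort
    return generate_cohort(
        CohortConfig(n_samples=10, seed=11, emit_probe_tracks=False))
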