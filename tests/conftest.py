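import numpy as np
import pandas as pd
import pytest

import frostgs as fg
from frostgs.study import prepare_dataset


@pytest.fixture(scope="session")
def small_pop():
    """A mid-size population with a planted major locus and default traits."""
    cfg = fg.SimConfig(n_lines=160, n_families=100, markers_per_chromosome=20, seed=42)
    return fg.simulate_population(cfg)


@pytest.fixture(scope="session")
def small_dataset(small_pop):
    """Processed genotypes, kinship and BLUEs for both traits."""
    return prepare_dataset(
        small_pop,
        {
            "frost": small_pop.phenotypes["frost_chamber"],
            "winter": [small_pop.phenotypes["winter_a"], small_pop.phenotypes["winter_b"]],
        },
        seed=42,
    )


@pytest.fixture(scope="session")
def complete_geno(small_pop):
    """The same population's complete (pre-missingness) genotype matrix."""
    return fg.GenotypeMatrix(small_pop.truth.complete_codes, small_pop.marker_map)


def make_geno(codes, n_chrom=1):
    """Small helper: wrap a codes array/DataFrame in a GenotypeMatrix."""
    if not isinstance(codes, pd.DataFrame):
        codes = pd.DataFrame(
            codes,
            index=[f"L{i}" for i in range(np.shape(codes)[0])],
            columns=[f"M{j}" for j in range(np.shape(codes)[1])],
        )
    m = codes.shape[1]
    chroms = np.resize(np.arange(1, n_chrom + 1), m) if n_chrom > 1 else np.ones(m, int)
    chroms = np.sort(chroms)
    mp = pd.DataFrame({"chrom": chroms, "pos": np.arange(1, m + 1) * 100}, index=codes.columns)
    return fg.GenotypeMatrix(codes, mp)


@pytest.fixture
def tiny_blues():
    def _make(lines, values, trait="frost"):
        return pd.DataFrame({"line": list(lines), "trait": trait, "blue": np.asarray(values, float)})

    return _make
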