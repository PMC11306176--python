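import numpy as np
import pandas as pd
import pytest

from rohsweep.types import GenotypeMatrix, MarkerMap


def make_map(positions, chromosome=1, alleles=("A", "G")):
    n = len(positions)
    return MarkerMap(
        pd.DataFrame(
            {
                "chromosome": chromosome,
                "position": positions,
                "marker_id": [f"m{i}" for i in range(n)],
                "allele_a": alleles[0],
                "allele_b": alleles[1],
            }
        )
    )


def make_genotypes(calls, positions=None, chromosome=1):
    calls = np.asarray(calls, dtype=np.int8)
    if positions is None:
        positions = (np.arange(calls.shape[1]) + 1) * 10_000
    samples = pd.DataFrame(
        {
            "individual_id": [f"ind{i}" for i in range(calls.shape[0])],
            "population": "TST",
        }
    )
    return GenotypeMatrix(samples, calls, make_map(positions, chromosome))


@pytest.fixture
def small_panel():
    """Neutral 20-individual panel on one 10-Mb chromosome."""
    from rohsweep.synthetic_data import simulate_panel

    return simulate_panel(
        n_ind=20, chromosomes=[(1, 10_000_000)], snp_spacing=50_000, seed=7
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
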