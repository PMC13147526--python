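import numpy as np
import pytest

from poolscan.data import FounderPanel, GeneticMap
from poolscan.neutral import HaplotypePanel, simulate_neutral_haplotypes


@pytest.fixture(scope="session")
def small_panel() -> HaplotypePanel:
    """A reduced-scale neutral panel shared across tests (~2k sites)."""
    return simulate_neutral_haplotypes(
        n=100, L=50_000, N_e=1e6, u=5e-9, r=2e-8, seed=42
    )


@pytest.fixture()
def toy_founder_panel() -> FounderPanel:
    """4 sites x 3 founders, one missing state at the last site."""
    matrix = np.array(
        [
            [0.0, 1.0, 0.0],
            [1.0, 1.0, 0.0],
            [0.0, 0.0, 1.0],
            [1.0, np.nan, 0.0],
        ]
    )
    return FounderPanel(
        founder_ids=["F1", "F2", "F3"],
        chrom=np.array(["chr1"] * 4, dtype=object),
        positions_bp=np.array([100, 200, 300, 400]),
        matrix=matrix,
        ref=np.array(list("ACGT"), dtype=object),
        alt=np.array(list("TGCA"), dtype=object),
    )


@pytest.fixture()
def linear_map() -> GeneticMap:
    return GeneticMap({"chr1": (np.array([0, 1_000_000]), np.array([0.0, 2.0]))})
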