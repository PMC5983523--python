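from __future__ import annotations

import numpy as np
import pytest

from coibarcode import (
    BarcodeDataset,
    BarcodeRecord,
    SimulationConfig,
    simulate,
)
from coibarcode.divergence import DistanceMatrix


def make_dataset(seq_by_id: dict[str, str],
                 taxonomy: dict[str, tuple[str, str, str, str]],
                 codon_offset: int = 0) -> BarcodeDataset:
    """Hand-built dataset for unit tests."""
    records = [
        BarcodeRecord(id=rid, sequence=seq, species=taxonomy[rid][0],
                      genus=taxonomy[rid][1], family=taxonomy[rid][2],
                      order=taxonomy[rid][3], source="synthetic")
        for rid, seq in seq_by_id.items()
    ]
    length = len(next(iter(seq_by_id.values())))
    return BarcodeDataset(records, length, codon_offset)


def matrix_from_percent(ids: list[str],
                        pct: dict[tuple[str, str], float]) -> DistanceMatrix:
    """DistanceMatrix from hand-specified pairwise distances in percent."""
    n = len(ids)
    d = np.zeros((n, n))
    for (a, b), v in pct.items():
        i, j = ids.index(a), ids.index(b)
        d[i, j] = d[j, i] = v / 100.0
    return DistanceMatrix(list(ids), d,
                          np.full((n, n), 655, dtype=int),
                          np.ones((n, n), dtype=bool))


@pytest.fixture(scope="session")
def small_sim():
    """A small, well-separated synthetic dataset shared across tests:
    2 orders x 2 families x 2 genera x 2 species x 3 individuals."""
    return simulate(SimulationConfig(
        n_orders=2, families_per_order=2, genera_per_family=2,
        species_per_genus=2, individuals_per_species=3, seed=20240601))


@pytest.fixture(scope="session")
def small_matrix(small_sim):
    from coibarcode.divergence import distance_matrix
    return distance_matrix(small_sim.dataset)
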