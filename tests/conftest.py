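import numpy as np
import pandas as pd
import pytest

from stresshap.genotypes import GenotypeMatrix, GeoRecord
from stresshap.simulate import SimulationTruth, simulate_dataset


@pytest.fixture
def tiny_geno() -> GenotypeMatrix:
    """4 accessions x 6 markers, handmade."""
    calls = np.array(
        [
            [0, 1, 0, 1, 1, 0],
            [1, 1, 0, 0, 1, 0],
            [0, 0, 1, 1, 0, 1],
            [1, 0, 1, 0, 0, 1],
        ]
    )
    markers = pd.DataFrame(
        {
            "marker_id": [f"m{i}" for i in range(6)],
            "chromosome": ["1", "1", "1", "2", "2", "2"],
            "position": [100, 200, 300, 100, 200, 300],
        }
    )
    return GenotypeMatrix(
        accession_ids=["acc1", "acc2", "acc3", "acc4"],
        markers=markers,
        calls=calls,
    )


@pytest.fixture
def tiny_geo(tiny_geno) -> list[GeoRecord]:
    return [
        GeoRecord("acc1", 30.0, 0.0, 100.0),    # on the latitude bound
        GeoRecord("acc2", 45.0, 10.0, 500.0),
        GeoRecord("acc3", 29.9, 5.0, 300.0),    # below latitude bound
        GeoRecord("acc4", 50.0, 60.0, 100.0),   # east of longitude bound
    ]


@pytest.fixture(scope="session")
def small_sim():
    """Shared small simulated panel (60 accessions, ~400 markers)."""
    truth = SimulationTruth(
        seed=7, n_accessions=60, n_markers=400,
        exp1_blocks=4, exp1_racks=3, exp1_shelves=2, exp1_reps=2,
        exp2_trays_per_block=10, exp2_dropout=0.0,
    )
    return simulate_dataset(truth)
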