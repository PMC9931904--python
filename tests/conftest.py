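from pathlib import Path

import numpy as np
import pandas as pd
import pytest

from riqtl.io import GenotypeMatrix
from riqtl.simulate import SimConfig, simulate_genotypes

DATA_DIR = Path(__file__).parent / "data"


@pytest.fixture(scope="session")
def candidate_flags() -> pd.DataFrame:
    """Published 21-gene candidate table: per-criterion flags + printed totals."""
    return pd.read_csv(
        DATA_DIR / "candidate_flags.csv", dtype={"gene_id": str, "chromosome": str}
    )


@pytest.fixture
def tiny_genotypes() -> GenotypeMatrix:
    """4 strains x 3 markers, written out by hand for arithmetic oracles."""
    calls = np.array(
        [
            ["B", "B", "D"],
            ["B", "D", "D"],
            ["D", "B", "B"],
            ["D", "D", "B"],
        ],
        dtype="<U1",
    )
    return GenotypeMatrix(
        strain_ids=["s1", "s2", "s3", "s4"],
        marker_ids=["m1", "m2", "m3"],
        chromosome=np.array(["1", "1", "2"]),
        position_mb=np.array([10.0, 20.0, 5.0]),
        calls=calls,
    )


@pytest.fixture(scope="session")
def small_panel() -> GenotypeMatrix:
    """Deterministic 60-strain, 2x150-marker RI panel for scan-level tests."""
    cfg = SimConfig(
        n_strains=60,
        n_chromosomes=2,
        markers_per_chromosome=150,
        n_genes=1,
        seed=11,
    )
    return simulate_genotypes(cfg)
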