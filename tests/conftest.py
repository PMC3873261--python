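import numpy as np
import pandas as pd
import pytest

from allelemap.core_io import GeneticMap, GenotypePanel, PhenotypeTable
from allelemap.synthetic_data import SimulationConfig, default_qtls, simulate_panel


def make_panel(calls, positions=None, chromosomes=None, accession_ids=None,
               marker_ids=None):
    """Small panel builder for hand-constructed fixtures."""
    calls = np.asarray(calls, dtype=np.int16)
    n, m = calls.shape
    accession_ids = accession_ids or [f"A{i + 1}" for i in range(n)]
    marker_ids = marker_ids or [f"M{j + 1}" for j in range(m)]
    gmap = None
    if positions is not None:
        chromosomes = chromosomes or ["1"] * m
        gmap = GeneticMap(pd.DataFrame({
            "marker_id": marker_ids,
            "chromosome": chromosomes,
            "position_cM": [float(p) for p in positions],
        }))
    return GenotypePanel(accession_ids, marker_ids, calls, gmap)


def make_pheno(records):
    """records: iterable of (accession, env, rep, trait, value)."""
    return PhenotypeTable(pd.DataFrame(records, columns=PhenotypeTable.COLUMNS))


@pytest.fixture(scope="session")
def sim_result():
    """One moderately sized structured panel shared across tests."""
    cfg = SimulationConfig(
        n_accessions=200, n_loci=60, n_chromosomes=10, chrom_length_cM=100,
        seed=42, qtl_spec=default_qtls(60),
    )
    return cfg, simulate_panel(cfg)
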