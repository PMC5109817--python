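import numpy as np
import pytest

from germcore import GenotypeMatrix, SimulationConfig, simulate_collection


def make_genotypes(rows: dict[str, list], marker_ids=None) -> GenotypeMatrix:
    """Build a GenotypeMatrix from {accession: [call, ...]} with calls as
    'A/B' strings or None."""
    accs = list(rows)
    n_markers = len(next(iter(rows.values())))
    markers = marker_ids or [f"m{j + 1}" for j in range(n_markers)]
    calls = np.empty((len(accs), n_markers), dtype=object)
    for i, a in enumerate(accs):
        for j, c in enumerate(rows[a]):
            if c is None:
                calls[i, j] = None
            else:
                x, y = c.split("/")
                calls[i, j] = (x, y) if x <= y else (y, x)
    return GenotypeMatrix(accs, markers, calls)


@pytest.fixture(scope="session")
def sim_small():
    """A 200-accession, 4-cluster simulated collection with truth."""
    cfg = SimulationConfig(n_accessions=200, K=4, F_div=0.4, seed=1)
    return simulate_collection(cfg)
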