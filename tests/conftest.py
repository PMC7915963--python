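import numpy as np
import pytest

import venomtx as v
from venomtx.records import Contig


@pytest.fixture(scope="session")
def small_transcriptome():
    """10 transcripts across two families, fixed seed."""
    return v.generate_transcriptome(
        10, {"3FTx": 0.7, "PLA2": 0.3}, mean_length=500, seed=11, species_id="spA"
    )


@pytest.fixture(scope="session")
def small_batch():
    """Two small multiplexed samples with 1% cross-contamination."""
    tsets = [
        v.generate_transcriptome(5, {"3FTx": 0.8, "kunitz": 0.2}, seed=21 + i,
                                 species_id=f"sp{i}")
        for i in range(2)
    ]
    rsets = [
        v.simulate_reads(ts, 3000, 150, 0.01, seed=31 + i)
        for i, ts in enumerate(tsets)
    ]
    return tsets, v.spike_contamination(rsets, 0.01, seed=41)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(7)


def random_contig(rng, n, contig_id="c"):
    return Contig(contig_id, "".join(rng.choice(list("ACGT"), size=n)))
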