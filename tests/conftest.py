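import numpy as np
import pytest
from importlib import resources

from gbskit.cli_io import read_key
from gbskit.demux_tagger import demultiplex_and_count
from gbskit.gbs_simulator import SimSpec, simulate_experiment
from gbskit.restriction_digest import get_enzyme
from gbskit.snp_caller import anchor_tags


@pytest.fixture(scope="session")
def key48():
    with resources.as_file(
        resources.files("gbskit.data").joinpath("barcodes48.tsv")
    ) as p:
        return read_key(p)


@pytest.fixture(scope="session")
def pstI():
    return get_enzyme("PstI")


@pytest.fixture(scope="session")
def small_sim(key48):
    """A shared 48-plex simulation on a 1.6 Mb genome (error-free)."""
    spec = SimSpec(
        chrom_sizes={"chr1": 800_000, "chr2": 800_000},
        mean_site_spacing=2600,
        size_window=(600, 1100),
        n_sites=150,
        fst=0.25,
        inbreeding=0.2,
        maf_range=(0.25, 0.5),
        mean_reads_per_sample=4000,
        cv_reads=0.39,
        error_rate=0.0,
    )
    return simulate_experiment(spec, key48, seed=101)


@pytest.fixture(scope="session")
def small_sim_called(small_sim, key48, pstI):
    """Tag matrix + anchors + demux summary for the shared simulation."""
    matrix, summary = demultiplex_and_count(small_sim.records, key48, pstI)
    aligned = anchor_tags(matrix.tags, small_sim.genome, pstI)
    return matrix, summary, aligned


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
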