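import numpy as np
import pytest

from thoipakit.coevolution import DcaParams
from thoipakit.model import assemble_feature_table
from thoipakit.msa_features import Alignment
from thoipakit.synthetic_fixtures import FixtureSpec, synth_msa, synth_tmd_benchmark


@pytest.fixture(scope="session")
def planted_msa() -> Alignment:
    """MSA with two conserved columns and one strongly coupled pair."""
    spec = FixtureSpec(
        L=20, n_seqs=100, conserved_positions=(3, 7), coupled_pairs=((5, 12, 0.9),),
        seed=1,
    )
    return synth_msa(spec)


@pytest.fixture(scope="session")
def benchmark():
    """Small labelled multi-TMD benchmark shared across model tests."""
    records, alignments = synth_tmd_benchmark(n_tmds=14, seed=7, n_seqs=60)
    return records, alignments


@pytest.fixture(scope="session")
def benchmark_table(benchmark):
    records, alignments = benchmark
    return assemble_feature_table(records, alignments, DcaParams())


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
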