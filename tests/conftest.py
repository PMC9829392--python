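import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from padlockrca.seq_core import NucSeq, build_kmer_index

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    max_examples=60,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


def random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=n))


@pytest.fixture(scope="session")
def toy_transcriptome():
    """Ten seeded 500-nt transcripts plus their k=15 uniqueness index."""
    rng = np.random.default_rng(42)
    transcripts = [
        (f"tx{i}", NucSeq(random_dna(rng, 500))) for i in range(10)
    ]
    index = build_kmer_index(transcripts, k=15)
    return transcripts, index
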