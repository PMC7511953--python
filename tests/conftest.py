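import numpy as np
import pytest

from ribocompete import TranscriptParams, generate_counts, generate_transcriptome
from ribocompete.te import differential_te


def make_transcript(
    gene_id="g",
    ki=0.1,
    ke=10.0,
    m=1.0,
    L=10,
    n_codons=300,
    charge_profile=None,
):
    return TranscriptParams(
        gene_id=gene_id, ki=ki, ke=ke, m=m, L=L, n_codons=n_codons,
        charge_profile=charge_profile,
    )


def random_transcriptome(rng: np.random.Generator, n_genes: int) -> list[TranscriptParams]:
    """Random valid transcriptome for solver tests (all genes sub-jamming
    for free-ribosome levels up to ~15)."""
    out = []
    for g in range(n_genes):
        out.append(
            TranscriptParams(
                gene_id=f"t{g}",
                ki=float(rng.uniform(0.01, 0.3)),
                ke=float(rng.uniform(5.0, 20.0)),
                m=float(rng.uniform(0.01, 1.0)),
                L=10,
                n_codons=int(rng.integers(100, 600)),
            )
        )
    return out


@pytest.fixture(scope="session")
def default_transcriptome():
    return generate_transcriptome(seed=0)


@pytest.fixture(scope="session")
def default_experiment(default_transcriptome):
    return generate_counts(default_transcriptome, seed=100)


@pytest.fixture(scope="session")
def default_te_result(default_experiment):
    return differential_te(default_experiment, n_perm=2000, seed=0)
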