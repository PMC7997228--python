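import numpy as np
import pytest

from m6apred.sequence_io import (
    LabeledSequenceSet,
    SyntheticConfig,
    generate_synthetic,
    write_fasta,
)

RNA = "ACGU"


def random_rna(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(RNA), size=length))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_seqset() -> LabeledSequenceSet:
    """100 + 100 sequences with a moderate planted bias."""
    return generate_synthetic(
        SyntheticConfig(
            n_pos=100,
            n_neg=100,
            length=41,
            motif_strength=0.6,
            enriched_positions=(14, 16, 24, 26),
            seed=42,
        )
    )


@pytest.fixture
def fasta_pair(tmp_path, small_seqset):
    """(pos_path, neg_path) FASTA files written from the small synthetic set."""
    pos_idx = np.flatnonzero(small_seqset.labels == 1)
    neg_idx = np.flatnonzero(small_seqset.labels == 0)
    pos_path = tmp_path / "pos.fasta"
    neg_path = tmp_path / "neg.fasta"
    write_fasta(small_seqset.subset(pos_idx), pos_path)
    write_fasta(small_seqset.subset(neg_idx), neg_path)
    return pos_path, neg_path
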