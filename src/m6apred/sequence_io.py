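"""Reading, validation, synthesis and fold-splitting of labeled RNA sequence sets.

Sequences are fixed-length windows over the alphabet {A, C, G, U} with the
putative modification site (an adenine) at the central position.  DNA input
(T instead of U) is normalized automatically; ambiguity codes are rejected.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

RNA_ALPHABET = ("A", "C", "G", "U")

__all__ = [
    "RNA_ALPHABET",
    "LabeledSequenceSet",
    "SyntheticConfig",
    "FoldAssignment",
    "read_sample_files",
    "read_labeled_tsv",
    "write_fasta",
    "validate_center",
    "generate_synthetic",
    "stratified_kfold",
]


class SequenceValidationError(ValueError):
    """Raised when input sequences violate the length/alphabet/center contract."""


def _normalize(seq: str) -> str:
    """Uppercase and map DNA thymine to RNA uracil."""
    return seq.upper().replace("T", "U")


def _check_alphabet(seq: str, record_id: str) -> None:
    bad = set(seq) - set(RNA_ALPHABET)
    if bad:
        raise SequenceValidationError(
            f"record '{record_id}' contains characters outside "
            f"{{A,C,G,U,T}}: {sorted(bad)}"
        )


@dataclass
class LabeledSequenceSet:
    """Fixed-length RNA sequences with binary labels (1 = positive class).

    Invariants (enforced in ``__post_init__``): all sequences share one
    length, the alphabet is exactly {A, C, G, U}, labels are 0/1, and ids
    are unique.
    """

    sequences: list[str]
    labels: np.ndarray
    ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if len(self.sequences) != len(self.labels):
            raise SequenceValidationError(
                f"{len(self.sequences)} sequences but {len(self.labels)} labels"
            )
        if not self.ids:
            self.ids = [f"seq_{i}" for i in range(len(self.sequences))]
        if len(self.ids) != len(self.sequences):
            raise SequenceValidationError("ids and sequences differ in length")
        if not set(np.unique(self.labels)) <= {0, 1}:
            raise SequenceValidationError("labels must be binary 0/1")
        lengths = {len(s) for s in self.sequences}
        if len(lengths) > 1:
            raise SequenceValidationError(
                f"sequences have mixed lengths: {sorted(lengths)}"
            )
        for rid, seq in zip(self.ids, self.sequences):
            _check_alphabet(seq, rid)

    @property
    def length(self) -> int:
        """Common sequence length L (0 for an empty set)."""
        return len(self.sequences[0]) if self.sequences else 0

    def __len__(self) -> int:
        return len(self.sequences)

    def subset(self, indices: Sequence[int] | np.ndarray) -> "LabeledSequenceSet":
        idx = np.asarray(indices, dtype=int)
        return LabeledSequenceSet(
            sequences=[self.sequences[i] for i in idx],
            labels=self.labels[idx],
            ids=[self.ids[i] for i in idx],
        )


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of the position-weight synthetic sequence generator.

    With ``motif_strength`` = 0 positives and negatives come from the same
    background distribution; with 1 the ``motif_base`` is deterministic at
    every enriched position of every positive sample.
    """

    n_pos: int = 1000
    n_neg: int = 1000
    length: int = 41
    motif_strength: float = 0.5
    enriched_positions: tuple[int, ...] = ()
    motif_base: str = "G"
    seed: int = 0


@dataclass(frozen=True)
class FoldAssignment:
    """Stratified partition of sample indices into k folds."""

    k: int
    fold_of: np.ndarray  # fold index per sample, values in 0..k-1
    seed: int

    def split(self, fold: int) -> tuple[np.ndarray, np.ndarray]:
        """(train_indices, test_indices) for one held-out fold."""
        test = np.flatnonzero(self.fold_of == fold)
        train = np.flatnonzero(self.fold_of != fold)
        return train, test

    def __iter__(self):
        for f in range(self.k):
            yield self.split(f)


def read_sample_files(
    pos_path: str | Path,
    neg_path: str | Path,
    expected_length: int | None = None,
) -> LabeledSequenceSet:
    """Read paired positive/negative FASTA files into one labeled set.

    Sequences are uppercased, T is mapped to U, positives come first
    (label 1) followed by negatives (label 0), in file order.

    Parameters
    ----------
    pos_path, neg_path
        FASTA files with the positive and negative samples.
    expected_length
        If given, every record must have exactly this length.
    """
    sequences: list[str] = []
    ids: list[str] = []
    labels: list[int] = []
    for path, label in ((Path(pos_path), 1), (Path(neg_path), 0)):
        if not path.exists():
            raise FileNotFoundError(path)
        n_before = len(sequences)
        for record in SeqIO.parse(str(path), "fasta"):
            seq = _normalize(str(record.seq))
            _check_alphabet(seq, record.id)
            if expected_length is not None and len(seq) != expected_length:
                raise SequenceValidationError(
                    f"record '{record.id}' in {path.name} has length "
                    f"{len(seq)}, expected {expected_length}"
                )
            sequences.append(seq)
            ids.append(record.id)
            labels.append(label)
        if len(sequences) == n_before:
            raise SequenceValidationError(f"no FASTA records found in {path}")
    return LabeledSequenceSet(sequences=sequences, labels=np.array(labels), ids=ids)


def read_labeled_tsv(path: str | Path) -> dict[str, int]:
    """Read a two-column (id, label) TSV as an alternative label source."""
    out: dict[str, int] = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        rid, lab = line.split("\t")[:2]
        out[rid] = int(lab)
    return out


def write_fasta(seqset: LabeledSequenceSet, path: str | Path) -> None:
    records = [
        SeqRecord(Seq(seq), id=rid, description="")
        for rid, seq in zip(seqset.ids, seqset.sequences)
    ]
    SeqIO.write(records, str(path), "fasta")


def validate_center(seqset: LabeledSequenceSet) -> LabeledSequenceSet:
    """Check that the central base of every sequence is adenine.

    Requires odd L; the center is position ceil(L/2) 1-based (21 for L=41).
    Returns the set unchanged on success.
    """
    L = seqset.length
    if L % 2 == 0:
        raise SequenceValidationError(f"center validation requires odd length, got L={L}")
    center = L // 2  # 0-based
    offenders = [
        rid
        for rid, seq in zip(seqset.ids, seqset.sequences)
        if seq[center] != "A"
    ]
    if offenders:
        raise SequenceValidationError(
            f"center base (position {center + 1}) is not A in "
            f"{len(offenders)} record(s): {offenders[:10]}"
        )
    return seqset


def generate_synthetic(config: SyntheticConfig) -> LabeledSequenceSet:
    """Generate a balanced synthetic sequence set with planted position biases.

    Background: each non-center position draws uniformly from {A,C,G,U};
    the center is always A.  In positive samples, each enriched position
    draws ``motif_base`` with probability ``0.25 + motif_strength * 0.75``
    (so strength 0 is the null and strength 1 is deterministic) and the
    remaining mass is spread evenly over the other three bases.

    Identical config (including seed) gives byte-identical output.
    """
    if config.n_pos <= 0 or config.n_neg <= 0:
        raise ValueError("n_pos and n_neg must be positive")
    if not 0.0 <= config.motif_strength <= 1.0:
        raise ValueError("motif_strength must be in [0, 1]")
    if config.motif_base not in RNA_ALPHABET:
        raise ValueError(f"motif_base must be one of {RNA_ALPHABET}")
    L = config.length
    center = L // 2 if L % 2 == 1 else None
    for p in config.enriched_positions:
        if not 0 <= p < L:
            raise ValueError(f"enriched position {p} outside sequence (L={L})")

    rng = np.random.default_rng(config.seed)
    base_idx = {b: i for i, b in enumerate(RNA_ALPHABET)}
    p_hit = 0.25 + config.motif_strength * 0.75
    motif_probs = np.full(4, (1.0 - p_hit) / 3.0)
    motif_probs[base_idx[config.motif_base]] = p_hit
    alphabet = np.array(RNA_ALPHABET)

    def draw(n: int, enriched: bool) -> list[str]:
        codes = rng.integers(0, 4, size=(n, L))
        if enriched:
            for j in config.enriched_positions:
                codes[:, j] = rng.choice(4, size=n, p=motif_probs)
        if center is not None:
            codes[:, center] = base_idx["A"]
        return ["".join(row) for row in alphabet[codes]]

    pos = draw(config.n_pos, enriched=True)
    neg = draw(config.n_neg, enriched=False)
    labels = np.concatenate([np.ones(config.n_pos, int), np.zeros(config.n_neg, int)])
    ids = [f"pos_{i}" for i in range(config.n_pos)] + [
        f"neg_{i}" for i in range(config.n_neg)
    ]
    return LabeledSequenceSet(sequences=pos + neg, labels=labels, ids=ids)


def stratified_kfold(
    seqset_or_labels: LabeledSequenceSet | Iterable[int],
    k: int,
    seed: int = 0,
) -> FoldAssignment:
    """Stratified k-fold assignment: per-fold class counts within ±1.

    Indices of each class are put into canonical (sorted) order, shuffled
    with the seeded generator, and dealt round-robin into folds — so the
    assignment is invariant to input order up to relabeling.
    """
    if isinstance(seqset_or_labels, LabeledSequenceSet):
        labels = seqset_or_labels.labels
    else:
        labels = np.asarray(list(seqset_or_labels), dtype=int)
    if k < 2:
        raise ValueError(f"k must be >= 2, got {k}")
    rng = np.random.default_rng(seed)
    fold_of = np.empty(len(labels), dtype=int)
    for cls in np.unique(labels):
        idx = np.sort(np.flatnonzero(labels == cls))
        if len(idx) < k:
            raise ValueError(
                f"class {cls} has {len(idx)} members, fewer than k={k}"
            )
        rng.shuffle(idx)
        fold_of[idx] = np.arange(len(idx)) % k
    return FoldAssignment(k=k, fold_of=fold_of, seed=seed)
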