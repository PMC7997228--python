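"""Eight sequence feature encoders and their fusion into one feature matrix.

Encoders
--------
BE      per-position one-hot (4L)
TNC     overlapping trinucleotide frequencies (64)
ENAC    sliding-window mononucleotide frequencies (4*(L-window+1))
KSNPF   K-spaced ordered nucleotide pair frequencies (16*(K_max+1))
NCP     per-position 3-coordinate chemical-property code (3L)
PseDNC  16 dinucleotide frequencies + lambda tier-correlation terms
PSNP    position-specific nucleotide propensity lookup (L)
PSDP    position-specific dinucleotide propensity lookup (L-1)

PSNP/PSDP are label-dependent: their propensity matrices must be fitted on
training data only (``fit_propensity``) and applied to held-out sequences.

Alphabet order is fixed A, C, G, U (lexicographic for pairs and triples)
in every vector layout, so feature names are reproducible.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from m6apred.sequence_io import RNA_ALPHABET, LabeledSequenceSet

_BASE_IDX = {b: i for i, b in enumerate(RNA_ALPHABET)}
DINUCLEOTIDES = tuple("".join(p) for p in itertools.product(RNA_ALPHABET, repeat=2))
TRINUCLEOTIDES = tuple("".join(p) for p in itertools.product(RNA_ALPHABET, repeat=3))
_DI_IDX = {d: i for i, d in enumerate(DINUCLEOTIDES)}
_TRI_IDX = {t: i for i, t in enumerate(TRINUCLEOTIDES)}

# chemical-property coordinates: (ring structure, functional group, H-bond)
NCP_CODE = {"A": (1, 1, 1), "C": (0, 1, 0), "G": (1, 0, 0), "U": (0, 0, 1)}

CANONICAL_ENCODER_ORDER = ("BE", "KSNPF", "ENAC", "NCP", "PseDNC", "TNC", "PSNP", "PSDP")

__all__ = [
    "FeatureMatrix",
    "PropensityModel",
    "DinucPropertyTable",
    "PseDncParams",
    "KsnpfParams",
    "encode_be",
    "encode_tnc",
    "encode_enac",
    "encode_ksnpf",
    "encode_ncp",
    "encode_psednc",
    "encode_psnp",
    "encode_psdp",
    "fit_propensity",
    "fuse",
    "encode_set",
    "CANONICAL_ENCODER_ORDER",
    "DINUCLEOTIDES",
    "TRINUCLEOTIDES",
]


def _seq_indices(seq: str) -> np.ndarray:
    try:
        return np.array([_BASE_IDX[b] for b in seq], dtype=int)
    except KeyError as exc:
        raise ValueError(f"invalid character {exc.args[0]!r} in sequence") from None


# ---------------------------------------------------------------------------
# container types


@dataclass
class FeatureMatrix:
    """n_samples x d real matrix with per-column names and encoder provenance."""

    values: np.ndarray
    feature_names: list[str]
    encoder_tags: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D (n_samples x d)")
        d = self.values.shape[1]
        if len(self.feature_names) != d or len(self.encoder_tags) != d:
            raise ValueError("feature_names/encoder_tags length must equal column count")
        if len(set(self.feature_names)) != d:
            raise ValueError("feature names must be unique")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature matrix contains non-finite values")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def select_columns(self, indices: Sequence[int] | np.ndarray) -> "FeatureMatrix":
        idx = np.asarray(indices, dtype=int)
        return FeatureMatrix(
            values=self.values[:, idx],
            feature_names=[self.feature_names[i] for i in idx],
            encoder_tags=[self.encoder_tags[i] for i in idx],
        )

    def to_tsv(self, path: str | Path) -> None:
        header = "\t".join(self.feature_names)
        np.savetxt(path, self.values, delimiter="\t", header=header, comments="")


@dataclass
class PropensityModel:
    """Class-conditional position-specific frequency differences.

    ``Z[i, j] = freq_positive(symbol i at position j) - freq_negative(...)``
    with symbols the 4 nucleotides (order 1) or the 16 dinucleotides
    (order 2).  Every column of Z sums to 0 and entries lie in [-1, 1].
    """

    order: int  # 1 = mononucleotide, 2 = dinucleotide
    Z: np.ndarray  # (4, L) or (16, L-1)
    length: int  # sequence length L the model was fitted on

    def __post_init__(self) -> None:
        self.Z = np.asarray(self.Z, dtype=float)
        expected_rows = 4 if self.order == 1 else 16
        if self.order not in (1, 2):
            raise ValueError("order must be 1 or 2")
        if self.Z.shape[0] != expected_rows:
            raise ValueError(
                f"order-{self.order} model needs {expected_rows} rows, got {self.Z.shape[0]}"
            )

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {"order": self.order, "length": self.length, "Z": self.Z.tolist()}
            )
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "PropensityModel":
        obj = json.loads(Path(path).read_text())
        return cls(order=obj["order"], Z=np.array(obj["Z"]), length=obj["length"])


@dataclass
class DinucPropertyTable:
    """Physicochemical index values for the 16 dinucleotides.

    Rows are indices (Rise/Roll/Shift/Slide/Tilt/Twist by default), columns
    the 16 dinucleotides in lexicographic order.  ``standardize`` rescales
    each row to mean 0 / variance 1 over the 16 dinucleotides, the
    convention assumed by the tier-correlation features.
    """

    index_names: list[str]
    values: np.ndarray  # (n_indices, 16)
    standardized: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.index_names), 16):
            raise ValueError("values must be (n_indices, 16)")

    def standardize(self) -> "DinucPropertyTable":
        mu = self.values.mean(axis=1, keepdims=True)
        sd = self.values.std(axis=1, keepdims=True)
        sd[sd == 0] = 1.0
        return DinucPropertyTable(
            index_names=list(self.index_names),
            values=(self.values - mu) / sd,
            standardized=True,
        )

    @classmethod
    def default(cls) -> "DinucPropertyTable":
        """The packaged six-index RNA table, standardized."""
        raw = json.loads(
            resources.files("m6apred.data")
            .joinpath("rna_dinucleotide_indices.json")
            .read_text()
        )
        names = sorted(raw["indices"])
        values = np.array([raw["indices"][n] for n in names])
        return cls(index_names=names, values=values).standardize()


@dataclass(frozen=True)
class PseDncParams:
    """lambda = number of correlation tiers, w = tier weight factor."""

    lam: int = 30
    w: float = 0.5

    def __post_init__(self) -> None:
        if self.lam < 1:
            raise ValueError("lambda must be >= 1")
        if not 0.0 <= self.w <= 1.0:
            raise ValueError("w must be in [0, 1]")


@dataclass(frozen=True)
class KsnpfParams:
    """K_max = largest spacing between the paired nucleotides."""

    k_max: int = 5

    def __post_init__(self) -> None:
        if self.k_max < 0:
            raise ValueError("K_max must be >= 0")


# ---------------------------------------------------------------------------
# stateless encoders


def encode_be(seq: str) -> np.ndarray:
    """Position-major one-hot encoding: A→1000, C→0100, G→0010, U→0001."""
    idx = _seq_indices(seq)
    out = np.zeros((len(seq), 4))
    out[np.arange(len(seq)), idx] = 1.0
    return out.ravel()


def encode_tnc(seq: str) -> np.ndarray:
    """Frequencies of the 64 overlapping trinucleotides; sums to 1."""
    L = len(seq)
    if L < 3:
        raise ValueError(f"TNC needs length >= 3, got {L}")
    out = np.zeros(64)
    for i in range(L - 2):
        out[_TRI_IDX[seq[i : i + 3]]] += 1.0
    return out / (L - 2)


def encode_enac(seq: str, window: int = 5) -> np.ndarray:
    """Per-window mononucleotide frequencies, stride 1, windows fully inside."""
    L = len(seq)
    if window < 1 or window > L:
        raise ValueError(f"window must be in [1, {L}], got {window}")
    idx = _seq_indices(seq)
    n_windows = L - window + 1
    out = np.zeros((n_windows, 4))
    for start in range(n_windows):
        counts = np.bincount(idx[start : start + window], minlength=4)
        out[start] = counts / window
    return out.ravel()


def encode_ksnpf(seq: str, params: KsnpfParams = KsnpfParams()) -> np.ndarray:
    """Frequencies of ordered pairs separated by exactly K bases, K = 0..K_max.

    Layer K has 16 components N(N1 x{K} N2) / (L - K - 1); each layer sums
    to 1 since there are exactly L-K-1 such pairs.
    """
    L = len(seq)
    if L < params.k_max + 2:
        raise ValueError(f"KSNPF needs length >= K_max+2 = {params.k_max + 2}, got {L}")
    idx = _seq_indices(seq)
    layers = []
    for k in range(params.k_max + 1):
        counts = np.zeros(16)
        n_pairs = L - k - 1
        pair_codes = idx[: n_pairs] * 4 + idx[k + 1 :]
        counts = np.bincount(pair_codes, minlength=16).astype(float)
        layers.append(counts / n_pairs)
    return np.concatenate(layers)


def encode_ncp(seq: str) -> np.ndarray:
    """Chemical-property coordinates per base, position-major (3L)."""
    try:
        return np.array([NCP_CODE[b] for b in seq], dtype=float).ravel()
    except KeyError as exc:
        raise ValueError(f"invalid character {exc.args[0]!r} in sequence") from None


def encode_psednc(
    seq: str,
    params: PseDncParams = PseDncParams(),
    table: DinucPropertyTable | None = None,
    overlapping: bool = True,
) -> np.ndarray:
    """Pseudo dinucleotide composition: 16 frequency terms + lambda tiers.

    The first 16 components are normalized dinucleotide frequencies; the
    last lambda are weighted tier-correlation factors built from squared
    differences of standardized physicochemical indices.  All components
    share the denominator (sum f + w * sum theta), so the vector is
    non-negative and sums to 1.

    ``overlapping`` controls whether the frequency terms use all L-1
    overlapping dinucleotides (default, the usual convention) or the
    floor(L/2) non-overlapping ones.
    """
    L = len(seq)
    if params.lam >= L:
        raise ValueError(f"lambda ({params.lam}) must be < sequence length ({L})")
    if table is None:
        table = DinucPropertyTable.default()
    if not table.standardized:
        table = table.standardize()
    idx = _seq_indices(seq)
    di_codes = idx[:-1] * 4 + idx[1:]

    if overlapping:
        counts = np.bincount(di_codes, minlength=16).astype(float)
    else:
        counts = np.bincount(di_codes[::2], minlength=16).astype(float)
    freqs = counts / counts.sum()

    # theta_j: mean squared index-difference between dinucleotides j apart
    P = table.values  # (mu, 16)
    theta = np.zeros(params.lam)
    for j in range(1, params.lam + 1):
        if L - j - 1 <= 0:
            theta[j - 1] = 0.0
            continue
        a = P[:, di_codes[: L - j - 1]]
        b = P[:, di_codes[j : L - 1]]
        theta[j - 1] = np.mean(((a - b) ** 2).mean(axis=0))

    denom = freqs.sum() + params.w * theta.sum()
    return np.concatenate([freqs, params.w * theta]) / denom


# ---------------------------------------------------------------------------
# label-dependent propensity encoders


def fit_propensity(trainset: LabeledSequenceSet, order: int) -> PropensityModel:
    """Fit the position-specific (di)nucleotide propensity difference matrix.

    Z = per-position symbol frequency among positives minus the same among
    negatives.  Must be fitted on training data only; applying it to the
    sequences it was fitted on leaks label information into features.
    """
    if order not in (1, 2):
        raise ValueError("order must be 1 or 2")
    L = trainset.length
    pos_mask = trainset.labels == 1
    if pos_mask.all() or not pos_mask.any():
        raise ValueError("propensity fitting requires both classes")
    n_rows = 4 if order == 1 else 16
    n_cols = L if order == 1 else L - 1

    def freq(seqs: list[str]) -> np.ndarray:
        M = np.zeros((n_rows, n_cols))
        for seq in seqs:
            idx = _seq_indices(seq)
            codes = idx if order == 1 else idx[:-1] * 4 + idx[1:]
            M[codes, np.arange(n_cols)] += 1.0
        return M / len(seqs)

    pos_seqs = [s for s, m in zip(trainset.sequences, pos_mask) if m]
    neg_seqs = [s for s, m in zip(trainset.sequences, pos_mask) if not m]
    Z = freq(pos_seqs) - freq(neg_seqs)
    return PropensityModel(order=order, Z=Z, length=L)


def encode_psnp(seq: str, model: PropensityModel) -> np.ndarray:
    """Per-position lookup of the order-1 propensity difference (length L)."""
    if model.order != 1:
        raise ValueError("encode_psnp requires an order-1 model")
    if len(seq) != model.length:
        raise ValueError(
            f"sequence length {len(seq)} != model length {model.length}"
        )
    idx = _seq_indices(seq)
    return model.Z[idx, np.arange(len(seq))]


def encode_psdp(seq: str, model: PropensityModel) -> np.ndarray:
    """Per-position lookup of the order-2 propensity difference (length L-1)."""
    if model.order != 2:
        raise ValueError("encode_psdp requires an order-2 model")
    if len(seq) != model.length:
        raise ValueError(
            f"sequence length {len(seq)} != model length {model.length}"
        )
    idx = _seq_indices(seq)
    codes = idx[:-1] * 4 + idx[1:]
    return model.Z[codes, np.arange(len(seq) - 1)]


# ---------------------------------------------------------------------------
# set-level encoding and fusion


def _names(tag: str, parts: Iterable[str]) -> list[str]:
    return [f"{tag}.{p}" for p in parts]


def encode_set(
    sequences: Sequence[str],
    encoder: str,
    *,
    window: int = 5,
    ksnpf_params: KsnpfParams | None = None,
    psednc_params: PseDncParams | None = None,
    property_table: DinucPropertyTable | None = None,
    propensity: PropensityModel | None = None,
) -> FeatureMatrix:
    """Encode a list of sequences with one named encoder into a FeatureMatrix.

    ``encoder`` is one of BE, TNC, ENAC, KSNPF, NCP, PseDNC, PSNP, PSDP.
    PSNP/PSDP require a fitted ``propensity`` model.
    """
    if not sequences:
        raise ValueError("empty sequence list")
    L = len(sequences[0])
    enc = encoder
    if enc == "BE":
        rows = [encode_be(s) for s in sequences]
        names = _names(enc, (f"p{j+1}.{b}" for j in range(L) for b in RNA_ALPHABET))
    elif enc == "TNC":
        rows = [encode_tnc(s) for s in sequences]
        names = _names(enc, TRINUCLEOTIDES)
    elif enc == "ENAC":
        rows = [encode_enac(s, window=window) for s in sequences]
        names = _names(
            enc,
            (f"w{j+1}.{b}" for j in range(L - window + 1) for b in RNA_ALPHABET),
        )
    elif enc == "KSNPF":
        params = ksnpf_params or KsnpfParams()
        rows = [encode_ksnpf(s, params) for s in sequences]
        names = _names(
            enc,
            (f"k{k}.{d}" for k in range(params.k_max + 1) for d in DINUCLEOTIDES),
        )
    elif enc == "NCP":
        rows = [encode_ncp(s) for s in sequences]
        names = _names(
            enc, (f"p{j+1}.{c}" for j in range(L) for c in ("ring", "func", "hbond"))
        )
    elif enc == "PseDNC":
        params = psednc_params or PseDncParams()
        rows = [encode_psednc(s, params, property_table) for s in sequences]
        names = _names(
            enc,
            list(DINUCLEOTIDES) + [f"theta{j+1}" for j in range(params.lam)],
        )
    elif enc == "PSNP":
        if propensity is None:
            raise ValueError("PSNP requires a fitted propensity model")
        rows = [encode_psnp(s, propensity) for s in sequences]
        names = _names(enc, (f"p{j+1}" for j in range(L)))
    elif enc == "PSDP":
        if propensity is None:
            raise ValueError("PSDP requires a fitted propensity model")
        rows = [encode_psdp(s, propensity) for s in sequences]
        names = _names(enc, (f"p{j+1}" for j in range(L - 1)))
    else:
        raise ValueError(f"unknown encoder '{encoder}'")
    values = np.vstack(rows)
    return FeatureMatrix(
        values=values, feature_names=names, encoder_tags=[enc] * values.shape[1]
    )


def fuse(features: Sequence[FeatureMatrix]) -> FeatureMatrix:
    """Column-wise concatenation of per-encoder matrices in canonical order.

    Matrices whose (single) encoder tag appears in the canonical order
    BE, KSNPF, ENAC, NCP, PseDNC, TNC, PSNP, PSDP are sorted accordingly;
    unknown tags keep their given relative order at the end.
    """
    if not features:
        raise ValueError("nothing to fuse")
    n = features[0].n_samples
    for fm in features[1:]:
        if fm.n_samples != n:
            raise ValueError(
                f"sample count mismatch: {fm.n_samples} != {n}"
            )
    if len(features) == 1:
        return features[0]

    def rank(fm: FeatureMatrix) -> int:
        tags = set(fm.encoder_tags)
        if len(tags) == 1 and (tag := next(iter(tags))) in CANONICAL_ENCODER_ORDER:
            return CANONICAL_ENCODER_ORDER.index(tag)
        return len(CANONICAL_ENCODER_ORDER)

    ordered = sorted(features, key=rank)
    return FeatureMatrix(
        values=np.hstack([fm.values for fm in ordered]),
        feature_names=[n for fm in ordered for n in fm.feature_names],
        encoder_tags=[t for fm in ordered for t in fm.encoder_tags],
    )
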