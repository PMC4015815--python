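"""Distance-indexed symbol-pair feature vectors.

A symbol sequence S' over the 20-letter alphabet is mapped to a fixed-length
count vector

    F_dmax(S') = [D_0(S'), D_1(S'), ..., D_dmax(S')]

where D_0 holds the 20 symbol occurrence counts and, for 1 <= d <= d_max,
D_d holds the 400 ordered-pair counts T^d_(a,b): the number of position
pairs (p, p+d) with symbol a at p and symbol b at p+d.  The vector length
is therefore 20 + 400 * d_max.  Adjacent symbols have distance 1; the d=0
block is the plain composition.

The same construction serves both feature modes: applied to the native
residue string it yields the sequence-based DR representation, applied to
the Top-1-gram encoding of a frequency profile it yields the profile-based
DT representation.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np

from .profile_io import (
    FrequencyProfile,
    ProteinSequence,
    SymbolSequence,
    residues_to_symbols,
    top_ngram_encode,
)

#: Operating-point distance threshold: pair offsets beyond this are dropped.
#: Larger values buy little discrimination at substantial dimensional cost.
DEFAULT_D_MAX = 150

N_SYMBOLS = 20
PAIR_BLOCK = N_SYMBOLS * N_SYMBOLS  # 400


def vector_length(d_max: int) -> int:
    """Feature dimension 20 + 400 * d_max."""
    if d_max < 0:
        raise ValueError(f"d_max must be >= 0, got {d_max}")
    return N_SYMBOLS + PAIR_BLOCK * d_max


def feature_index(
    kind: Literal["unigram", "pair"],
    first: int,
    second: int | None = None,
    d: int = 0,
) -> int:
    """Map a feature name to its position in the flat vector.

    Layout: the 20 unigram counts first (index = symbol index), then one
    400-entry block per distance in increasing d, each block in row-major
    (first symbol, second symbol) order.  The map is a bijection onto
    [0, 20 + 400*d_max).
    """
    if not 0 <= first < N_SYMBOLS:
        raise ValueError(f"symbol index out of range: {first}")
    if kind == "unigram":
        if d != 0:
            raise ValueError("unigram features exist only at d=0")
        return first
    if kind == "pair":
        if second is None or not 0 <= second < N_SYMBOLS:
            raise ValueError(f"pair needs a second symbol index in [0, 19], got {second}")
        if d < 1:
            raise ValueError(f"pair distance must be >= 1, got {d}")
        return N_SYMBOLS + PAIR_BLOCK * (d - 1) + N_SYMBOLS * first + second
    raise ValueError(f"unknown feature kind {kind!r}")


@dataclass
class DistanceFeatureVector:
    """The count vector F_dmax(S') with its fixed index layout."""

    sequence_id: str
    d_max: int
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        expected = vector_length(self.d_max)
        if self.values.shape != (expected,):
            raise ValueError(
                f"feature vector for {self.sequence_id!r}: expected length "
                f"{expected} for d_max={self.d_max}, got {self.values.shape}"
            )

    def __len__(self) -> int:
        return len(self.values)

    def unigram_block(self) -> np.ndarray:
        return self.values[:N_SYMBOLS]

    def pair_block(self, d: int) -> np.ndarray:
        """The 20x20 pair-count matrix at distance d (view)."""
        if not 1 <= d <= self.d_max:
            raise ValueError(f"d must be in [1, {self.d_max}], got {d}")
        start = N_SYMBOLS + PAIR_BLOCK * (d - 1)
        return self.values[start : start + PAIR_BLOCK].reshape(N_SYMBOLS, N_SYMBOLS)


def count_distance_block(s: SymbolSequence, d: int) -> np.ndarray:
    """20x20 matrix of ordered pair counts at positional offset d.

    Entry (a, b) counts position pairs (p, p+d) with both positions valid,
    symbol a before symbol b.  Pairs spanning an invalid (masked) position
    are dropped.
    """
    if d < 1:
        raise ValueError(f"d must be >= 1, got {d}")
    L = len(s)
    counts = np.zeros(PAIR_BLOCK, dtype=np.int64)
    if d < L:
        a = s.symbols[: L - d]
        b = s.symbols[d:]
        ok = s.valid[: L - d] & s.valid[d:]
        if ok.any():
            flat = N_SYMBOLS * a[ok] + b[ok]
            counts = np.bincount(flat, minlength=PAIR_BLOCK).astype(np.int64)
    return counts.reshape(N_SYMBOLS, N_SYMBOLS)


def build_feature_vector(s: SymbolSequence, d_max: int) -> DistanceFeatureVector:
    """Count unigram occurrences and pair occurrences for every d <= d_max.

    One pass per distance over the sequence: O(L * d_max) time, O(L^2) in
    the regime where d_max is of order L.
    """
    values = np.zeros(vector_length(d_max), dtype=np.int64)
    if s.valid.any():
        values[:N_SYMBOLS] = np.bincount(s.symbols[s.valid], minlength=N_SYMBOLS)
    for d in range(1, d_max + 1):
        start = N_SYMBOLS + PAIR_BLOCK * (d - 1)
        values[start : start + PAIR_BLOCK] = count_distance_block(s, d).ravel()
    return DistanceFeatureVector(sequence_id=s.id, d_max=d_max, values=values)


def dr_features(seq: ProteinSequence, d_max: int = DEFAULT_D_MAX) -> DistanceFeatureVector:
    """Sequence-based features: count residue pairs on the native sequence."""
    return build_feature_vector(residues_to_symbols(seq), d_max)


def dt_features(profile: FrequencyProfile, d_max: int = DEFAULT_D_MAX) -> DistanceFeatureVector:
    """Profile-based features: count Top-1-gram pairs on the encoded profile."""
    encoded = top_ngram_encode(profile, n=1)
    assert isinstance(encoded, SymbolSequence)
    return build_feature_vector(encoded, d_max)


def write_sparse_features(
    vectors: Sequence[DistanceFeatureVector],
    labels: Sequence[int],
    path: str | Path,
) -> None:
    """Write vectors in SVM-light sparse format.

    One line per vector: the +1/-1 label followed by ``index:value`` pairs
    with 1-based ascending indices; a trailing comment carries the sequence
    id.  All vectors must share one d_max.
    """
    if len(vectors) != len(labels):
        raise ValueError("vectors and labels must have equal length")
    if vectors:
        d0 = vectors[0].d_max
        for v in vectors:
            if v.d_max != d0:
                raise ValueError(
                    f"inconsistent d_max: {v.sequence_id!r} has {v.d_max}, expected {d0}"
                )
    with open(path, "w") as handle:
        for v, y in zip(vectors, labels):
            nz = np.nonzero(v.values)[0]
            pairs = " ".join(f"{i + 1}:{_fmt(v.values[i])}" for i in nz)
            sep = " " if pairs else ""
            handle.write(f"{int(y):+d} {pairs}{sep}# {v.sequence_id} dmax={v.d_max}\n")


def _fmt(x) -> str:
    xf = float(x)
    return str(int(xf)) if xf == int(xf) else repr(xf)


def read_sparse_features(
    path: str | Path,
) -> tuple[np.ndarray, np.ndarray, list[str], int | None]:
    """Read an SVM-light sparse feature file written by this package.

    Returns (dense matrix, labels, sequence ids, d_max or None).  d_max is
    recovered from the per-line comment when present, otherwise from the
    vector length.
    """
    from .errors import FormatError

    rows: list[dict[int, float]] = []
    labels: list[int] = []
    ids: list[str] = []
    d_max: int | None = None
    max_index = 0
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            body, _, comment = line.partition("#")
            comment = comment.strip()
            seq_id = f"row{lineno}"
            if comment:
                toks = comment.split()
                if toks:
                    seq_id = toks[0]
                for tok in toks[1:]:
                    if tok.startswith("dmax="):
                        d_max = int(tok[len("dmax="):])
            toks = body.split()
            if not toks:
                continue
            try:
                labels.append(int(float(toks[0])))
                entries = {}
                for tok in toks[1:]:
                    idx_s, _, val_s = tok.partition(":")
                    idx = int(idx_s)
                    entries[idx - 1] = float(val_s)
                    max_index = max(max_index, idx)
            except ValueError as exc:
                raise FormatError(f"{path}: line {lineno}: {exc}") from exc
            rows.append(entries)
            ids.append(seq_id)

    n_features = vector_length(d_max) if d_max is not None else max_index
    X = np.zeros((len(rows), n_features), dtype=float)
    for i, entries in enumerate(rows):
        for j, val in entries.items():
            X[i, j] = val
    return X, np.asarray(labels, dtype=int), ids, d_max
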