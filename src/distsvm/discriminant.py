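"""Discriminant-weight recovery and per-pair feature-importance summaries.

For a linear-kernel family classifier the decision function can be pulled
back into the explicit feature space:

    w = M alpha

where the columns of M are the training vectors exactly as the kernel saw
them and alpha holds the label-signed dual coefficients.  The magnitude of
each component of w measures the discriminative power of the corresponding
feature.  Because one ordered symbol pair (a, b) owns one component per
distance d, pair-level importance is summarized by the L2 norm of its
per-distance weights, giving a 20 x 20 importance matrix; the 20 unigram
(d = 0) weights are reported separately.  The signed per-distance weights
of a single pair expose which offsets drive the discrimination (in real
families, short distances dominate).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .classify import TrainedModel
from .distance_features import N_SYMBOLS, PAIR_BLOCK, vector_length
from .profile_io import ALPHABET, ALPHABET_INDEX


@dataclass
class DiscriminantWeights:
    """Explicit feature-space weight vector of a linear family classifier."""

    w: np.ndarray
    d_max: int
    model_id: str = ""

    def __post_init__(self) -> None:
        self.w = np.asarray(self.w, dtype=float)
        if self.w.shape != (vector_length(self.d_max),):
            raise ValueError(
                f"weight vector length {self.w.shape} does not match "
                f"d_max={self.d_max} (expected {vector_length(self.d_max)})"
            )

    def pair_weights(self) -> np.ndarray:
        """The pair part of w as a (d_max, 20, 20) array indexed [d-1, a, b]."""
        return self.w[N_SYMBOLS:].reshape(self.d_max, N_SYMBOLS, N_SYMBOLS)


@dataclass
class PairImportance:
    """Non-negative importance of every ordered pair and unigram."""

    pair_norms: np.ndarray  # 20 x 20, entry (a, b) for pair (a, b)
    unigram: np.ndarray  # 20

    def top_pairs(self, k: int = 5) -> list[tuple[str, str, float]]:
        flat = np.argsort(-self.pair_norms, axis=None)[:k]
        out = []
        for idx in flat:
            a, b = divmod(int(idx), N_SYMBOLS)
            out.append((ALPHABET[a], ALPHABET[b], float(self.pair_norms[a, b])))
        return out

    def argmax_pair(self) -> tuple[int, int]:
        return divmod(int(np.argmax(self.pair_norms)), N_SYMBOLS)


def discriminant_weights(
    model: TrainedModel, M: np.ndarray | None = None
) -> DiscriminantWeights:
    """Compute w = M alpha from a trained model.

    M defaults to the model's stored training matrix (rows are samples in
    alpha order, already normalized as trained); a caller-supplied M must
    match that shape and ordering.  Only meaningful for the linear kernel,
    where dot(w, v) + bias reproduces the kernel-expansion score.
    """
    if M is None:
        M = model.X_train
    M = np.asarray(M, dtype=float)
    if M.shape != model.X_train.shape:
        raise ValueError(
            f"training matrix shape {M.shape} does not match model "
            f"({model.X_train.shape})"
        )
    w = M.T @ model.alpha
    return DiscriminantWeights(w=w, d_max=model.d_max, model_id=model.model_id)


def pair_l2_norms(dw: DiscriminantWeights) -> PairImportance:
    """L2 norm over distances of each ordered pair's weights.

    Entry (a, b) = sqrt( sum_d w[(a, b), d]^2 ) over d = 1..d_max; unigram
    importance is |w| of the d=0 block, kept separate from the pair matrix.
    """
    if dw.d_max == 0:
        norms = np.zeros((N_SYMBOLS, N_SYMBOLS))
    else:
        pw = dw.pair_weights()
        norms = np.sqrt(np.sum(pw**2, axis=0))
    return PairImportance(pair_norms=norms, unigram=np.abs(dw.w[:N_SYMBOLS]))


def pair_distance_profile(
    dw: DiscriminantWeights, pair: tuple[int | str, int | str]
) -> np.ndarray:
    """Signed weight of one ordered pair at each distance 1..d_max."""
    a, b = (_symbol_index(x) for x in pair)
    if dw.d_max == 0:
        return np.zeros(0)
    return dw.pair_weights()[:, a, b].copy()


def _symbol_index(x: int | str) -> int:
    if isinstance(x, str):
        try:
            return ALPHABET_INDEX[x.upper()]
        except KeyError:
            raise ValueError(f"unknown residue symbol {x!r}") from None
    x = int(x)
    if not 0 <= x < N_SYMBOLS:
        raise ValueError(f"symbol index out of range: {x}")
    return x


def write_weights_tsv(dw: DiscriminantWeights, path: str | Path) -> None:
    """Sparse TSV of nonzero weight components: feature kind, symbols, d, weight."""
    with open(path, "w") as handle:
        handle.write("kind\tfirst\tsecond\td\tweight\n")
        for a in range(N_SYMBOLS):
            if dw.w[a] != 0.0:
                handle.write(f"unigram\t{ALPHABET[a]}\t.\t0\t{dw.w[a]:.10g}\n")
        if dw.d_max:
            pw = dw.pair_weights()
            for d, a, b in zip(*np.nonzero(pw)):
                handle.write(
                    f"pair\t{ALPHABET[a]}\t{ALPHABET[b]}\t{d + 1}\t{pw[d, a, b]:.10g}\n"
                )


def write_pair_norms_tsv(pi: PairImportance, path: str | Path) -> None:
    """20x20 importance matrix in alphabet order (rows = first symbol)."""
    with open(path, "w") as handle:
        handle.write("first\\second\t" + "\t".join(ALPHABET) + "\n")
        for a in range(N_SYMBOLS):
            row = "\t".join(f"{pi.pair_norms[a, b]:.10g}" for b in range(N_SYMBOLS))
            handle.write(f"{ALPHABET[a]}\t{row}\n")


def write_distance_profile_tsv(
    dw: DiscriminantWeights, pair: tuple[int | str, int | str], path: str | Path
) -> None:
    profile = pair_distance_profile(dw, pair)
    a, b = (_symbol_index(x) for x in pair)
    with open(path, "w") as handle:
        handle.write(f"# pair ({ALPHABET[a]}, {ALPHABET[b]})\n")
        handle.write("d\tweight\n")
        for d, wv in enumerate(profile, start=1):
            handle.write(f"{d}\t{wv:.10g}\n")
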