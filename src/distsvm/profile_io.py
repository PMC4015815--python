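"""Sequence and frequency-profile input, and profile-based symbol encoding.

Protein sequences arrive as FASTA records; evolutionary information arrives
as per-sequence frequency profiles, i.e. the L x 20 column-stochastic matrix
of amino-acid frequencies that PSI-BLAST prints in the percentage block of
its ASCII PSSM output.  From a profile, each position can be re-expressed as
a *Top-n-gram*: the n most frequent amino acids of that column, ordered by
decreasing frequency.  The Top-1-gram sequence is the profile-based analogue
of the native residue string and is the input to the distance-pair feature
construction (the "DT" path); the native residues themselves feed the "DR"
path.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO

from .errors import FormatError

#: The fixed 20-symbol alphabet used for both residues and Top-1-grams.
#: Index 0 is A, index 19 is V.  All feature layouts depend on this order.
ALPHABET: str = "ARDCQEHIGNLKMFPSTWYV"

ALPHABET_INDEX: dict[str, int] = {aa: i for i, aa in enumerate(ALPHABET)}

#: Residue codes that carry no single standard amino acid (ambiguity or
#: non-standard codes).  Positions holding them are masked out of feature
#: counting rather than mapped to an extra symbol: the alphabet is strictly
#: 20 symbols and every feature dimension depends on that.
AMBIGUOUS_RESIDUES = frozenset("BZXUOJ*-.")

#: Column order of the classic PSI-BLAST ASCII PSSM layout.
PSSM_COLUMN_ORDER: str = "ARNDCQEGHILKMFPSTWYV"


@dataclass(frozen=True)
class ProteinSequence:
    """A named amino-acid sequence (uppercase one-letter codes)."""

    id: str
    residues: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence id must be nonempty")
        if len(self.residues) == 0:
            raise ValueError(f"sequence {self.id!r} is empty")

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class FrequencyProfile:
    """Per-position amino-acid frequencies of one protein.

    ``frequencies`` is an L x 20 row-stochastic matrix in :data:`ALPHABET`
    column order.  ``degenerate_rows`` flags rows that carried no signal in
    the source file (all-zero percentage rows) and were replaced by the
    uniform distribution.
    """

    sequence_id: str
    frequencies: np.ndarray
    degenerate_rows: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        if self.frequencies.ndim != 2 or self.frequencies.shape[1] != 20:
            raise ValueError(
                f"profile {self.sequence_id!r}: expected L x 20 matrix, "
                f"got shape {self.frequencies.shape}"
            )
        if self.degenerate_rows is None:
            self.degenerate_rows = np.zeros(len(self.frequencies), dtype=bool)
        sums = self.frequencies.sum(axis=1)
        if not np.allclose(sums, 1.0, atol=1e-6):
            bad = int(np.argmax(np.abs(sums - 1.0)))
            raise ValueError(
                f"profile {self.sequence_id!r}: row {bad} sums to {sums[bad]:.6g}, not 1"
            )

    def __len__(self) -> int:
        return len(self.frequencies)


@dataclass
class SymbolSequence:
    """A sequence over the 20-symbol alphabet with a per-position validity mask.

    ``symbols`` holds alphabet indices; positions that carry no standard
    symbol (ambiguity codes in the source sequence) are marked invalid and
    hold -1.
    """

    id: str
    symbols: np.ndarray
    valid: np.ndarray

    def __post_init__(self) -> None:
        self.symbols = np.asarray(self.symbols, dtype=np.int64)
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.symbols.shape != self.valid.shape or self.symbols.ndim != 1:
            raise ValueError("symbols and valid mask must be 1-D and same length")
        in_range = (self.symbols >= 0) & (self.symbols < 20)
        if not np.all(in_range[self.valid]):
            raise ValueError(f"symbol sequence {self.id!r}: valid symbol out of [0, 19]")

    def __len__(self) -> int:
        return len(self.symbols)

    @property
    def n_invalid(self) -> int:
        return int((~self.valid).sum())

    def to_string(self, invalid_char: str = "X") -> str:
        return "".join(
            ALPHABET[s] if ok else invalid_char
            for s, ok in zip(self.symbols, self.valid)
        )


def symbols_from_string(id: str, text: str) -> SymbolSequence:
    """Build a SymbolSequence from a plain string over the alphabet."""
    return residues_to_symbols(ProteinSequence(id=id, residues=text))


def read_fasta(path: str | Path) -> list[ProteinSequence]:
    """Read FASTA records as ProteinSequence objects, order preserved.

    Residues are uppercased; whitespace inside records is stripped by the
    parser.  A sequence line appearing before any header is a format error.
    """
    path = Path(path)
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            stripped = line.strip()
            if not stripped:
                continue
            if not stripped.startswith(">"):
                raise FormatError(
                    f"{path}: line {lineno}: sequence data before first FASTA header"
                )
            break
    records = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise FormatError(f"{path}: duplicate sequence id {rec.id!r}")
        seen.add(rec.id)
        records.append(ProteinSequence(id=rec.id, residues=str(rec.seq).upper()))
    return records


def write_fasta(sequences: Iterable[ProteinSequence], path: str | Path) -> None:
    with open(path, "w") as handle:
        for seq in sequences:
            handle.write(f">{seq.id}\n{seq.residues}\n")


def _parse_pssm_header_order(line: str) -> str | None:
    toks = line.split()
    if len(toks) >= 20 and all(len(t) == 1 and t in ALPHABET_INDEX for t in toks[:20]):
        return "".join(toks[:20])
    return None


def read_pssm(path: str | Path, sequence_id: str | None = None) -> FrequencyProfile:
    """Read a PSI-BLAST ASCII PSSM file and return its frequency profile.

    Only the 20-column percentage block (columns 23-42 of each data row) is
    consumed; the log-odds block and trailing statistics are ignored.
    Percentages are divided by 100 and each row renormalized to sum to 1.
    All-zero percentage rows (positions PSI-BLAST assigns no weighted
    frequencies) become uniform rows and are flagged as degenerate.

    A plain matrix file (one header line of 20 residue letters followed by
    L whitespace-separated rows of 20 frequencies) is accepted as a
    secondary dialect; see :func:`read_profile_matrix`.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    column_order = PSSM_COLUMN_ORDER
    data_rows: list[list[str]] = []
    first_content = next((ln for ln in lines if ln.strip()), "")
    toks = first_content.split()
    if len(toks) == 20 or (len(toks) == 21 and toks[0] == "#"):
        return read_profile_matrix(path, sequence_id=sequence_id)

    for lineno, line in enumerate(lines, start=1):
        toks = line.split()
        if not toks:
            continue
        order = _parse_pssm_header_order(line)
        if order is not None and not toks[0].isdigit():
            column_order = order
            continue
        if toks[0].isdigit():
            if len(toks) < 42:
                raise FormatError(
                    f"{path}: row at line {lineno} has {len(toks)} fields, "
                    "expected at least 42 (position, residue, 20 scores, 20 percentages)"
                )
            data_rows.append(toks)

    if not data_rows:
        raise FormatError(f"{path}: no PSSM data rows found")

    freqs = np.zeros((len(data_rows), 20), dtype=float)
    residues = []
    for i, toks in enumerate(data_rows):
        residues.append(toks[1])
        try:
            pct = np.array([float(x) for x in toks[22:42]], dtype=float)
        except ValueError as exc:
            raise FormatError(
                f"{path}: non-numeric percentage in data row {i + 1}: {exc}"
            ) from exc
        freqs[i] = pct / 100.0

    # reorder the file's columns into the package alphabet order
    perm = [column_order.index(aa) for aa in ALPHABET]
    freqs = freqs[:, perm]

    degenerate = freqs.sum(axis=1) == 0.0
    freqs[degenerate] = 1.0 / 20.0
    freqs /= freqs.sum(axis=1, keepdims=True)

    return FrequencyProfile(
        sequence_id=sequence_id or path.stem,
        frequencies=freqs,
        degenerate_rows=degenerate,
    )


def write_pssm(
    profile: FrequencyProfile,
    path: str | Path,
    residues: str | None = None,
) -> None:
    """Write a profile in the PSI-BLAST ASCII PSSM layout.

    Log-odds are written as zeros (they are never read back); percentages
    are written with enough precision that read/write round-trips reproduce
    the matrix within 1e-6.
    """
    L = len(profile)
    if residues is None:
        residues = "X" * L
    perm = [ALPHABET_INDEX[aa] for aa in PSSM_COLUMN_ORDER]
    with open(path, "w") as handle:
        handle.write("\n")
        handle.write(
            "Last position-specific scoring matrix computed, weighted observed "
            "percentages rounded down, information per position, and relative "
            "weight of gapless real matches to pseudocounts\n"
        )
        letters = "  ".join(PSSM_COLUMN_ORDER)
        handle.write(f"            {letters}   {letters}\n")
        for i in range(L):
            pct = profile.frequencies[i, perm] * 100.0
            zeros = " ".join(["0"] * 20)
            pcts = " ".join(f"{x:.4f}" for x in pct)
            handle.write(f"{i + 1:5d} {residues[i]}  {zeros}  {pcts}  0.00 0.00\n")


def read_profile_matrix(path: str | Path, sequence_id: str | None = None) -> FrequencyProfile:
    """Read the plain-matrix profile dialect used for fixtures.

    Line 1: the 20 residue letters giving the column order (optionally
    preceded by ``#``); then L rows of 20 frequencies.
    """
    path = Path(path)
    lines = [ln for ln in path.read_text().splitlines() if ln.strip()]
    if not lines:
        raise FormatError(f"{path}: empty profile matrix file")
    header = lines[0].split()
    if header and header[0] == "#":
        header = header[1:]
    if len(header) != 20 or any(t not in ALPHABET_INDEX for t in header):
        raise FormatError(f"{path}: header must list the 20 residue letters")
    column_order = "".join(header)
    try:
        freqs = np.array([[float(x) for x in ln.split()] for ln in lines[1:]])
    except ValueError as exc:
        raise FormatError(f"{path}: non-numeric frequency value: {exc}") from exc
    if freqs.ndim != 2 or freqs.shape[1] != 20:
        raise FormatError(f"{path}: expected 20 columns per row")
    perm = [column_order.index(aa) for aa in ALPHABET]
    freqs = freqs[:, perm]
    degenerate = freqs.sum(axis=1) == 0.0
    freqs[degenerate] = 1.0 / 20.0
    freqs /= freqs.sum(axis=1, keepdims=True)
    return FrequencyProfile(
        sequence_id=sequence_id or path.stem,
        frequencies=freqs,
        degenerate_rows=degenerate,
    )


def write_profile_matrix(profile: FrequencyProfile, path: str | Path) -> None:
    with open(path, "w") as handle:
        handle.write(" ".join(ALPHABET) + "\n")
        for row in profile.frequencies:
            handle.write(" ".join(f"{x:.8f}" for x in row) + "\n")


def top_ngram_encode(
    profile: FrequencyProfile, n: int = 1
) -> SymbolSequence | list[tuple[int, ...]]:
    """Encode each profile column as its Top-n-gram.

    A Top-n-gram is the n most frequent amino acids of the column in
    descending frequency order; the order reflects their relative weight in
    the underlying alignment.  Ties are broken toward the symbol earliest in
    :data:`ALPHABET` (so an all-uniform column encodes to A).

    For ``n == 1`` the result is a :class:`SymbolSequence` (every position
    valid); for larger n, a list of index tuples.
    """
    if not (1 <= n <= 20):
        raise ValueError(f"n must be in [1, 20], got {n}")
    # stable argsort of -freq: equal frequencies keep ascending alphabet index
    order = np.argsort(-profile.frequencies, axis=1, kind="stable")
    if n == 1:
        top = order[:, 0]
        return SymbolSequence(
            id=profile.sequence_id,
            symbols=top,
            valid=np.ones(len(top), dtype=bool),
        )
    return [tuple(int(s) for s in row[:n]) for row in order]


def residues_to_symbols(seq: ProteinSequence) -> SymbolSequence:
    """Map residues to alphabet indices; ambiguity codes become invalid positions.

    Unknown characters are not an error: they are masked invalid and counted
    via :attr:`SymbolSequence.n_invalid`.
    """
    symbols = np.full(len(seq), -1, dtype=np.int64)
    valid = np.zeros(len(seq), dtype=bool)
    for i, aa in enumerate(seq.residues):
        idx = ALPHABET_INDEX.get(aa)
        if idx is not None:
            symbols[i] = idx
            valid[i] = True
    return SymbolSequence(id=seq.id, symbols=symbols, valid=valid)
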