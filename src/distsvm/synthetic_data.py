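"""Synthetic sequences, profiles and two-class families with planted structure.

The generator emulates the statistical skeleton that the distance-pair
method exploits: a family is a set of sequences sharing an over-represented
ordered symbol pair at a characteristic positional offset (the synthetic
analogue of a conserved motif).  Positive sequences are i.i.d. background
draws with ``insertions_per_sequence`` planted occurrences of symbol a at
position p and symbol b at p + planted_distance.  Negative sequences
receive the same number of a and b symbols at unpaired random positions,
so both classes share the same residue composition and discrimination must
come from pair-distance structure, not from the d=0 composition block.

Profiles are a concentration mixture: each column puts mass
``profile_concentration`` on the native residue and spreads the remainder
randomly over the other 19 symbols, so with concentration above 0.5 the
Top-1-gram channel reproduces the native sequence exactly and at
concentration 1 the profile is degenerate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .evaluate import FamilySplit
from .profile_io import ALPHABET, ALPHABET_INDEX, FrequencyProfile, ProteinSequence


def uniform_background() -> np.ndarray:
    return np.full(20, 1.0 / 20.0)


@dataclass
class SyntheticFamilyConfig:
    """Conditions for one synthetic two-class family.

    planted_pair is a pair of residue letters (or None for a null family in
    which both classes are pure background); planted_distance is the
    positional offset of the planted pair (adjacent = 1).
    """

    n_pos_train: int = 30
    n_neg_train: int = 30
    n_pos_test: int = 15
    n_neg_test: int = 15
    seq_length: tuple[int, int] = (80, 120)
    planted_pair: tuple[str, str] | None = ("G", "G")
    planted_distance: int = 5
    insertions_per_sequence: int = 6
    background: np.ndarray = field(default_factory=uniform_background)
    profile_concentration: float = 0.9
    seed: int = 0

    def __post_init__(self) -> None:
        self.background = np.asarray(self.background, dtype=float)
        if self.background.shape != (20,) or not np.isclose(self.background.sum(), 1.0):
            raise ValueError("background must be a 20-vector summing to 1")
        if not (0.0 < self.profile_concentration <= 1.0):
            raise ValueError("profile_concentration must be in (0, 1]")
        lo, hi = self.seq_length
        if not (1 <= lo <= hi):
            raise ValueError(f"invalid seq_length range {self.seq_length}")
        if self.planted_pair is not None:
            if self.planted_distance < 1:
                raise ValueError("planted_distance must be >= 1")
            if self.planted_distance >= lo:
                raise ValueError(
                    "planted_distance must be smaller than the minimum sequence length"
                )
            if self.insertions_per_sequence < 1:
                raise ValueError("insertions_per_sequence must be >= 1")
            for sym in self.planted_pair:
                if sym not in ALPHABET_INDEX:
                    raise ValueError(f"unknown planted symbol {sym!r}")


def generate_null_sequence(
    length: int, background: np.ndarray, rng: np.random.Generator, seq_id: str = "null"
) -> ProteinSequence:
    """i.i.d. draws from the background residue distribution."""
    background = np.asarray(background, dtype=float)
    if background.shape != (20,) or not np.isclose(background.sum(), 1.0):
        raise ValueError("background must be a 20-vector summing to 1")
    idx = rng.choice(20, size=length, p=background)
    return ProteinSequence(id=seq_id, residues="".join(ALPHABET[i] for i in idx))


def generate_planted_sequence(
    cfg: SyntheticFamilyConfig, rng: np.random.Generator, seq_id: str = "planted"
) -> ProteinSequence:
    """Background sequence with planted (a, b) occurrences at the set offset.

    Each of the ``insertions_per_sequence`` insertions overwrites positions
    p and p + planted_distance with the pair symbols; insertion sites are
    drawn uniformly and do not overlap each other.
    """
    if cfg.planted_pair is None:
        raise ValueError("config has no planted pair")
    L = int(rng.integers(cfg.seq_length[0], cfg.seq_length[1] + 1))
    d = cfg.planted_distance
    k = cfg.insertions_per_sequence
    if L <= d or 2 * k > L:
        raise ValueError(
            f"sequence of length {L} cannot host {k} planted pairs at distance {d}"
        )
    residues = list(
        generate_null_sequence(L, cfg.background, rng, seq_id=seq_id).residues
    )
    a, b = cfg.planted_pair
    used: set[int] = set()
    placed = 0
    attempts = 0
    while placed < k:
        attempts += 1
        if attempts > 1000 * k:
            raise ValueError(
                f"could not place {k} non-overlapping pairs at distance {d} in length {L}"
            )
        p = int(rng.integers(0, L - d))
        if p in used or p + d in used:
            continue
        used.update((p, p + d))
        residues[p] = a
        residues[p + d] = b
        placed += 1
    return ProteinSequence(id=seq_id, residues="".join(residues))


def generate_composition_matched_sequence(
    cfg: SyntheticFamilyConfig, rng: np.random.Generator, seq_id: str = "decoy"
) -> ProteinSequence:
    """Negative-class sequence: same inserted symbols, no planted pairing.

    The same number of a and b symbols is written at random positions, but
    no two inserted symbols are allowed to form the pair (a, b) at exactly
    the planted offset, so the class differs from positives only in
    pair-distance structure.
    """
    if cfg.planted_pair is None:
        raise ValueError("config has no planted pair")
    L = int(rng.integers(cfg.seq_length[0], cfg.seq_length[1] + 1))
    d = cfg.planted_distance
    k = cfg.insertions_per_sequence
    residues = list(
        generate_null_sequence(L, cfg.background, rng, seq_id=seq_id).residues
    )
    a, b = cfg.planted_pair
    placed: dict[int, str] = {}
    symbols = [a] * k + [b] * k
    rng.shuffle(symbols)
    attempts = 0
    for sym in symbols:
        while True:
            attempts += 1
            if attempts > 2000 * k:
                raise ValueError("could not place unpaired insertions; sequence too short")
            p = int(rng.integers(0, L))
            if p in placed:
                continue
            makes_pair = (sym == a and placed.get(p + d) == b) or (
                sym == b and placed.get(p - d) == a
            )
            if makes_pair:
                continue
            placed[p] = sym
            residues[p] = sym
            break
    return ProteinSequence(id=seq_id, residues="".join(residues))


def synthetic_profile(
    seq: ProteinSequence, concentration: float, rng: np.random.Generator
) -> FrequencyProfile:
    """Frequency profile concentrated on the native residue of each column.

    Mass ``concentration`` goes to the native residue; the remainder is
    spread over the other 19 symbols with random proportions.  With
    concentration > 0.5 the per-column maximum is always the native
    residue; at concentration 1 the profile is degenerate (point masses).
    """
    if not (0.0 < concentration <= 1.0):
        raise ValueError("concentration must be in (0, 1]")
    L = len(seq)
    freqs = np.zeros((L, 20))
    for i, aa in enumerate(seq.residues):
        native = ALPHABET_INDEX.get(aa)
        if native is None:
            freqs[i] = 1.0 / 20.0
            continue
        if concentration == 1.0:
            freqs[i, native] = 1.0
            continue
        others = rng.random(19)
        others *= (1.0 - concentration) / others.sum()
        row = np.empty(20)
        row[native] = concentration
        row[np.arange(20) != native] = others
        freqs[i] = row
    return FrequencyProfile(sequence_id=seq.id, frequencies=freqs)


def generate_family(
    cfg: SyntheticFamilyConfig, family_id: str = "fam1"
) -> tuple[FamilySplit, dict[str, ProteinSequence], dict[str, FrequencyProfile]]:
    """Generate a full two-class family with train/test splits and profiles.

    Positives carry the planted pair; negatives are composition-matched
    decoys (or, for a null family, both classes are pure background).
    Fully reproducible from ``cfg.seed``.
    """
    rng = np.random.default_rng(cfg.seed)
    sequences: dict[str, ProteinSequence] = {}
    profiles: dict[str, FrequencyProfile] = {}
    roles = {
        "pos-train": (cfg.n_pos_train, True),
        "pos-test": (cfg.n_pos_test, True),
        "neg-train": (cfg.n_neg_train, False),
        "neg-test": (cfg.n_neg_test, False),
    }
    id_lists: dict[str, list[str]] = {}
    for role, (count, positive) in roles.items():
        ids = []
        for i in range(count):
            seq_id = f"{family_id}-{role}-{i}"
            if cfg.planted_pair is None:
                L = int(rng.integers(cfg.seq_length[0], cfg.seq_length[1] + 1))
                seq = generate_null_sequence(L, cfg.background, rng, seq_id=seq_id)
            elif positive:
                seq = generate_planted_sequence(cfg, rng, seq_id=seq_id)
            else:
                seq = generate_composition_matched_sequence(cfg, rng, seq_id=seq_id)
            sequences[seq_id] = seq
            profiles[seq_id] = synthetic_profile(seq, cfg.profile_concentration, rng)
            ids.append(seq_id)
        id_lists[role] = ids

    split = FamilySplit(
        family_id=family_id,
        positive_train=id_lists["pos-train"],
        positive_test=id_lists["pos-test"],
        negative_train=id_lists["neg-train"],
        negative_test=id_lists["neg-test"],
    )
    return split, sequences, profiles


def generate_benchmark(
    base_cfg: SyntheticFamilyConfig, n_families: int
) -> tuple[
    list[FamilySplit], dict[str, ProteinSequence], dict[str, FrequencyProfile]
]:
    """Generate several independent families (seeds offset from the base seed)."""
    splits = []
    sequences: dict[str, ProteinSequence] = {}
    profiles: dict[str, FrequencyProfile] = {}
    for i in range(n_families):
        cfg = SyntheticFamilyConfig(
            n_pos_train=base_cfg.n_pos_train,
            n_neg_train=base_cfg.n_neg_train,
            n_pos_test=base_cfg.n_pos_test,
            n_neg_test=base_cfg.n_neg_test,
            seq_length=base_cfg.seq_length,
            planted_pair=base_cfg.planted_pair,
            planted_distance=base_cfg.planted_distance,
            insertions_per_sequence=base_cfg.insertions_per_sequence,
            background=base_cfg.background.copy(),
            profile_concentration=base_cfg.profile_concentration,
            seed=base_cfg.seed + i,
        )
        split, seqs, profs = generate_family(cfg, family_id=f"fam{i + 1}")
        splits.append(split)
        sequences.update(seqs)
        profiles.update(profs)
    return splits, sequences, profiles
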