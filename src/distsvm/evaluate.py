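"""ROC / ROC50 evaluation and the per-family benchmark protocol.

Family benchmarks for remote homology detection are heavily unbalanced
(a handful of positives against thousands of negatives), so ranking
metrics are used: the ROC score is the normalized area under the
true-positive vs false-positive curve — equivalently the probability that
a random positive outranks a random negative, with ties counting one half —
and the ROC50 score is the area under that curve truncated at the 50th
false positive, normalized by n_pos * min(50, n_neg) so that perfect early
retrieval scores 1.  When a family has at most 50 negatives the truncation
is vacuous and ROC50 equals ROC exactly.

The benchmark driver trains one classifier per family on its train split,
scores the test split, and reports per-family and unweighted average
scores.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .classify import SVMConfig, TrainingSet, score_many, train_family_classifier
from .distance_features import (
    DistanceFeatureVector,
    dr_features,
    dt_features,
)
from .errors import FormatError
from .profile_io import FrequencyProfile, ProteinSequence

ROLES = ("pos-train", "pos-test", "neg-train", "neg-test")


@dataclass
class FamilySplit:
    """Train/test membership lists for one held-out family."""

    family_id: str
    positive_train: list[str]
    positive_test: list[str]
    negative_train: list[str]
    negative_test: list[str]

    def __post_init__(self) -> None:
        lists = [
            self.positive_train,
            self.positive_test,
            self.negative_train,
            self.negative_test,
        ]
        all_ids = [i for lst in lists for i in lst]
        if len(set(all_ids)) != len(all_ids):
            raise ValueError(f"family {self.family_id!r}: split lists are not disjoint")

    def role_of(self, seq_id: str) -> str | None:
        for role, lst in zip(ROLES, self._lists()):
            if seq_id in lst:
                return role
        return None

    def _lists(self) -> tuple[list[str], ...]:
        return (
            self.positive_train,
            self.positive_test,
            self.negative_train,
            self.negative_test,
        )


@dataclass
class EvalResult:
    family_id: str
    roc: float
    roc50: float
    n_pos: int
    n_neg: int


def _truncated_roc_area(
    scores: np.ndarray, labels: np.ndarray, max_fp: int
) -> float:
    """Normalized area under the ROC curve up to the max_fp-th false positive.

    The curve is built by sweeping the decision threshold over score groups
    in descending order; a group of tied scores contributes a straight
    segment (trapezoid), which is exactly the half-credit tie convention.
    The area is normalized by n_pos * min(max_fp, n_neg).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == -1).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present to compute a ROC score")
    cutoff = min(max_fp, n_neg)

    order = np.argsort(-scores, kind="stable")
    s_sorted = scores[order]
    y_sorted = labels[order]
    # boundaries of tied-score groups
    boundaries = np.nonzero(np.diff(s_sorted))[0] + 1
    group_starts = np.concatenate(([0], boundaries))
    group_ends = np.concatenate((boundaries, [len(s_sorted)]))

    area = 0.0
    fp = tp = 0
    for start, end in zip(group_starts, group_ends):
        grp = y_sorted[start:end]
        p = int((grp == 1).sum())
        f = int((grp == -1).sum())
        new_fp, new_tp = fp + f, tp + p
        if new_fp >= cutoff:
            # interpolate the segment at the cutoff and stop
            if f > 0:
                t = (cutoff - fp) / f
                tp_at_cut = tp + t * p
                area += (cutoff - fp) * (tp + tp_at_cut) / 2.0
            return area / (n_pos * cutoff)
        area += f * (tp + new_tp) / 2.0
        fp, tp = new_fp, new_tp
    return area / (n_pos * cutoff)


def roc_score(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Full ROC area: P(score_pos > score_neg) + 0.5 P(tie)."""
    labels = np.asarray(labels, dtype=int)
    n_neg = int((labels == -1).sum())
    return _truncated_roc_area(np.asarray(scores, dtype=float), labels, n_neg)


def roc50_score(scores: Sequence[float], labels: Sequence[int]) -> float:
    """ROC area truncated at the 50th false positive, normalized to [0, 1]."""
    return _truncated_roc_area(
        np.asarray(scores, dtype=float), np.asarray(labels, dtype=int), 50
    )


def evaluate_family(
    scores: Sequence[float], labels: Sequence[int], family_id: str = ""
) -> EvalResult:
    labels = np.asarray(labels, dtype=int)
    return EvalResult(
        family_id=family_id,
        roc=roc_score(scores, labels),
        roc50=roc50_score(scores, labels),
        n_pos=int((labels == 1).sum()),
        n_neg=int((labels == -1).sum()),
    )


def _features_for(
    seq_id: str,
    family_id: str,
    mode: str,
    d_max: int,
    sequences: Mapping[str, ProteinSequence],
    profiles: Mapping[str, FrequencyProfile] | None,
) -> DistanceFeatureVector:
    if mode == "dr":
        if seq_id not in sequences:
            raise KeyError(f"family {family_id!r}: no sequence for id {seq_id!r}")
        return dr_features(sequences[seq_id], d_max)
    if mode == "dt":
        if profiles is None or seq_id not in profiles:
            raise KeyError(f"family {family_id!r}: no profile for id {seq_id!r}")
        return dt_features(profiles[seq_id], d_max)
    raise ValueError(f"unknown feature mode {mode!r} (expected 'dr' or 'dt')")


def run_benchmark(
    splits: Iterable[FamilySplit],
    sequences: Mapping[str, ProteinSequence],
    profiles: Mapping[str, FrequencyProfile] | None = None,
    mode: str = "dt",
    d_max: int = 150,
    svm_config: SVMConfig | None = None,
) -> tuple[list[EvalResult], dict[str, float]]:
    """Train and evaluate one classifier per family; report averages.

    Returns the per-family results and a summary dict with unweighted mean
    ROC and ROC50 across families.
    """
    results: list[EvalResult] = []
    for split in splits:
        train_ids = split.positive_train + split.negative_train
        train_labels = [1] * len(split.positive_train) + [-1] * len(split.negative_train)
        test_ids = split.positive_test + split.negative_test
        test_labels = [1] * len(split.positive_test) + [-1] * len(split.negative_test)
        if not split.positive_test or not split.negative_test:
            raise ValueError(
                f"family {split.family_id!r}: test split needs both classes"
            )

        train_vecs = [
            _features_for(i, split.family_id, mode, d_max, sequences, profiles)
            for i in train_ids
        ]
        test_vecs = [
            _features_for(i, split.family_id, mode, d_max, sequences, profiles)
            for i in test_ids
        ]
        ts = TrainingSet.from_vectors(train_vecs, train_labels)
        model = train_family_classifier(ts, svm_config)
        scores = score_many(model, test_vecs)
        results.append(evaluate_family(scores, test_labels, split.family_id))

    summary = {
        "mean_roc": float(np.mean([r.roc for r in results])) if results else float("nan"),
        "mean_roc50": float(np.mean([r.roc50 for r in results])) if results else float("nan"),
        "n_families": float(len(results)),
    }
    return results, summary


def results_to_frame(
    results: Sequence[EvalResult], summary: Mapping[str, float] | None = None
) -> pd.DataFrame:
    """Tabulate per-family results, with an optional trailing mean row."""
    df = pd.DataFrame(
        [
            {
                "family_id": r.family_id,
                "roc": r.roc,
                "roc50": r.roc50,
                "n_pos": r.n_pos,
                "n_neg": r.n_neg,
            }
            for r in results
        ]
    )
    if summary is not None and len(df):
        mean_row = pd.DataFrame(
            [
                {
                    "family_id": "MEAN",
                    "roc": summary["mean_roc"],
                    "roc50": summary["mean_roc50"],
                    "n_pos": "",
                    "n_neg": "",
                }
            ]
        )
        df = pd.concat([df, mean_row], ignore_index=True)
    return df


def write_results_tsv(
    results: Sequence[EvalResult],
    summary: Mapping[str, float],
    path: str | Path,
) -> None:
    results_to_frame(results, summary).to_csv(path, sep="\t", index=False)


def read_split_file(path: str | Path, family_id: str | None = None) -> FamilySplit:
    """Read a tab/space-separated split file: one ``<id> <role>`` pair per line.

    Roles are pos-train / pos-test / neg-train / neg-test; blank lines and
    ``#`` comments are ignored.
    """
    path = Path(path)
    lists: dict[str, list[str]] = {role: [] for role in ROLES}
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        toks = line.split()
        if len(toks) != 2:
            raise FormatError(f"{path}: line {lineno}: expected '<id> <role>'")
        seq_id, role = toks
        if role not in lists:
            raise FormatError(
                f"{path}: line {lineno}: unknown role {role!r} (expected one of {ROLES})"
            )
        lists[role].append(seq_id)
    return FamilySplit(
        family_id=family_id or path.stem,
        positive_train=lists["pos-train"],
        positive_test=lists["pos-test"],
        negative_train=lists["neg-train"],
        negative_test=lists["neg-test"],
    )


def write_split_file(split: FamilySplit, path: str | Path) -> None:
    with open(path, "w") as handle:
        handle.write(f"# family {split.family_id}\n")
        for role, lst in zip(ROLES, split._lists()):
            for seq_id in lst:
                handle.write(f"{seq_id}\t{role}\n")


def read_split_dir(directory: str | Path, family_id: str | None = None) -> FamilySplit:
    """Read a benchmark-style family directory with one file per role.

    Each of pos-train / pos-test / neg-train / neg-test is a file listing
    member ids, either one id per line or as FASTA headers.
    """
    directory = Path(directory)
    lists = {}
    for role in ROLES:
        fpath = directory / role
        if not fpath.exists():
            matches = list(directory.glob(f"{role}.*"))
            if not matches:
                raise FormatError(f"{directory}: missing split file for role {role!r}")
            fpath = matches[0]
        lines = [ln.strip() for ln in fpath.read_text().splitlines() if ln.strip()]
        if any(ln.startswith(">") for ln in lines):
            ids = [ln[1:].split()[0] for ln in lines if ln.startswith(">")]
        else:
            ids = [ln.split()[0] for ln in lines]
        lists[role] = ids
    return FamilySplit(
        family_id=family_id or directory.name,
        positive_train=lists["pos-train"],
        positive_test=lists["pos-test"],
        negative_train=lists["neg-train"],
        negative_test=lists["neg-test"],
    )
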