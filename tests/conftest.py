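"""Shared fixtures: small profile files and independent brute-force oracles."""

from __future__ import annotations

import numpy as np
import pytest

from distsvm.profile_io import ALPHABET, PSSM_COLUMN_ORDER

# ---------------------------------------------------------------------------
# A 4-position PSI-BLAST-style ASCII PSSM for the sequence AGLP whose
# percentage-block column maxima are K, F, F, K, so its Top-1-gram encoding
# is the string KFFK.  Percentages are deliberately mixed (not one-hot) so
# the argmax is doing real work.
# ---------------------------------------------------------------------------

_FIG_ROWS = [
    ("A", {"K": 70, "V": 30}),
    ("G", {"F": 60, "L": 40}),
    ("L", {"F": 100}),
    ("P", {"K": 55, "R": 45}),
]


def _pssm_text(rows) -> str:
    letters = "   ".join(PSSM_COLUMN_ORDER)
    lines = [
        "",
        "Last position-specific scoring matrix computed, weighted observed "
        "percentages rounded down, information per position, and relative "
        "weight of gapless real matches to pseudocounts",
        f"            {letters}    {letters}",
    ]
    for i, (residue, pct) in enumerate(rows, start=1):
        scores = " ".join(["0"] * 20)
        pcts = " ".join(str(pct.get(aa, 0)) for aa in PSSM_COLUMN_ORDER)
        lines.append(f"{i:5d} {residue}   {scores}   {pcts}  0.50 0.10")
    lines.append("")
    return "\n".join(lines)


@pytest.fixture
def worked_example_pssm(tmp_path):
    """PSSM file for AGLP with column maxima K, F, F, K."""
    path = tmp_path / "aglp.pssm"
    path.write_text(_pssm_text(_FIG_ROWS))
    return path


@pytest.fixture
def zero_row_pssm(tmp_path):
    """PSSM file whose middle row has all-zero percentages."""
    rows = [("A", {"K": 70, "V": 30}), ("G", {}), ("L", {"F": 100})]
    path = tmp_path / "zero.pssm"
    path.write_text(_pssm_text(rows))
    return path


# ---------------------------------------------------------------------------
# Independent oracles.  These stay deliberately naive (double loops, direct
# pair counting) and never call the code paths they check.
# ---------------------------------------------------------------------------


def naive_feature_vector(symbols, valid, d_max: int) -> np.ndarray:
    """O(L^2) double loop over all ordered position pairs."""
    symbols = np.asarray(symbols)
    valid = np.asarray(valid, dtype=bool)
    v = np.zeros(20 + 400 * d_max, dtype=np.int64)
    L = len(symbols)
    for i in range(L):
        if valid[i]:
            v[symbols[i]] += 1
    for i in range(L):
        for j in range(L):
            d = j - i
            if 1 <= d <= d_max and valid[i] and valid[j]:
                v[20 + 400 * (d - 1) + 20 * symbols[i] + symbols[j]] += 1
    return v


def pairwise_roc(scores, labels) -> float:
    """U-statistic by direct pair counting with half credit for ties."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    pos = scores[labels == 1]
    neg = scores[labels == -1]
    wins = sum(1.0 if p > n else 0.5 if p == n else 0.0 for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


def trapezoid_roc_curve(scores, labels):
    """(fp, tp) curve points swept over all distinct thresholds, plus origin."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    fps, tps = [0], [0]
    for thr in sorted(set(scores), reverse=True):
        picked = scores >= thr
        fps.append(int(np.sum(picked & (labels == -1))))
        tps.append(int(np.sum(picked & (labels == 1))))
    return np.array(fps, dtype=float), np.array(tps, dtype=float)


def trapezoid_roc(scores, labels) -> float:
    fps, tps = trapezoid_roc_curve(scores, labels)
    labels = np.asarray(labels, dtype=int)
    n_pos = int(np.sum(labels == 1))
    n_neg = int(np.sum(labels == -1))
    return float(np.trapezoid(tps, fps)) / (n_pos * n_neg)


def trapezoid_roc50(scores, labels, max_fp: int = 50) -> float:
    """Truncated area by clipping the brute-force curve at the FP cutoff."""
    fps, tps = trapezoid_roc_curve(scores, labels)
    labels = np.asarray(labels, dtype=int)
    n_pos = int(np.sum(labels == 1))
    n_neg = int(np.sum(labels == -1))
    cutoff = min(max_fp, n_neg)
    area = 0.0
    for k in range(1, len(fps)):
        f0, f1, t0, t1 = fps[k - 1], fps[k], tps[k - 1], tps[k]
        if f1 <= cutoff:
            area += (f1 - f0) * (t0 + t1) / 2.0
        else:
            if f0 < cutoff:
                t_cut = t0 + (t1 - t0) * (cutoff - f0) / (f1 - f0)
                area += (cutoff - f0) * (t0 + t_cut) / 2.0
            break
    return area / (n_pos * cutoff)


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)
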