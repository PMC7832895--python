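"""Independent brute-force oracles used to cross-check the implementation.

These deliberately share no code with the package: pair counting for AUC,
exhaustive threshold/weight scans, and a plain Gotoh dynamic program for
local alignment.
"""

from __future__ import annotations

import numpy as np


def auc_rank_sum(labels, scores) -> float:
    """Mann-Whitney AUC by direct pair counting (ties count half)."""
    labels = np.asarray(labels).astype(int)
    scores = np.asarray(scores, dtype=float)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = halves = 0
    for p in pos:
        for n in neg:
            if p > n:
                wins += 1
            elif p == n:
                halves += 1
    return (wins + 0.5 * halves) / (len(pos) * len(neg))


def mcc_brute(labels, preds) -> float:
    labels = np.asarray(labels).astype(int)
    preds = np.asarray(preds).astype(int)
    tp = int(((labels == 1) & (preds == 1)).sum())
    tn = int(((labels == 0) & (preds == 0)).sum())
    fp = int(((labels == 0) & (preds == 1)).sum())
    fn = int(((labels == 1) & (preds == 0)).sum())
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom == 0:
        return 0.0
    return (tp * tn - fp * fn) / np.sqrt(denom)


def best_threshold_exhaustive(track, labels) -> tuple[float, float]:
    """Try a cut between every pair of adjacent sorted unique values plus
    end cuts; return (threshold, mcc) with the smallest maximizing cut."""
    track = np.asarray(track, dtype=float)
    uniq = np.unique(track)
    cands = [uniq[0] - 0.5]
    cands += [(a + b) / 2 for a, b in zip(uniq[:-1], uniq[1:])]
    cands += [uniq[-1] + 0.5]
    best = (cands[0], -np.inf)
    for thr in cands:
        mcc = mcc_brute(labels, (track > thr).astype(int))
        if mcc > best[1] + 1e-12:
            best = (thr, mcc)
    return best


def weighted_combination_surface(tracks, labels):
    """AUC at every (w1, w2) grid point with w3 >= 0.1, by brute force."""
    out = []
    for i in range(1, 10):
        for j in range(1, 10):
            k = 10 - i - j
            if k < 1:
                continue
            w1, w2, w3 = i / 10, j / 10, k / 10
            merged = w1 * tracks[0] + w2 * tracks[1] + w3 * tracks[2]
            out.append((w1, w2, w3, auc_rank_sum(labels, merged)))
    return out


def smith_waterman_affine(seq_a: str, seq_b: str, matrix, gap_open: int,
                          gap_extend: int) -> float:
    """Gotoh local alignment score; the first gap residue costs gap_open,
    each further residue gap_extend."""
    la, lb = len(seq_a), len(seq_b)
    neg = -1e9
    m = np.zeros((la + 1, lb + 1))   # ending in a match/mismatch
    x = np.full((la + 1, lb + 1), neg)  # gap in seq_b (consume a)
    y = np.full((la + 1, lb + 1), neg)  # gap in seq_a (consume b)
    best = 0.0
    for i in range(1, la + 1):
        for j in range(1, lb + 1):
            s = matrix[seq_a[i - 1], seq_b[j - 1]]
            m[i, j] = max(0.0, s + max(m[i - 1, j - 1], x[i - 1, j - 1],
                                       y[i - 1, j - 1]))
            x[i, j] = max(m[i - 1, j] - gap_open, x[i - 1, j] - gap_extend)
            y[i, j] = max(m[i, j - 1] - gap_open, y[i, j - 1] - gap_extend)
            best = max(best, m[i, j])
    return best
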