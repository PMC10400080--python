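"""Sequence-level statistics of decoded latent states.

Fractional occupancy (proportion of TRs in each state), dwell times
(maximal consecutive runs of one state), empirical transition matrices
(row- or column-normalized, never counting across run boundaries),
intersubject state-sequence similarity, and a bootstrap contrast of
pairwise synchrony between conditions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .hmm_core import StateSequence

__all__ = [
    "TransitionMatrix",
    "fractional_occupancy",
    "dwell_times",
    "transition_matrix",
    "sequence_similarity",
    "pairwise_similarity",
    "bootstrap_condition_contrast",
]


@dataclass
class TransitionMatrix:
    counts: np.ndarray  # K×K integer transition counts (run boundaries excluded)
    probabilities: np.ndarray  # normalized per `normalization`
    normalization: str  # "row" (to-state probs) or "column" (from-state probs)
    empty: np.ndarray | None = None  # rows/columns with zero counts, left as zeros


def fractional_occupancy(seq: StateSequence) -> np.ndarray:
    """Proportion of TRs spent in each state; entries sum to 1."""
    counts = np.bincount(seq.labels, minlength=seq.K)
    return counts / seq.T


def dwell_times(seq: StateSequence) -> list[list[int]]:
    """Per-state list of maximal consecutive-occupancy lengths (in TRs).

    Dwells never span run boundaries, and the dwell lengths over all states
    always total T.
    """
    out: list[list[int]] = [[] for _ in range(seq.K)]
    for run in seq.runs():
        change = np.flatnonzero(np.diff(run) != 0)
        starts = np.concatenate([[0], change + 1])
        stops = np.concatenate([change + 1, [run.size]])
        for a, b in zip(starts, stops):
            out[run[a]].append(int(b - a))
    return out


def transition_matrix(seq: StateSequence, normalization: str = "row") -> TransitionMatrix:
    """Empirical K×K transition matrix from consecutive within-run pairs.

    Row normalization gives the probability of transitioning *to* each
    state given the current one; column normalization the probability of
    having arrived *from* each state.  Rows/columns with no counts are
    emitted as zeros and flagged.
    """
    if seq.T < 2:
        raise ValueError("need at least two time points")
    if normalization not in ("row", "column"):
        raise ValueError("normalization must be 'row' or 'column'")
    K = seq.K
    counts = np.zeros((K, K), dtype=int)
    for run in seq.runs():
        np.add.at(counts, (run[:-1], run[1:]), 1)
    probs = counts.astype(float)
    axis = 1 if normalization == "row" else 0
    sums = probs.sum(axis=axis, keepdims=True)
    empty = (sums == 0).ravel()
    with np.errstate(invalid="ignore", divide="ignore"):
        probs = np.where(sums > 0, probs / sums, 0.0)
    return TransitionMatrix(counts, probs, normalization, empty)


def sequence_similarity(seqA: StateSequence, seqB: StateSequence) -> float:
    """Proportion of TRs at which two subjects occupy the same state."""
    if seqA.T != seqB.T:
        raise ValueError("sequences must have equal length")
    return float(np.mean(seqA.labels == seqB.labels))


def pairwise_similarity(
    seqs: list[StateSequence],
) -> tuple[float, float, np.ndarray]:
    """All unordered pairwise similarities of a group.

    Returns (mean, sd over pairs, full symmetric matrix with unit diagonal).
    """
    n = len(seqs)
    if n < 2:
        raise ValueError("need at least two subjects")
    mat = np.eye(n)
    vals = []
    for i in range(n):
        for j in range(i + 1, n):
            s = sequence_similarity(seqs[i], seqs[j])
            mat[i, j] = mat[j, i] = s
            vals.append(s)
    vals = np.asarray(vals)
    return float(vals.mean()), float(vals.std(ddof=1)) if vals.size > 1 else 0.0, mat


def bootstrap_condition_contrast(
    similaritiesA,
    similaritiesB,
    n_outer: int = 1000,
    seed: int | None = None,
) -> tuple[np.ndarray, float]:
    """Bootstrap contrast of pairwise synchrony between two paired conditions.

    The two inputs are per-pair similarities for the *same* participant
    pairs under conditions A and B.  Each outer iterate resamples the pairs
    with replacement (as many draws as pairs) and takes the median of the
    paired A−B differences; the two-tailed p-value is the add-one-corrected
    proportion of the ``n_outer`` medians crossing 0.
    """
    a = np.asarray(similaritiesA, dtype=float).ravel()
    b = np.asarray(similaritiesB, dtype=float).ravel()
    if a.size != b.size:
        raise ValueError("conditions must index the same participant pairs")
    if a.size < 2:
        raise ValueError("need at least two pairs")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, a.size, size=(n_outer, a.size))
    medians = np.median(a[idx] - b[idx], axis=1)
    n_le = np.count_nonzero(medians <= 0)
    n_ge = np.count_nonzero(medians >= 0)
    p = min(1.0, 2.0 * (min(n_le, n_ge) + 1) / (n_outer + 1))
    return medians, float(p)
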